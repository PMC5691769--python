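"""Self-organizing-map subtyping with sex-rank normalization.

Workflow: fit a :class:`SexRankTransformer` on the training set, train a
batch SOM (Gaussian neighborhood, linearly shrinking radius) on the ranked
training profiles, assign evaluation participants to best-matching units,
color the lattice by trait averages, cut the codebook into K contiguous
subgroups, and summarize each subgroup with bootstrap confidence intervals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans

from .errors import ConfigurationError, ValidationError

#: Default SOM training variables: the nutritional/socio-economic profile.
#: Region and outcomes stay out of training and are used for coloring only.
DEFAULT_TRAINING_VARIABLES = (
    "rice",
    "wheat",
    "total_meat",
    "total_vegetable",
    "legumes",
    "fibre",
    "soy_sauce",
    "iron",
    "total_calories",
    "income_numeric",
    "urban",
)


class SexRankTransformer:
    """Within-sex mid-rank transform to [0, 1], pooled back together.

    Fitting records, per sex and variable, the sorted unique training values
    and their scaled mid-ranks; transforming interpolates new values onto
    that curve (clipping outside the training range). This removes the sex
    main effect from every variable before pooling.
    """

    def __init__(self):
        self._tables: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        self.variables: list[str] | None = None

    def fit(self, data: pd.DataFrame, sex) -> "SexRankTransformer":
        sex = np.asarray(sex)
        self.variables = list(data.columns)
        for level in pd.unique(sex):
            mask = sex == level
            if mask.sum() < 2:
                raise ValidationError(
                    f"need at least 2 participants per sex, got {mask.sum()}"
                    f" for {level!r}")
            for var in self.variables:
                x = data.loc[mask, var].to_numpy(dtype=float)
                x = x[np.isfinite(x)]
                if x.size == 0:
                    warnings.warn(f"variable {var!r} all-missing in sex "
                                  f"{level!r}; excluded from its transform")
                    continue
                n = x.size
                ranks = sps.rankdata(x, method="average")
                scaled = (ranks - 1) / (n - 1) if n > 1 else np.full(n, 0.5)
                # mid-rank per unique value
                order = np.argsort(x, kind="stable")
                xs, rs = x[order], scaled[order]
                uniq_vals, idx = np.unique(xs, return_index=True)
                uniq_ranks = np.array(
                    [rs[xs == v].mean() for v in uniq_vals])
                self._tables[(str(level), var)] = (uniq_vals, uniq_ranks)
        return self

    def transform(self, data: pd.DataFrame, sex) -> pd.DataFrame:
        if self.variables is None:
            raise ValidationError("transformer is not fitted")
        sex = np.asarray(sex)
        out = pd.DataFrame(np.nan, index=data.index, columns=self.variables)
        for level in pd.unique(sex):
            mask = sex == level
            for var in self.variables:
                key = (str(level), var)
                if key not in self._tables:
                    continue
                vals, ranks = self._tables[key]
                x = data.loc[mask, var].to_numpy(dtype=float)
                y = np.interp(x, vals, ranks)
                y[~np.isfinite(x)] = np.nan
                out.loc[mask, var] = y
        return out

    def fit_transform(self, data: pd.DataFrame, sex) -> pd.DataFrame:
        return self.fit(data, sex).transform(data, sex)


def rank_transform_by_sex(data: pd.DataFrame, sex) -> pd.DataFrame:
    """One-shot within-sex mid-rank transform (fit and apply on same data)."""
    return SexRankTransformer().fit_transform(data, sex)


# --------------------------------------------------------------------------
# SOM
# --------------------------------------------------------------------------

@dataclass
class SOMModel:
    """A trained two-dimensional batch SOM."""

    grid: tuple[int, int]                 # (width, height)
    unit_coords: np.ndarray               # (n_units, 2) lattice coordinates
    codebook: np.ndarray                  # (n_units, n_variables)
    variables: list[str]
    epochs: int
    radius: tuple[float, float]
    seed: int
    quantization_error_initial: float = np.nan
    quantization_error_final: float = np.nan

    @property
    def n_units(self) -> int:
        return self.unit_coords.shape[0]

    def lattice_distances(self) -> np.ndarray:
        d = self.unit_coords[:, None, :] - self.unit_coords[None, :, :]
        return np.sqrt((d ** 2).sum(axis=2))

    def to_json(self, path) -> None:
        payload = {
            "grid": list(self.grid),
            "unit_coords": self.unit_coords.tolist(),
            "codebook": self.codebook.tolist(),
            "variables": self.variables,
            "epochs": self.epochs,
            "radius": list(self.radius),
            "seed": self.seed,
            "quantization_error_initial": self.quantization_error_initial,
            "quantization_error_final": self.quantization_error_final,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SOMModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            grid=tuple(payload["grid"]),
            unit_coords=np.array(payload["unit_coords"], dtype=float),
            codebook=np.array(payload["codebook"], dtype=float),
            variables=list(payload["variables"]),
            epochs=int(payload["epochs"]),
            radius=tuple(payload["radius"]),
            seed=int(payload["seed"]),
            quantization_error_initial=float(
                payload["quantization_error_initial"]),
            quantization_error_final=float(
                payload["quantization_error_final"]),
        )


def _grid_coords(grid: tuple[int, int]) -> np.ndarray:
    width, height = grid
    xs, ys = np.meshgrid(np.arange(width), np.arange(height), indexing="ij")
    return np.column_stack([xs.ravel(), ys.ravel()]).astype(float)


def _quantization_error(x: np.ndarray, codebook: np.ndarray) -> float:
    d = np.sqrt(((x[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2))
    return float(d.min(axis=1).mean())


def train_som(ranked: pd.DataFrame, grid: tuple[int, int] = (8, 6),
              epochs: int = 20, radius: tuple[float, float] = (4.0, 1.0),
              seed: int = 0) -> SOMModel:
    """Train a batch SOM on rank-transformed profiles.

    Gaussian neighborhood with radius shrinking linearly from ``radius[0]``
    to ``radius[1]`` over the epochs; the codebook is initialized uniformly
    at random within each variable's training range (seeded). Deterministic
    given the seed. Rows with any missing value are excluded from training.
    """
    x = ranked.to_numpy(dtype=float)
    complete = np.isfinite(x).all(axis=1)
    x = x[complete]
    n, _ = x.shape
    if n == 0:
        raise ValidationError("no complete training rows")
    coords = _grid_coords(grid)
    n_units = coords.shape[0]
    if n_units > 4 * n:
        warnings.warn(f"{n_units} units for only {n} training rows; "
                      "the map will be sparsely populated")
    rng = np.random.default_rng(seed)
    lo, hi = x.min(axis=0), x.max(axis=0)
    # data mean plus small seeded jitter: a deliberately poor quantizer, so
    # training reliably improves on it; the jitter breaks lattice symmetry
    codebook = (x.mean(axis=0)
                + rng.uniform(-0.05, 0.05, size=(n_units, x.shape[1]))
                * (hi - lo))
    qe_initial = _quantization_error(x, codebook)

    lattice_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    for epoch in range(epochs):
        frac = epoch / max(1, epochs - 1)
        r = radius[0] + (radius[1] - radius[0]) * frac
        d = ((x[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
        bmu = d.argmin(axis=1)
        h = np.exp(-lattice_d2 / (2.0 * r * r))  # (units, units)
        counts = np.bincount(bmu, minlength=n_units).astype(float)
        sums = np.zeros_like(codebook)
        np.add.at(sums, bmu, x)
        denom = h @ counts
        codebook = (h @ sums) / denom[:, None]

    model = SOMModel(
        grid=grid, unit_coords=coords, codebook=codebook,
        variables=list(ranked.columns), epochs=epochs, radius=radius,
        seed=seed, quantization_error_initial=qe_initial,
        quantization_error_final=_quantization_error(x, codebook))
    return model


def assign_bmu(model: SOMModel, profiles: pd.DataFrame) -> pd.Series:
    """Best-matching unit per row (mean squared difference over observed
    dimensions; ties broken by lowest unit index; all-missing rows get -1)."""
    if list(profiles.columns) != model.variables:
        profiles = profiles[model.variables]
    x = profiles.to_numpy(dtype=float)
    obs = np.isfinite(x)
    x_filled = np.where(obs, x, 0.0)
    # squared distances accumulated over observed dims only
    d2 = np.zeros((x.shape[0], model.n_units))
    for k in range(model.n_units):
        diff = np.where(obs, x_filled - model.codebook[k], 0.0)
        d2[:, k] = (diff ** 2).sum(axis=1)
    n_obs = obs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = d2 / n_obs[:, None]
    bmu = d2.argmin(axis=1)
    bmu[n_obs == 0] = -1
    if (n_obs == 0).any():
        warnings.warn(f"{int((n_obs == 0).sum())} profile(s) with no observed "
                      "dimensions left unassigned")
    return pd.Series(bmu, index=profiles.index, name="bmu")


# --------------------------------------------------------------------------
# Colorings and subgroups
# --------------------------------------------------------------------------

@dataclass
class MapColoring:
    """Per-unit smoothed trait average plus raw occupancy."""

    trait: str
    per_unit_value: np.ndarray  # NaN where the smoothed weight is zero
    occupancy: np.ndarray       # raw resident count per unit
    radius: float


def color_map(model: SOMModel, assignments: pd.Series, values: pd.Series,
              radius: float = 1.0) -> MapColoring:
    """Neighborhood-smoothed per-unit average of a trait.

    Each unit's value is the Gaussian-kernel-weighted mean of the trait over
    residents of the unit and its lattice neighbors; ``radius=0`` uses each
    unit's own residents only. Units with zero smoothed weight stay NaN.
    """
    if len(assignments) == 0:
        raise ValidationError("no assignments to color")
    vals = values.loc[assignments.index].to_numpy(dtype=float)
    bmu = assignments.to_numpy()
    ok = (bmu >= 0) & np.isfinite(vals)
    n_units = model.n_units
    occupancy = np.bincount(bmu[bmu >= 0], minlength=n_units).astype(float)
    sums = np.bincount(bmu[ok], weights=vals[ok], minlength=n_units)
    counts = np.bincount(bmu[ok], minlength=n_units).astype(float)
    if radius == 0:
        kernel = np.eye(n_units)
    else:
        d = model.lattice_distances()
        kernel = np.exp(-d ** 2 / (2.0 * radius ** 2))
    weight = kernel @ counts
    with np.errstate(invalid="ignore", divide="ignore"):
        smoothed = np.where(weight > 0, (kernel @ sums) / weight, np.nan)
    return MapColoring(trait=str(values.name), per_unit_value=smoothed,
                       occupancy=occupancy, radius=radius)


@dataclass
class SubgroupAssignment:
    """Unit-level regions and the induced participant membership."""

    regions: np.ndarray          # region id per unit (1..K)
    membership: pd.Series        # participant -> region id (NaN if unassigned)
    n_regions: int


def _lattice_neighbors(model: SOMModel) -> list[np.ndarray]:
    d = model.lattice_distances()
    return [np.flatnonzero((d[u] > 0) & (d[u] <= 1.0))
            for u in range(model.n_units)]


def _repair_contiguity(regions: np.ndarray, model: SOMModel) -> np.ndarray:
    """Reassign units of non-largest connected fragments to the majority
    neighboring region until every region is lattice-contiguous."""
    neighbors = _lattice_neighbors(model)
    regions = regions.copy()
    for _ in range(model.n_units):
        changed = False
        for region in np.unique(regions):
            members = np.flatnonzero(regions == region)
            # connected components within the region
            seen: set[int] = set()
            components = []
            for start in members:
                if start in seen:
                    continue
                stack, comp = [start], set()
                while stack:
                    u = stack.pop()
                    if u in comp:
                        continue
                    comp.add(u)
                    stack.extend(v for v in neighbors[u]
                                 if regions[v] == region and v not in comp)
                seen |= comp
                components.append(comp)
            if len(components) <= 1:
                continue
            components.sort(key=lambda c: (len(c), -min(c)))
            for comp in components[:-1]:
                for u in sorted(comp):
                    neigh_regions = [regions[v] for v in neighbors[u]
                                     if regions[v] != region]
                    if neigh_regions:
                        vals, counts = np.unique(neigh_regions,
                                                 return_counts=True)
                        regions[u] = vals[counts.argmax()]
                        changed = True
        if not changed:
            break
    return regions


def define_subgroups(model: SOMModel, assignments: pd.Series,
                     coloring: MapColoring | None = None, k: int = 4,
                     manual_regions: dict[int, int] | None = None,
                     seed: int = 0) -> SubgroupAssignment:
    """Cut the map into K contiguous regions and derive memberships.

    Default automation: seeded k-means on the codebook vectors followed by
    contiguity repair. ``manual_regions`` (unit -> region id covering every
    unit) overrides the automation, reproducing a user-drawn partition.
    ``coloring`` orders the region ids by descending smoothed value (so
    region 1 is the highest-value region); without it, ids follow the lowest
    member unit.
    """
    if manual_regions is not None:
        missing = set(range(model.n_units)) - set(manual_regions)
        if missing:
            raise ValidationError(
                f"manual regions do not cover units: {sorted(missing)[:5]}")
        regions = np.array([manual_regions[u] for u in range(model.n_units)])
    else:
        if k > model.n_units:
            raise ConfigurationError(
                f"k={k} exceeds the number of units ({model.n_units})")
        if k == 1:
            regions = np.ones(model.n_units, dtype=int)
        else:
            km = KMeans(n_clusters=k, random_state=seed, n_init=10)
            regions = km.fit_predict(model.codebook) + 1
            regions = _repair_contiguity(regions, model)
    # relabel regions deterministically
    unique = np.unique(regions)
    if coloring is not None:
        order = sorted(
            unique,
            key=lambda r: -np.nanmean(np.where(
                regions == r, coloring.per_unit_value, np.nan)))
    else:
        order = sorted(unique, key=lambda r: np.flatnonzero(regions == r)[0])
    relabel = {old: new + 1 for new, old in enumerate(order)}
    regions = np.array([relabel[r] for r in regions])
    bmu = assignments.to_numpy()
    membership = np.where(bmu >= 0, regions[np.clip(bmu, 0, None)], np.nan)
    return SubgroupAssignment(
        regions=regions,
        membership=pd.Series(membership, index=assignments.index,
                             name="subgroup"),
        n_regions=len(unique))


# --------------------------------------------------------------------------
# Bootstrap summaries
# --------------------------------------------------------------------------

def subgroup_summary(membership: pd.Series, traits: pd.DataFrame,
                     n_boot: int = 10_000, seed: int = 0,
                     reference_means: pd.Series | None = None) -> pd.DataFrame:
    """Per-subgroup trait means with bootstrap percentile CI95.

    ``reference_means`` (default: the column means over all participants in
    ``membership``) provides the evaluation-set mean whose exclusion from
    the CI sets ``outside_reference``. Subgroups of size one get a
    degenerate CI at the observed value.
    """
    traits = traits.loc[membership.index]
    if reference_means is None:
        reference_means = traits.mean()
    rng = np.random.default_rng(seed)
    rows = []
    for subgroup in sorted(pd.unique(membership.dropna())):
        members = membership.index[membership == subgroup]
        if len(members) == 0:
            continue
        block = traits.loc[members]
        n = len(members)
        idx = rng.integers(0, n, size=(n_boot, n))
        for trait in traits.columns:
            x = block[trait].to_numpy(dtype=float)
            finite = np.isfinite(x)
            if not finite.all():
                x = x[finite]
                if x.size == 0:
                    continue
                idx_t = rng.integers(0, x.size, size=(n_boot, x.size))
            else:
                idx_t = idx
            mean = float(x.mean())
            if x.size == 1:
                lo = hi = mean
            else:
                boot_means = x[idx_t].mean(axis=1)
                lo, hi = np.percentile(boot_means, [2.5, 97.5])
            ref = float(reference_means[trait])
            rows.append({
                "subgroup": subgroup, "trait": trait, "n": n,
                "mean": mean, "ci_low": float(lo), "ci_high": float(hi),
                "reference_mean": ref,
                "outside_reference": bool(ref < lo or ref > hi),
            })
    return pd.DataFrame(rows)
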
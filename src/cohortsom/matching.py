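"""Age-matched case-control selection and PC-score-matched training sets.

Two procedures:

- :func:`match_age_controls` — per sex stratum, keep the largest subset of
  eligible controls whose age distribution is not significantly different
  from the cases (greedy farthest-from-case-mean removal).
- :func:`match_training_set` — greedy nearest-neighbour pairing of training
  candidates to a reference set in standardized module-PC space, with
  balance tests on a configured variable list and iterative worst-pair
  dropping when balance fails.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import SEX_LEVELS
from .errors import MatchingError, ValidationError

BALANCE_ALPHA = 0.05


@dataclass
class MatchResult:
    """Outcome of one matching procedure (self-validating balance record)."""

    case_ids: list[str]
    control_ids: list[str]
    stratum: str
    balance_tests: dict[str, float]
    method: str
    pair_distances: list[float] = field(default_factory=list)

    def __post_init__(self):
        overlap = set(self.case_ids) & set(self.control_ids)
        if overlap:
            raise ValidationError(
                f"case and control sets overlap: {sorted(overlap)[:5]}")

    @property
    def balanced(self) -> bool:
        return all(p > BALANCE_ALPHA for p in self.balance_tests.values())

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "stratum": self.stratum,
            "case_ids": list(self.case_ids),
            "control_ids": list(self.control_ids),
            "balance_tests": dict(self.balance_tests),
            "pair_distances": list(self.pair_distances),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "MatchResult":
        return cls(**payload)


def write_match_results(results: dict[str, MatchResult], path) -> None:
    with open(path, "w") as fh:
        json.dump({k: r.to_dict() for k, r in results.items()}, fh, indent=2)


def read_match_results(path) -> dict[str, MatchResult]:
    with open(path) as fh:
        payload = json.load(fh)
    return {k: MatchResult.from_dict(v) for k, v in payload.items()}


def welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch t-test p-value, with degenerate inputs handled.

    Zero variance in both groups gives p = 1 for equal means and p = 0
    otherwise; empty groups give p = 0 (no evidence of balance).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        return 0.0
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = sps.ttest_ind(a, b, equal_var=False).pvalue
    return float(p) if np.isfinite(p) else 1.0


def ks_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov p-value (config-switchable balance test)."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        return 0.0
    return float(sps.ks_2samp(a, b).pvalue)


_BALANCE_TESTS = {"welch": welch_p, "ks": ks_p}


def match_age_controls(cases: list[str], eligible: list[str],
                       cohort: pd.DataFrame, *, alpha: float = BALANCE_ALPHA,
                       test: str = "welch") -> dict[str, MatchResult]:
    """Select, per sex, as many controls as possible with balanced ages.

    Starting from all eligible controls of the stratum, the control whose
    age lies farthest from the case mean age is removed (ties broken by
    participant id) until the two-sample test on age exceeds ``alpha``.
    Returns a :class:`MatchResult` per sex stratum; an empty control set
    with a warning if even one control cannot be balanced.
    """
    if test not in _BALANCE_TESTS:
        raise ValidationError(f"unknown balance test: {test!r}")
    p_of = _BALANCE_TESTS[test]
    overlap = set(cases) & set(eligible)
    if overlap:
        raise ValidationError(
            f"ids appear in both cases and eligible: {sorted(overlap)[:5]}")
    indexed = cohort.set_index("id")
    results = {}
    for stratum in SEX_LEVELS:
        sex = indexed["sex"]
        s_cases = [i for i in cases if sex.loc[i] == stratum]
        s_eligible = [i for i in eligible if sex.loc[i] == stratum]
        if not s_cases or not s_eligible:
            results[stratum] = MatchResult(
                case_ids=s_cases, control_ids=[], stratum=stratum,
                balance_tests={}, method=f"age-greedy-{test}")
            continue
        case_ages = indexed.loc[s_cases, "age"].to_numpy(dtype=float)
        target = case_ages.mean()
        # removal order: farthest from the case mean first, id as tie-break
        pool = sorted(s_eligible,
                      key=lambda i: (-abs(indexed.at[i, "age"] - target), i))
        selected = list(pool)
        p = p_of(case_ages, indexed.loc[selected, "age"].to_numpy(dtype=float))
        while p <= alpha and selected:
            selected = selected[1:]
            p = p_of(case_ages,
                     indexed.loc[selected, "age"].to_numpy(dtype=float))
        if not selected:
            warnings.warn(
                f"no age-balanced control subset found for stratum {stratum!r}")
            results[stratum] = MatchResult(
                case_ids=s_cases, control_ids=[], stratum=stratum,
                balance_tests={"age": 0.0}, method=f"age-greedy-{test}")
            continue
        results[stratum] = MatchResult(
            case_ids=s_cases, control_ids=sorted(selected), stratum=stratum,
            balance_tests={"age": p}, method=f"age-greedy-{test}")
    return results


def _balance_report(selected: pd.DataFrame, reference: pd.DataFrame,
                    balance_vars: list[str]) -> dict[str, float]:
    report = {}
    for var in balance_vars:
        if var == "sex":
            table = pd.crosstab(
                np.r_[np.zeros(len(selected)), np.ones(len(reference))],
                pd.concat([selected["sex"], reference["sex"]]).to_numpy())
            if table.shape[1] < 2:
                report[var] = 1.0  # single sex on both sides
            else:
                report[var] = float(
                    sps.chi2_contingency(table.to_numpy()).pvalue)
        else:
            report[var] = welch_p(selected[var].to_numpy(dtype=float),
                                  reference[var].to_numpy(dtype=float))
    return report


def match_training_set(candidates: list[str], reference: list[str],
                       scores: pd.DataFrame, balance_vars: list[str],
                       cohort: pd.DataFrame, *, alpha: float = BALANCE_ALPHA,
                       floor_fraction: float = 0.5) -> MatchResult:
    """Pair candidates to a reference set in standardized PC-score space.

    Greedy nearest-neighbour pairing without replacement: the globally
    closest (candidate, reference) pair is accepted first, then the next
    closest among the unused, and so on (Euclidean distance on score
    columns standardized over both sets; ties broken by row order). If the
    selected candidates fail any balance test against the reference set
    (Welch t for quantitative variables, chi-squared for sex), the worst
    (largest-distance) pairs are dropped one at a time until balance is
    reached or the selection would fall below ``floor_fraction`` of the
    reference size, which raises :class:`MatchingError` naming the
    offending variables.
    """
    if not candidates or not reference:
        raise ValidationError("candidates and reference must be non-empty")
    candidates, reference = list(candidates), list(reference)
    missing = [i for i in candidates + reference if i not in scores.index]
    if missing:
        raise ValidationError(f"ids without PC scores: {missing[:5]}")
    both = scores.loc[candidates + reference]
    mu, sd = both.mean(), both.std(ddof=0).replace(0.0, 1.0)
    cand = ((scores.loc[candidates] - mu) / sd).to_numpy(dtype=float)
    ref = ((scores.loc[reference] - mu) / sd).to_numpy(dtype=float)

    dist = np.sqrt(((cand[:, None, :] - ref[None, :, :]) ** 2).sum(axis=2))
    n_pairs = min(len(candidates), len(reference))
    used_c = np.zeros(len(candidates), dtype=bool)
    used_r = np.zeros(len(reference), dtype=bool)
    order = np.dstack(np.unravel_index(
        np.argsort(dist, axis=None, kind="stable"), dist.shape))[0]
    pairs: list[tuple[int, int, float]] = []
    for ci, ri in order:
        if used_c[ci] or used_r[ri]:
            continue
        used_c[ci] = used_r[ri] = True
        pairs.append((int(ci), int(ri), float(dist[ci, ri])))
        if len(pairs) == n_pairs:
            break
    pairs.sort(key=lambda t: t[2])

    indexed = cohort.set_index("id")
    ref_df = indexed.loc[reference]
    floor = max(1, int(np.ceil(floor_fraction * len(reference))))
    while True:
        ids = [candidates[ci] for ci, _, _ in pairs]
        report = _balance_report(indexed.loc[ids], ref_df, balance_vars)
        failing = sorted(v for v, p in report.items() if p <= alpha)
        if not failing:
            return MatchResult(
                case_ids=reference, control_ids=ids, stratum="pooled",
                balance_tests=report, method="pc-greedy-nn",
                pair_distances=[d for _, _, d in pairs])
        if len(pairs) - 1 < floor:
            raise MatchingError(
                "training-set balance unattainable above the "
                f"{floor_fraction:.0%} floor; failing variables: {failing}; "
                f"p-values: { {v: round(report[v], 6) for v in failing} }")
        pairs = pairs[:-1]
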
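"""Correlation network of cohort variables and its module decomposition.

Pipeline: sex-weighted Spearman correlations -> maximum spanning tree on
absolute weights -> greedy agglomerative modularity communities -> per-module
principal-component scores. All stages are deterministic, with documented
lexicographic tie-breaking.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class CorrelationNetwork:
    """Weighted variable-variable network (weights in [-1, 1])."""

    graph: nx.Graph
    pruned: bool = False

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edges(self) -> list[tuple[str, str, float]]:
        return sorted((min(u, v), max(u, v), d["weight"])
                      for u, v, d in self.graph.edges(data=True))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges(), columns=["u", "v", "weight"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, pruned: bool = False):
        g = nx.Graph()
        for u, v, w in frame[["u", "v", "weight"]].itertuples(index=False):
            g.add_edge(str(u), str(v), weight=float(w))
        return cls(graph=g, pruned=pruned)


@dataclass
class ModuleSet:
    """Variable-to-module assignment with optional per-module PC scores."""

    assignment: dict[str, int]
    scores: pd.DataFrame | None = None  # index: participant, cols (module, pc)
    explained_variance: dict[int, np.ndarray] = field(default_factory=dict)
    loadings: dict[int, pd.DataFrame] = field(default_factory=dict)

    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for var, mod in self.assignment.items():
            out.setdefault(mod, []).append(var)
        return {m: sorted(vs) for m, vs in out.items()}


def sex_weighted_spearman(data: pd.DataFrame, sex) -> CorrelationNetwork:
    """Combine per-sex Spearman correlations, weighted by sex fractions.

    Edge weight = w_f * rho_f + w_m * rho_m where the weights are the
    fractions of participants in each sex stratum (pairwise-complete
    observations within stratum). Strata where a correlation is undefined
    (constant variable) are dropped from the combination with their weight
    renormalized; a variable constant in every stratum gets zero-weight
    edges and a warning.
    """
    sex = np.asarray(sex)
    if data.shape[1] < 2:
        raise ValidationError("need at least 2 variables")
    levels = [lev for lev in pd.unique(sex)]
    for lev in levels:
        if (sex == lev).sum() < 3:
            raise ValidationError(
                f"need at least 3 participants per sex, got {(sex == lev).sum()}"
                f" for {lev!r}")
    variables = list(data.columns)
    combined = np.zeros((len(variables), len(variables)))
    weight_sum = np.zeros_like(combined)
    for lev in levels:
        mask = sex == lev
        frac = mask.mean()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = data.loc[mask].corr(method="spearman").to_numpy()
        ok = np.isfinite(rho)
        combined[ok] += frac * rho[ok]
        weight_sum[ok] += frac
    with np.errstate(invalid="ignore", divide="ignore"):
        combined = np.where(weight_sum > 0, combined / weight_sum, 0.0)
    dead = [variables[i] for i in range(len(variables))
            if not (weight_sum[i, :][np.arange(len(variables)) != i] > 0).any()]
    if dead:
        warnings.warn(f"variables constant within every sex: {dead}; "
                      "their edges were set to 0")
    g = nx.Graph()
    g.add_nodes_from(variables)
    for i, j in itertools.combinations(range(len(variables)), 2):
        g.add_edge(variables[i], variables[j], weight=float(combined[i, j]))
    return CorrelationNetwork(graph=g, pruned=False)


class _DisjointSet:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def prune_spanning_tree(network: CorrelationNetwork) -> CorrelationNetwork:
    """Keep the maximum spanning forest on absolute edge weights.

    Kruskal with deterministic ordering (descending |weight|, then labels).
    Per connected component the retained edge count is ``nodes - 1``; the
    result is sign-invariant (flipping every correlation's sign retains the
    same edge set).
    """
    g = network.graph
    pruned = nx.Graph()
    pruned.add_nodes_from(g.nodes)
    edges = sorted(((min(u, v), max(u, v), d["weight"])
                    for u, v, d in g.edges(data=True)),
                   key=lambda e: (-abs(e[2]), e[0], e[1]))
    dsu = _DisjointSet(list(g.nodes))
    for u, v, w in edges:
        if dsu.union(u, v):
            pruned.add_edge(u, v, weight=w)
    return CorrelationNetwork(graph=pruned, pruned=True)


def _modularity(adj: np.ndarray, communities: list[set[int]]) -> float:
    two_m = adj.sum()
    if two_m == 0:
        return 0.0
    degrees = adj.sum(axis=1)
    q = 0.0
    for comm in communities:
        idx = sorted(comm)
        q += adj[np.ix_(idx, idx)].sum() / two_m
        q -= (degrees[idx].sum() / two_m) ** 2
    return q


def _greedy_agglomeration(adj: np.ndarray) -> list[set[int]]:
    """CNM-style greedy merging of connected community pairs.

    Repeatedly applies the merge with the largest modularity gain (ties
    broken lexicographically on the smallest member index of the merged
    pair) until no merge improves modularity.
    """
    communities: list[set[int]] = [{i} for i in range(adj.shape[0])]
    q = _modularity(adj, communities)
    while len(communities) > 1:
        best = None
        for a, b in itertools.combinations(range(len(communities)), 2):
            ia, ib = sorted(communities[a]), sorted(communities[b])
            if adj[np.ix_(ia, ib)].sum() == 0:
                continue  # only merge connected communities
            merged = (communities[:a] + communities[a + 1:b]
                      + communities[b + 1:] + [communities[a] | communities[b]])
            gain = _modularity(adj, merged) - q
            key = (-gain, min(communities[a] | communities[b]))
            if best is None or key < best[0]:
                best = (key, a, b, gain)
        if best is None or best[3] <= 1e-12:
            break
        _, a, b, gain = best
        merged_comm = communities[a] | communities[b]
        communities = [c for k, c in enumerate(communities) if k not in (a, b)]
        communities.append(merged_comm)
        q += gain
    return communities


def _canonical(partition) -> tuple:
    return tuple(sorted(tuple(sorted(c)) for c in partition))


def _exact_agglomeration(adj: np.ndarray) -> list[set[int]]:
    """Best partition reachable by any sequence of connected-pair merges.

    Exhaustive search with memoization; tractable only for small graphs.
    Ties between equally-modular partitions are broken by the canonical
    (lexicographically smallest) form.
    """
    n = adj.shape[0]
    start = frozenset(frozenset([i]) for i in range(n))
    best_q, best_part = _modularity(adj, [set(c) for c in start]), start
    seen = {start}
    stack = [start]
    while stack:
        part = stack.pop()
        comms = sorted(part, key=min)
        for a, b in itertools.combinations(range(len(comms)), 2):
            ia, ib = sorted(comms[a]), sorted(comms[b])
            if adj[np.ix_(ia, ib)].sum() == 0:
                continue
            merged = frozenset(
                [c for k, c in enumerate(comms) if k not in (a, b)]
                + [comms[a] | comms[b]])
            if merged in seen:
                continue
            seen.add(merged)
            stack.append(merged)
            q = _modularity(adj, [set(c) for c in merged])
            if (q > best_q + 1e-12
                    or (abs(q - best_q) <= 1e-12
                        and _canonical(merged) < _canonical(best_part))):
                best_q, best_part = q, merged
    return [set(c) for c in best_part]


#: Node-count bound below which module detection is exact.
EXACT_MODULE_SEARCH_LIMIT = 8


def detect_modules(network: CorrelationNetwork) -> ModuleSet:
    """Agglomerative modularity communities on absolute weights.

    Small graphs (at most :data:`EXACT_MODULE_SEARCH_LIMIT` nodes) get the
    exhaustively best merge sequence; larger graphs use greedy
    modularity-maximizing agglomeration (merge the connected pair with the
    largest gain; ties broken lexicographically on the smallest member
    label) stopped when no merge improves modularity. Either way the
    returned modularity is never below the all-singletons partition, every
    node is assigned, and the result is deterministic. Module ids follow
    each module's smallest member label.
    """
    nodes = sorted(network.graph.nodes)
    if not nodes:
        return ModuleSet(assignment={})
    index = {v: i for i, v in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)))
    for u, v, d in network.graph.edges(data=True):
        w = abs(d["weight"])
        adj[index[u], index[v]] = adj[index[v], index[u]] = w

    if len(nodes) <= EXACT_MODULE_SEARCH_LIMIT:
        communities = _exact_agglomeration(adj)
    else:
        communities = _greedy_agglomeration(adj)

    communities.sort(key=lambda c: nodes[min(c)])
    assignment = {}
    for mod_id, comm in enumerate(communities):
        for i in comm:
            assignment[nodes[i]] = mod_id
    return ModuleSet(assignment=assignment)


def module_scores(data: pd.DataFrame, modules: ModuleSet,
                  n_components: int = 2) -> ModuleSet:
    """Fill per-module principal-component scores (correlation-matrix PCA).

    Variables are z-scored before the decomposition. PC1 is sign-fixed to
    load positively on the module's alphabetically-first variable with a
    nonzero loading (PC2 likewise). Single-variable modules return the
    z-scored variable as PC1 and zeros for PC2; zero-variance variables are
    dropped from their module with a warning.
    """
    score_blocks = {}
    explained = {}
    loadings = {}
    for mod_id, variables in modules.modules().items():
        missing = [v for v in variables if v not in data.columns]
        if missing:
            raise ValidationError(
                f"module {mod_id} variables absent from data: {missing}")
        block = data[variables].to_numpy(dtype=float)
        sd = block.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            dropped = [v for v, k in zip(variables, keep) if not k]
            warnings.warn(
                f"zero-variance variable(s) dropped from module {mod_id}: {dropped}")
            variables = [v for v, k in zip(variables, keep) if k]
            block, sd = block[:, keep], sd[keep]
        if not variables:
            continue
        z = (block - block.mean(axis=0)) / sd
        n, k = z.shape
        u_mat, s, vt = np.linalg.svd(z, full_matrices=False)
        var_frac = s ** 2 / (s ** 2).sum()
        comps = np.zeros((n_components, k))
        comps[:min(n_components, k)] = vt[:min(n_components, k)]
        for c in range(min(n_components, k)):
            nz = np.flatnonzero(np.abs(comps[c]) > 1e-12)
            if nz.size and comps[c, nz[0]] < 0:
                comps[c] = -comps[c]
        block_scores = z @ comps.T
        score_blocks[mod_id] = block_scores
        explained[mod_id] = np.pad(var_frac, (0, max(0, n_components - k)))[:n_components]
        loadings[mod_id] = pd.DataFrame(
            comps.T, index=variables,
            columns=[f"pc{c + 1}" for c in range(n_components)])

    columns = pd.MultiIndex.from_tuples(
        [(m, f"pc{c + 1}") for m in sorted(score_blocks)
         for c in range(n_components)], names=["module", "component"])
    values = np.hstack([score_blocks[m] for m in sorted(score_blocks)]) \
        if score_blocks else np.empty((len(data), 0))
    scores = pd.DataFrame(values, index=data.index, columns=columns)
    return ModuleSet(assignment=dict(modules.assignment), scores=scores,
                     explained_variance=explained, loadings=loadings)
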
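"""Network-based statistic: differential-edge selection with permutation FWE.

Edge-wise two-group GLM (pooled two-sample t-test) over the 171 partial
correlations, suprathreshold edge selection at a primary p cutoff,
breadth-first connected-component search, and a max-component-size
permutation null giving family-wise-error-corrected component p-values.
Hubs are ranked by degree within the selected differential network.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from vnsnet.montage import CHANNELS, edge_pairs
from vnsnet.preprocessing import RESPONDER

Edge = tuple[int, int]

DEFAULT_THRESHOLD = 0.05
DEFAULT_N_PERMUTATIONS = 5000
THRESHOLD_LADDER = (0.05, 0.01, 0.005, 0.001)


@dataclass
class EdgeStatistics:
    t: np.ndarray
    p: np.ndarray
    n_group1: int
    n_group0: int


@dataclass
class SupraThresholdGraph:
    threshold: float
    edges: list[Edge]
    n_nodes: int

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg


@dataclass
class NBSResult:
    components: list[list[Edge]]
    fwe_p: list[float]
    max_component_size: int
    selected_edges: list[Edge]
    threshold: float
    n_permutations: int
    unit: str
    seed: object = None
    alpha: float = 0.05
    perm_max_sizes: np.ndarray = field(default=None, repr=False)


def _binary_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "OUS":
        return (labels == RESPONDER).astype(float)
    return labels.astype(float)


def _t_stats_multi(features: np.ndarray, label_rows: np.ndarray):
    """Pooled two-sample t per edge for each row of 0/1 labels.

    ``features``: [n, E]; ``label_rows``: [P, n]. Returns (t, p) of shape
    [P, E]. Degenerate zero-pooled-variance edges get t = 0, p = 1.
    """
    n = features.shape[0]
    n1 = label_rows.sum(axis=1, keepdims=True)
    n0 = n - n1
    tot = features.sum(axis=0, keepdims=True)
    tot_sq = (features**2).sum(axis=0, keepdims=True)
    s1 = label_rows @ features
    q1 = label_rows @ (features**2)
    s0, q0 = tot - s1, tot_sq - q1
    m1, m0 = s1 / n1, s0 / n0
    ss1 = np.maximum(q1 - n1 * m1**2, 0.0)
    ss0 = np.maximum(q0 - n0 * m0**2, 0.0)
    sp2 = (ss1 + ss0) / (n - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (m1 - m0) / np.where(se > 0, se, 1.0), 0.0)
    p = np.where(se > 0, 2.0 * stats.t.sf(np.abs(t), df=n - 2), 1.0)
    return t, p


def edgewise_glm_stats(features: np.ndarray, labels) -> EdgeStatistics:
    """Two-group GLM (pooled-variance t-test, two-sided p, n-2 df) per edge."""
    features = np.asarray(features, dtype=float)
    y = _binary_labels(labels)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if min(n1, n0) < 2:
        raise ValueError("each group needs at least 2 observations")
    t, p = _t_stats_multi(features, y[None, :])
    return EdgeStatistics(t=t[0], p=p[0], n_group1=n1, n_group0=n0)


def suprathreshold_graph(
    stats_: EdgeStatistics, threshold: float, n_nodes: int | None = None
) -> SupraThresholdGraph:
    """Edges with uncorrected p strictly below the primary threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    n_edges = len(stats_.p)
    if n_nodes is None:
        n_nodes = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    pairs = edge_pairs(n_nodes)
    edges = [pairs[k] for k in np.flatnonzero(stats_.p < threshold)]
    return SupraThresholdGraph(threshold=float(threshold), edges=edges, n_nodes=n_nodes)


def _bfs_components(edges: list[Edge]) -> list[list[Edge]]:
    """Breadth-first search over the node graph induced by ``edges``;
    each component is returned as its sorted edge list."""
    adjacency: dict[int, list[int]] = {}
    for i, j in edges:
        adjacency.setdefault(i, []).append(j)
        adjacency.setdefault(j, []).append(i)
    seen: set[int] = set()
    components: list[list[Edge]] = []
    for start in sorted(adjacency):
        if start in seen:
            continue
        queue = deque([start])
        seen.add(start)
        nodes = {start}
        while queue:
            u = queue.popleft()
            for v in adjacency[u]:
                if v not in seen:
                    seen.add(v)
                    nodes.add(v)
                    queue.append(v)
        comp = sorted(e for e in edges if e[0] in nodes)
        components.append(comp)
    components.sort(key=lambda c: (-len(c), c))
    return components


def connected_components(graph: SupraThresholdGraph) -> list[list[Edge]]:
    """Connected components of the suprathreshold graph, as edge sets,
    largest first."""
    return _bfs_components(graph.edges)


def _max_component_size(p_values: np.ndarray, threshold: float, pairs: list[Edge]) -> int:
    edges = [pairs[k] for k in np.flatnonzero(p_values < threshold)]
    if not edges:
        return 0
    return len(_bfs_components(edges)[0])


def _permuted_label_rows(y: np.ndarray, patient_ids, unit: str, n_perm: int, rng):
    if unit == "epoch":
        return rng.permuted(np.tile(y, (n_perm, 1)), axis=1)
    if unit != "patient":
        raise ValueError("unit must be 'epoch' or 'patient'")
    patient_ids = np.asarray(patient_ids)
    uniq, inverse = np.unique(patient_ids, return_inverse=True)
    patient_y = np.array([y[patient_ids == u][0] for u in uniq])
    if min(patient_y.sum(), len(uniq) - patient_y.sum()) < 2:
        raise ValueError("patient-level permutation needs >= 2 patients per group")
    perm_patient = rng.permuted(np.tile(patient_y, (n_perm, 1)), axis=1)
    return perm_patient[:, inverse]


def nbs_fwe_test(
    features: np.ndarray,
    labels,
    threshold: float = DEFAULT_THRESHOLD,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    unit: str = "epoch",
    patient_ids=None,
    seed=None,
    alpha: float = 0.05,
) -> NBSResult:
    """Full NBS: observed components + permutation max-component-size null.

    Group labels are shuffled ``n_perm`` times at the chosen
    exchangeability unit (whole-patient label swaps or epoch-level
    shuffles); each component's FWE p-value is
    (1 + #{perm max >= observed size}) / (n_perm + 1). Components with
    fwe_p < ``alpha`` form ``selected_edges``.
    """
    features = np.asarray(features, dtype=float)
    stats_obs = edgewise_glm_stats(features, labels)
    graph = suprathreshold_graph(stats_obs, threshold)
    components = connected_components(graph)
    pairs = edge_pairs(graph.n_nodes)

    y = _binary_labels(labels)
    if unit == "patient":
        if patient_ids is None:
            raise ValueError("patient_ids required for unit='patient'")
        uniq = np.unique(np.asarray(patient_ids))
        per_pat = np.array([y[np.asarray(patient_ids) == u][0] for u in uniq])
        if min(per_pat.sum(), len(uniq) - per_pat.sum()) < 2:
            raise ValueError("patient-level permutation needs >= 2 patients per group")
    rng = np.random.default_rng(seed)
    perm_max = np.zeros(n_perm, dtype=int)
    if components:
        label_rows = _permuted_label_rows(y, patient_ids, unit, n_perm, rng)
        # chunk the vectorized t computation to bound memory at ~50 MB
        chunk = max(1, int(5e7 // max(features.size, 1)))
        for start in range(0, n_perm, chunk):
            rows = label_rows[start : start + chunk]
            _, p = _t_stats_multi(features, rows)
            for k in range(rows.shape[0]):
                perm_max[start + k] = _max_component_size(p[k], threshold, pairs)

    fwe_p, selected = [], []
    for comp in components:
        pv = (1.0 + np.sum(perm_max >= len(comp))) / (n_perm + 1.0)
        fwe_p.append(float(pv))
        if pv < alpha:
            selected.extend(comp)
    return NBSResult(
        components=components,
        fwe_p=fwe_p,
        max_component_size=len(components[0]) if components else 0,
        selected_edges=sorted(set(selected)),
        threshold=float(threshold),
        n_permutations=int(n_perm),
        unit=unit,
        seed=seed,
        alpha=alpha,
        perm_max_sizes=perm_max,
    )


def rank_hubs(result: NBSResult, channels=CHANNELS) -> list[dict]:
    """Degree ranking of nodes within the selected differential network.

    Returns dicts with ``node``, ``degree`` (distinct neighbors within
    selected edges) and ``ratio`` formatted ``'degree/n_nodes'``, sorted
    by descending degree with ties broken by canonical channel order.
    """
    neighbors: dict[int, set[int]] = {}
    for i, j in result.selected_edges:
        neighbors.setdefault(i, set()).add(j)
        neighbors.setdefault(j, set()).add(i)
    ranking = [
        {
            "node": channels[node],
            "degree": len(nbrs),
            "ratio": f"{len(nbrs)}/{len(channels)}",
        }
        for node, nbrs in neighbors.items()
    ]
    order = {name: k for k, name in enumerate(channels)}
    ranking.sort(key=lambda r: (-r["degree"], order[r["node"]]))
    return ranking
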
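"""Weighted brain-graph metrics on cost-thresholded connectivity matrices.

A correlation matrix is sparsified by *proportional cost thresholding*:
the ``round(cost * n(n-1)/2)`` strongest positive correlations survive as
weighted edges.  On the resulting graph the module evaluates the standard
weighted metric set

* characteristic path length ``L`` (shortest paths over edge lengths
  ``1/w``; unreachable pairs are excluded and their fraction recorded),
* clustering coefficient ``C`` (geometric-mean triangle intensity on
  max-normalized weights; ``C_i = 0`` for degree < 2),
* local efficiency ``E_loc`` (neighborhood-restricted shortest paths),
* global efficiency ``E_glob`` (mean inverse distance; unreachable pairs
  count as zero efficiency),
* normalized ratios ``lambda = L / L_rand`` and ``gamma = C / C_rand``
  against an ensemble of degree-preserving rewired null graphs, and the
  small-worldness ``SW = gamma / lambda``.

The feasibility scan reproduces the usual three group-level criteria for
an admissible cost range: limited disconnection, mean degree above
``ln(n)``, and small-worldness above 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .connectivity import FCMatrix


@dataclass(frozen=True)
class WeightedGraph:
    """Symmetric nonnegative weight matrix with zero diagonal."""

    w: np.ndarray
    cost: float

    def __post_init__(self) -> None:
        w = self.w
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if np.any(np.diag(w) != 0):
            raise ValueError("no self-loops allowed")

    @property
    def n(self) -> int:
        return self.w.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return (self.w > 0).sum(axis=1)

    @property
    def n_edges(self) -> int:
        return int((self.w > 0).sum() // 2)

    def lengths(self) -> np.ndarray:
        """Edge length transform 1/w (absent edges -> inf handled sparsely)."""
        with np.errstate(divide="ignore"):
            length = np.where(self.w > 0, 1.0 / self.w, 0.0)
        return length

    def normalized(self) -> np.ndarray:
        """Weights rescaled by the maximum so triangle terms stay in [0, 1]."""
        mx = self.w.max()
        return self.w / mx if mx > 0 else self.w.copy()


@dataclass(frozen=True)
class GraphMetricsResult:
    L: float
    lam: float
    C: float
    gamma: float
    e_loc: float
    e_glob: float
    sw: float
    l_rand: float
    c_rand: float
    disconnected_pair_fraction: float
    per_node_L: np.ndarray = field(repr=False)
    per_node_C: np.ndarray = field(repr=False)
    per_node_eloc: np.ndarray = field(repr=False)
    per_node_eglob: np.ndarray = field(repr=False)
    degenerate_null: bool = False


def cost_threshold(fc: FCMatrix | np.ndarray, cost: float) -> WeightedGraph:
    """Keep the m = round(cost * n(n-1)/2) largest positive correlations.

    Ties at the boundary are broken by lexicographic (i, j) order so the
    retained edge set is reproducible.
    """
    values = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    n = values.shape[0]
    if not 0 < cost <= 1:
        raise ValueError("cost must lie in (0, 1]")
    m = int(round(cost * n * (n - 1) / 2))
    iu, ju = np.triu_indices(n, k=1)
    w = values[iu, ju]
    positive = w > 0
    if positive.sum() < m:
        raise ValueError(
            f"infeasible cost {cost}: requires {m} edges but only "
            f"{int(positive.sum())} positive correlations available")
    order = np.lexsort((ju, iu, -w))       # strongest first, then (i, j)
    keep = order[:m]
    adj = np.zeros_like(values)
    adj[iu[keep], ju[keep]] = w[keep]
    adj += adj.T
    return WeightedGraph(w=adj, cost=cost)


def shortest_paths(g: WeightedGraph) -> np.ndarray:
    """All-pairs weighted shortest path lengths over edge lengths 1/w."""
    sparse = csr_matrix(g.lengths())
    d = dijkstra(sparse, directed=False)
    np.fill_diagonal(d, 0.0)
    return d


def char_path_length(d: np.ndarray) -> tuple[float, np.ndarray, float]:
    """Characteristic path length.

    ``L_i`` is the mean finite distance from node *i* to the others
    (unreachable pairs excluded); isolated nodes get ``L_i = nan``.
    Returns (L, per-node L_i, fraction of infinite off-diagonal pairs).
    """
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    counts = finite.sum(axis=1)
    sums = np.where(finite, d, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        per_node = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if not np.any(counts > 0):
        raise ValueError("graph has no finite paths at all")
    L = float(np.nanmean(per_node))
    frac_inf = float((off & ~finite).sum() / off.sum())
    return L, per_node, frac_inf


def weighted_clustering(g: WeightedGraph) -> tuple[float, np.ndarray]:
    """Geometric-mean triangle clustering on max-normalized weights."""
    wn = np.cbrt(g.normalized())
    t = np.diag(wn @ wn @ wn) / 2.0        # weighted triangle intensity
    k = g.degrees
    per_node = np.zeros(g.n)
    mask = k >= 2
    per_node[mask] = 2.0 * t[mask] / (k[mask] * (k[mask] - 1))
    return float(per_node.mean()), per_node


def local_efficiency(g: WeightedGraph) -> tuple[float, np.ndarray]:
    """Weighted local efficiency via neighborhood-restricted shortest paths.

    For node *i* with neighbors N(i) (degree >= 2):

        E_loc(i) = sum_{j != h in N(i)} (w_ij w_ih / d_jh(N_i))^(1/3)
                   / (k_i (k_i - 1))

    with weights max-normalized and ``d_jh(N_i)`` the shortest path
    between j and h inside the subgraph induced by N(i), on lengths 1/w.
    The ordered-pair sum over the pair-count k(k-1) makes a binary clique
    score exactly 1.
    """
    wn = g.normalized()
    per_node = np.zeros(g.n)
    for i in range(g.n):
        nbrs = np.flatnonzero(wn[i] > 0)
        k = len(nbrs)
        if k < 2:
            continue
        sub = wn[np.ix_(nbrs, nbrs)]
        with np.errstate(divide="ignore"):
            sub_len = np.where(sub > 0, 1.0 / sub, 0.0)
        d_sub = dijkstra(csr_matrix(sub_len), directed=False)
        with np.errstate(divide="ignore"):
            inv_d = np.where(np.isfinite(d_sub) & (d_sub > 0), 1.0 / d_sub, 0.0)
        wi = wn[i, nbrs]
        prod = np.cbrt(np.outer(wi, wi) * inv_d)
        np.fill_diagonal(prod, 0.0)
        per_node[i] = prod.sum() / (k * (k - 1))
    return float(per_node.mean()), per_node


def global_efficiency(d: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean inverse shortest path length; unreachable pairs contribute 0."""
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(off & np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    per_node = inv.sum(axis=1) / (n - 1)
    return float(per_node.mean()), per_node


def _rewire(g: WeightedGraph, rng: np.random.Generator,
            swaps_per_edge: int = 10) -> np.ndarray | None:
    """One degree-preserving double-edge-swap realization; weights travel
    with their edges.  Returns None when the graph admits no swaps."""
    iu, ju = np.nonzero(np.triu(g.w, k=1))
    weights = g.w[iu, ju]
    edges = [(int(a), int(b)) for a, b in zip(iu, ju)]
    m = len(edges)
    if m < 2:
        return None
    present = set(edges)
    target = swaps_per_edge * m
    max_attempts = 20 * target
    accepted = attempts = 0
    while accepted < target and attempts < max_attempts:
        attempts += 1
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, dd = edges[e2]
        if rng.integers(0, 2):
            c, dd = dd, c
        # proposed: (a, c) and (b, dd)
        if len({a, b, c, dd}) < 4:
            continue
        n1 = (min(a, c), max(a, c))
        n2 = (min(b, dd), max(b, dd))
        if n1 in present or n2 in present:
            continue
        present.discard(edges[e1])
        present.discard(edges[e2])
        present.add(n1)
        present.add(n2)
        edges[e1] = n1
        edges[e2] = n2
        accepted += 1
    if accepted == 0:
        return None
    adj = np.zeros_like(g.w)
    for (a, b), w in zip(edges, weights):
        adj[a, b] = w
        adj[b, a] = w
    return adj


def random_ensemble(g: WeightedGraph, n_rand: int = 100,
                    rng: np.random.Generator | None = None,
                    swaps_per_edge: int = 10
                    ) -> tuple[float, float, bool]:
    """Ensemble means (L_rand, C_rand) of rewired degree-matched nulls.

    Falls back to the graph's own metrics (flagged) when the topology
    admits no swaps (clique or near-clique).
    """
    if g.n_edges < 2:
        raise ValueError("need at least 2 edges for a null ensemble")
    rng = rng or np.random.default_rng()
    l_vals, c_vals = [], []
    degenerate = False
    for _ in range(n_rand):
        adj = _rewire(g, rng, swaps_per_edge)
        if adj is None:
            degenerate = True
            adj = g.w
        null = WeightedGraph(w=adj, cost=g.cost)
        d = shortest_paths(null)
        L, _, _ = char_path_length(d)
        C, _ = weighted_clustering(null)
        l_vals.append(L)
        c_vals.append(C)
    return float(np.mean(l_vals)), float(np.mean(c_vals)), degenerate


def normalized_metrics(L: float, C: float, l_rand: float, c_rand: float
                       ) -> tuple[float, float, float]:
    """lambda = L/L_rand, gamma = C/C_rand, SW = gamma/lambda."""
    if l_rand == 0 or c_rand == 0:
        raise ValueError("degenerate null ensemble (zero reference metric)")
    lam = L / l_rand
    gamma = C / c_rand
    return lam, gamma, gamma / lam


def compute_metrics(g: WeightedGraph, n_rand: int = 100,
                    rng: np.random.Generator | None = None,
                    swaps_per_edge: int = 10) -> GraphMetricsResult:
    """The full metric set for one thresholded graph."""
    d = shortest_paths(g)
    L, per_L, frac_inf = char_path_length(d)
    C, per_C = weighted_clustering(g)
    e_loc, per_eloc = local_efficiency(g)
    e_glob, per_eglob = global_efficiency(d)
    l_rand, c_rand, degenerate = random_ensemble(g, n_rand, rng, swaps_per_edge)
    lam, gamma, sw = normalized_metrics(L, C, l_rand, c_rand)
    return GraphMetricsResult(
        L=L, lam=lam, C=C, gamma=gamma, e_loc=e_loc, e_glob=e_glob, sw=sw,
        l_rand=l_rand, c_rand=c_rand, disconnected_pair_fraction=frac_inf,
        per_node_L=per_L, per_node_C=per_C, per_node_eloc=per_eloc,
        per_node_eglob=per_eglob, degenerate_null=degenerate)


def disconnected_fraction(g: WeightedGraph) -> float:
    """Fraction of nodes outside the largest connected component."""
    n_comp, labels = connected_components(csr_matrix(g.w), directed=False)
    if n_comp == 1:
        return 0.0
    largest = np.bincount(labels).max()
    return 1.0 - largest / g.n


def feasible_cost_range(fcs: list[FCMatrix], step: float = 0.005,
                        n_rand: int = 20,
                        rng: np.random.Generator | None = None,
                        swaps_per_edge: int = 10,
                        max_cost: float = 0.5,
                        disconnect_tol: float = 0.10,
                        subject_tol: float = 0.95
                        ) -> tuple[float, float] | None:
    """Scan the cost grid for the maximal contiguous admissible range.

    Criteria at each grid cost: (1) at most ``disconnect_tol`` of nodes
    disconnected from the giant component in at least ``subject_tol`` of
    subjects; (2) mean degree above ln(n); (3) subject-mean small-
    worldness above 1.  Returns None when no cost qualifies.
    """
    if len(fcs) < 2:
        raise ValueError("need at least 2 subjects for a group-level range")
    rng = rng or np.random.default_rng()
    n = fcs[0].n
    grid = np.round(np.arange(step, max_cost + step / 2, step), 10)
    ok = []
    for cost in grid:
        m = round(cost * n * (n - 1) / 2)
        if m < 1 or 2 * m / n <= np.log(n):
            ok.append(False)
            continue
        try:
            graphs = [cost_threshold(fc, cost) for fc in fcs]
        except ValueError:
            ok.append(False)
            continue
        frac_ok = np.mean([disconnected_fraction(g) <= disconnect_tol
                           for g in graphs])
        if frac_ok < subject_tol:
            ok.append(False)
            continue
        sws = []
        for g in graphs:
            d = shortest_paths(g)
            L, _, _ = char_path_length(d)
            C, _ = weighted_clustering(g)
            l_rand, c_rand, _ = random_ensemble(g, n_rand, rng, swaps_per_edge)
            _, _, sw = normalized_metrics(L, C, l_rand, c_rand)
            sws.append(sw)
        ok.append(float(np.mean(sws)) > 1.0)
    ok = np.asarray(ok)
    if not ok.any():
        return None
    # maximal contiguous run of admissible costs
    best_len, best_start = 0, 0
    run_len, run_start = 0, 0
    for idx, flag in enumerate(ok):
        if flag:
            if run_len == 0:
                run_start = idx
            run_len += 1
            if run_len > best_len:
                best_len, best_start = run_len, run_start
        else:
            run_len = 0
    return (float(grid[best_start]), float(grid[best_start + best_len - 1]))


def metrics_over_costs(fc: FCMatrix, costs: list[float] | np.ndarray,
                       n_rand: int = 100,
                       rng: np.random.Generator | None = None,
                       swaps_per_edge: int = 10) -> GraphMetricsResult:
    """Metrics averaged across a cost grid (area-under-curve convention)."""
    costs = list(costs)
    if not costs:
        raise ValueError("empty cost range")
    rng = rng or np.random.default_rng()
    results = [compute_metrics(cost_threshold(fc, c), n_rand, rng,
                               swaps_per_edge) for c in costs]
    if len(results) == 1:
        return results[0]

    def m(attr):
        return float(np.mean([getattr(r, attr) for r in results]))

    def mv(attr):
        return np.nanmean([getattr(r, attr) for r in results], axis=0)

    return GraphMetricsResult(
        L=m("L"), lam=m("lam"), C=m("C"), gamma=m("gamma"),
        e_loc=m("e_loc"), e_glob=m("e_glob"), sw=m("sw"),
        l_rand=m("l_rand"), c_rand=m("c_rand"),
        disconnected_pair_fraction=m("disconnected_pair_fraction"),
        per_node_L=mv("per_node_L"), per_node_C=mv("per_node_C"),
        per_node_eloc=mv("per_node_eloc"), per_node_eglob=mv("per_node_eglob"),
        degenerate_null=any(r.degenerate_null for r in results))
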
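"""Permutation and exact tests.

``mantel_screen`` asks, per group-day, whether the observed distribution of
play looks like the equal-play expectation.  The observed count matrix and a
hypothetical matrix that spreads each animal's attacks evenly over its
partners (preserving row totals) are both reduced to dyadic dissimilarities;
their Pearson correlation is assessed by jointly permuting the row/column
labels of the observed matrix.  A *significant* correlation means play was
distributed as evenly as the hypothetical matrix predicts — i.e. no partner
preferences — and the group-day is excluded from preference analyses.

``modularity_significance`` tests sub-group structure of the undirected play
network by permuting edge weights across the fixed set of dyads, and
``sign_test_exact`` is the exact two-sided binomial sign test used for the
availability correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .events import CountMatrix

DEFAULT_N_PERM = 9999
ALPHA = 0.05


class DegenerateMatrixError(ValueError):
    """Raised when a dissimilarity vector has zero variance, so a Mantel
    correlation is undefined (e.g. all animals initiated identical totals)."""


@dataclass(frozen=True)
class MantelResult:
    """Mantel screen outcome for one group-day.

    ``excluded`` is true when ``p < alpha``: the observed matrix correlates
    with the equal-play expectation, so play looks random and the day is
    dropped from preference analyses.
    """

    group_id: int
    day: int
    r: float
    p: float
    n_perm: int
    seed: int | None
    excluded: bool


@dataclass(frozen=True)
class ModularityResult:
    group_id: int
    day: int
    q: float
    communities: tuple[frozenset, ...]
    p: float
    n_perm: int
    seed: int | None

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


@dataclass(frozen=True)
class SignTestResult:
    n_success: int
    n_trials: int
    p_two_sided: float


def _dyadic_dissimilarity(matrix: np.ndarray) -> np.ndarray:
    """Symmetric dyadic dissimilarity of a directed matrix.

    The two directions of each dyad are averaged into a closeness score and
    subtracted from the maximum so that much-playing dyads are 'close'.
    Diagonal is zero.
    """
    m = np.asarray(matrix, dtype=float)
    sym = (m + m.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    d = sym.max() - sym
    np.fill_diagonal(d, 0.0)
    return d


def _upper(vec_matrix: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(vec_matrix.shape[0], k=1)
    return vec_matrix[iu]


def mantel_screen(counts: CountMatrix, n_perm: int = DEFAULT_N_PERM,
                  seed: int | None = None, alpha: float = ALPHA
                  ) -> MantelResult:
    """Screen one group-day's count matrix against the equal-play expectation.

    The observed side is the *proportion* matrix (each animal's attacks
    divided by its total), removing between-animal variation in play output;
    the hypothetical side spreads each animal's observed total evenly,
    ``H_ij = B_i / (k - 1)`` off-diagonal, which preserves row totals and so
    keeps the hypothetical dissimilarities non-constant.  Both matrices
    become dyadic dissimilarities; ``r`` is the Pearson correlation of
    their upper triangles and ``p`` the one-sided add-one permutation
    p-value under joint row/column label permutation of the observed matrix
    (so ``p >= 1 / (n_perm + 1)`` always).

    Raises :class:`DegenerateMatrixError` when either dissimilarity vector
    is constant (zero variance), rather than returning a silent NaN.
    """
    from .events import to_proportions

    k = counts.k
    totals = counts.row_totals.astype(float)
    H = np.repeat(totals[:, None] / (k - 1), k, axis=1)
    np.fill_diagonal(H, 0.0)

    d_real = _dyadic_dissimilarity(to_proportions(counts).proportions)
    d_hyp = _dyadic_dissimilarity(H)
    v_real, v_hyp = _upper(d_real), _upper(d_hyp)
    if np.std(v_real) == 0 or np.std(v_hyp) == 0:
        raise DegenerateMatrixError(
            f"group {counts.group_id} day {counts.day}: constant "
            "dissimilarities, Mantel correlation undefined")

    r = float(np.corrcoef(v_real, v_hyp)[0, 1])

    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(k, k=1)
    perms = np.array([rng.permutation(k) for _ in range(n_perm)])
    # permuted upper-triangle vectors of the observed dissimilarity matrix
    permuted = d_real[perms[:, iu], perms[:, ju]]  # (n_perm, n_dyads)
    pm = permuted - permuted.mean(axis=1, keepdims=True)
    hv = v_hyp - v_hyp.mean()
    denom = np.sqrt((pm ** 2).sum(axis=1)) * np.sqrt((hv ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r_null = (pm @ hv) / denom
    r_null = np.nan_to_num(r_null, nan=-np.inf)  # constant permuted vector
    p = (int(np.sum(r_null >= r)) + 1) / (n_perm + 1)
    return MantelResult(group_id=counts.group_id, day=counts.day, r=r,
                        p=p, n_perm=n_perm, seed=seed,
                        excluded=bool(p < alpha))


# ---------------------------------------------------------------------------
# modularity significance


def _greedy_q(graph: nx.Graph) -> tuple[float, tuple[frozenset, ...]]:
    if graph.number_of_edges() == 0:
        return 0.0, tuple(frozenset([n]) for n in graph.nodes)
    comms = nx.community.greedy_modularity_communities(graph, weight="weight")
    q = nx.community.modularity(graph, comms, weight="weight")
    return float(q), tuple(frozenset(c) for c in comms)


def modularity_significance(graph: nx.Graph, n_perm: int = 999,
                            seed: int | None = None, group_id: int = 0,
                            day: int = 0) -> ModularityResult:
    """Weighted-modularity community detection with permutation significance.

    Communities come from greedy (CNM) weighted modularity maximisation.
    The null shuffles the observed edge weights across the fixed set of all
    node pairs (absent edges count as weight 0) and recomputes the maximised
    modularity; ``p`` is add-one corrected.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    q, comms = _greedy_q(graph)

    nodes = sorted(graph.nodes)
    pairs = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]]
    weights = np.array([graph[a][b]["weight"] if graph.has_edge(a, b) else 0.0
                        for a, b in pairs])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        w = rng.permutation(weights)
        g_null = nx.Graph()
        g_null.add_nodes_from(nodes)
        for (a, b), wt in zip(pairs, w):
            if wt > 0:
                g_null.add_edge(a, b, weight=wt)
        q_null, _ = _greedy_q(g_null)
        if q_null >= q:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return ModularityResult(group_id=group_id, day=day, q=q,
                            communities=comms, p=p, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# exact sign test


def sign_test_exact(n_success: int, n_trials: int) -> SignTestResult:
    """Exact two-sided binomial sign test at success probability 1/2.

    ``p = min(1, 2 * min{P(X <= s), P(X >= s)})`` with
    ``X ~ Binomial(n, 1/2)`` summed exactly.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if not 0 <= n_success <= n_trials:
        raise ValueError(f"n_success {n_success} outside 0..{n_trials}")
    lower = float(stats.binom.cdf(n_success, n_trials, 0.5))
    upper = float(stats.binom.sf(n_success - 1, n_trials, 0.5))
    p = min(1.0, 2.0 * min(lower, upper))
    return SignTestResult(n_success=n_success, n_trials=n_trials,
                          p_two_sided=p)
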
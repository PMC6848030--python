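"""Spearman-rank resemblance, average-linkage clustering, SIMPROF, and
query-correlation analysis of abundance matrices.

The resemblance between two abundance profiles is the Spearman rank
correlation (mid-ranks for ties), turned into a dissimilarity as
d = 1 - rho, bounded in [0, 2].  Only the ordering of d matters to the
linkage, so this choice is equivalent to any affine rescaling.

Average linkage (UPGMA) is implemented here rather than delegated so that
tie-breaking is fully specified: equal-height candidate merges are
resolved in favour of the pair with the lowest original indices, making
dendrograms reproducible across platforms.  Agreement with SciPy's
implementation is checked in the test suite, not assumed.

SIMPROF (similarity profile analysis) tests each dendrogram node for
internal structure: the observed sorted profile of pairwise similarities
among member samples is compared to a mean profile from permutations
that shuffle every feature's values independently across those samples;
the departure statistic is pi = sum_i |s_(i) - sbar_(i)| and its p-value
comes from a second, independent set of permutations.  Recursion descends
only into nodes with significant structure, and the leaves of the
recursion define the significant sample groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .errors import ValidationError
from .profiling import AbundanceMatrix

DEFAULT_ALPHA = 0.05
DEFAULT_N_PERM_MEAN = 1000
DEFAULT_N_PERM_TEST = 999


# ---------------------------------------------------------------------------
# resemblance


@dataclass
class ResemblanceMatrix:
    """Symmetric Spearman correlation matrix with derived distances."""

    ids: list[str]
    rho: np.ndarray
    #: ids dropped because their profile was constant (rho undefined)
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.rho.shape != (n, n):
            raise ValidationError("rho must be square over ids")
        if not np.allclose(self.rho, self.rho.T, atol=1e-12):
            raise ValidationError("rho must be symmetric")
        np.fill_diagonal(self.rho, 1.0)

    @property
    def distance(self) -> np.ndarray:
        d = 1.0 - self.rho
        np.fill_diagonal(d, 0.0)
        return d


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=1)


def spearman_matrix(m: AbundanceMatrix, axis: str = "samples"
                    ) -> ResemblanceMatrix:
    """All-pairs Spearman correlation of feature rows or sample columns.

    Vectors that are constant (or contain missing values) have no defined
    rank correlation; they are excluded and reported on the result.
    """
    if axis not in ("features", "samples"):
        raise ValidationError(f"axis must be 'features' or 'samples', got {axis!r}")
    df = m.values if axis == "features" else m.values.T
    ids = [str(i) for i in df.index]
    x = df.to_numpy(dtype=float)
    if x.shape[0] < 3:
        raise ValidationError("need at least 3 vectors for a resemblance matrix")
    ok = np.isfinite(x).all(axis=1) & (np.ptp(x, axis=1) > 0)
    excluded = [ids[i] for i in np.flatnonzero(~ok)]
    if len(excluded) == len(ids):
        raise ValidationError("all vectors are constant or incomplete")
    kept = [ids[i] for i in np.flatnonzero(ok)]
    ranks = _rank_rows(x[ok])
    rho = np.corrcoef(ranks)
    rho = np.clip(rho, -1.0, 1.0)
    return ResemblanceMatrix(ids=kept, rho=rho, excluded=excluded)


# ---------------------------------------------------------------------------
# average linkage (UPGMA)


@dataclass
class Dendrogram:
    """Merge tree over ``leaves`` in SciPy node-id convention.

    Leaf i has node id i; the t-th merge creates node ``n_leaves + t``.
    Each merge is (left id, right id, height, member count).
    """

    leaves: list[str]
    merges: list[tuple[int, int, float, int]]

    def to_linkage(self) -> np.ndarray:
        return np.array([[a, b, h, c] for a, b, h, c in self.merges], dtype=float)

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.to_linkage())
        return [self.leaves[i] for i in order]

    def cut(self, k: int) -> dict[str, int]:
        """Partition the leaves into ``k`` groups by merge height."""
        labels = hierarchy.fcluster(self.to_linkage(), t=k, criterion="maxclust")
        return {leaf: int(lbl) for leaf, lbl in zip(self.leaves, labels)}

    def cophenetic(self) -> np.ndarray:
        from scipy.spatial.distance import squareform
        return squareform(hierarchy.cophenet(self.to_linkage()))

    def node_members(self, node_id: int) -> list[int]:
        """Leaf indices under ``node_id`` (a leaf id or merge id)."""
        n = len(self.leaves)
        if node_id < n:
            return [node_id]
        a, b, _, _ = self.merges[node_id - n]
        return self.node_members(a) + self.node_members(b)

    def to_newick(self) -> str:
        """Newick string with cophenetic branch lengths."""
        n = len(self.leaves)
        heights = {i: 0.0 for i in range(n)}
        for t, (_, _, h, _) in enumerate(self.merges):
            heights[n + t] = h

        def label(i: int) -> str:
            safe = "".join(c if c not in "(),:;'\"[] \t\n" else "_"
                           for c in self.leaves[i])
            return safe

        def render(node: int, parent_h: float) -> str:
            length = parent_h - heights[node]
            if node < n:
                return f"{label(node)}:{length:.6g}"
            a, b, h, _ = self.merges[node - n]
            return f"({render(a, h)},{render(b, h)}):{length:.6g}"

        root = n + len(self.merges) - 1
        a, b, h, _ = self.merges[-1]
        return f"({render(a, h)},{render(b, h)});"


def average_linkage(rm: ResemblanceMatrix) -> Dendrogram:
    """UPGMA on ``d = 1 - rho`` with deterministic tie-breaking.

    The inter-cluster distance is the arithmetic mean of all cross-pair
    leaf distances (maintained exactly by the Lance-Williams update).
    When several candidate merges share the minimal height, the pair with
    the lowest original indices merges first.
    """
    n = len(rm.ids)
    if n < 2:
        raise ValidationError("need at least 2 items to cluster")
    d = rm.distance.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    active = np.ones(n, dtype=bool)
    node_id = list(range(n))
    size = np.ones(n)
    merges: list[tuple[int, int, float, int]] = []
    for t in range(n - 1):
        masked = np.where(np.outer(active, active), d, np.inf)
        # row-major argmin: first occurrence = lowest (i, j) index pair
        i, j = np.unravel_index(np.argmin(masked), masked.shape)
        if i > j:
            i, j = j, i
        h = float(d[i, j])
        merges.append((node_id[i], node_id[j], h, int(size[i] + size[j])))
        # Lance-Williams UPGMA update into slot i; slot j retires
        others = active.copy()
        others[[i, j]] = False
        new = (size[i] * d[i, others] + size[j] * d[j, others]) / (size[i] + size[j])
        d[i, others] = new
        d[others, i] = new
        size[i] += size[j]
        active[j] = False
        node_id[i] = n + t
    return Dendrogram(leaves=list(rm.ids), merges=merges)


def cluster_2d(m: AbundanceMatrix
               ) -> tuple[Dendrogram, Dendrogram, AbundanceMatrix]:
    """Independent feature- and sample-axis clustering plus reordering.

    Returns the feature (row) dendrogram, the sample (column) dendrogram,
    and the matrix reordered to dendrogram leaf order.  Constant profiles
    have undefined rank correlations and are omitted from the reordered
    matrix (they are listed in its provenance).
    """
    row_rm = spearman_matrix(m, axis="features")
    col_rm = spearman_matrix(m, axis="samples")
    row_dg = average_linkage(row_rm)
    col_dg = average_linkage(col_rm)
    reordered = m.values.loc[row_dg.leaf_order(), col_dg.leaf_order()]
    prov = list(m.provenance) + ["reordered by 2D Spearman/UPGMA clustering"]
    for side, rm in (("feature", row_rm), ("sample", col_rm)):
        if rm.excluded:
            prov.append(f"excluded constant {side} profiles: {rm.excluded}")
    return row_dg, col_dg, AbundanceMatrix(values=reordered, mode=m.mode,
                                           provenance=prov)


# ---------------------------------------------------------------------------
# SIMPROF


@dataclass(frozen=True)
class SimprofNodeResult:
    node_id: int
    members: tuple[str, ...]
    pi: float
    p_value: float
    significant: bool


@dataclass
class SimprofResult:
    """Tested nodes and the resulting significant sample groups."""

    tested: list[SimprofNodeResult]
    groups: list[tuple[str, ...]]
    alpha: float
    n_perm_mean: int
    n_perm_test: int
    seed: int

    @property
    def root_p(self) -> float | None:
        return self.tested[0].p_value if self.tested else None


def _similarity_profile(sub: np.ndarray) -> np.ndarray:
    """Sorted pairwise Spearman similarities among the columns of ``sub``."""
    ranks = stats.rankdata(sub, axis=0)
    rho = np.corrcoef(ranks, rowvar=False)
    iu = np.triu_indices(rho.shape[1], k=1)
    return np.sort(rho[iu])


def _simprof_node(sub: np.ndarray, rng: np.random.Generator,
                  n_perm_mean: int, n_perm_test: int) -> tuple[float, float]:
    """Return (pi, p) for one node's member-sample submatrix."""
    observed = _similarity_profile(sub)
    mean_prof = np.zeros_like(observed)
    for _ in range(n_perm_mean):
        mean_prof += _similarity_profile(rng.permuted(sub, axis=1))
    mean_prof /= n_perm_mean
    pi_obs = float(np.abs(observed - mean_prof).sum())
    n_ge = 0
    for _ in range(n_perm_test):
        pi_b = np.abs(_similarity_profile(rng.permuted(sub, axis=1))
                      - mean_prof).sum()
        if pi_b >= pi_obs:
            n_ge += 1
    p = (n_ge + 1) / (n_perm_test + 1)
    return pi_obs, p


def simprof(m: AbundanceMatrix, alpha: float = DEFAULT_ALPHA,
            n_perm_mean: int = DEFAULT_N_PERM_MEAN,
            n_perm_test: int = DEFAULT_N_PERM_TEST,
            seed: int = 0) -> SimprofResult:
    """Similarity-profile test of sample-group structure.

    Clusters the samples (columns) by Spearman/UPGMA, then walks the
    dendrogram from the root: each node of >= 3 samples is tested for
    internal structure; recursion continues into the children of
    significant nodes, and every node where recursion stops contributes
    its member samples as one final group.  All randomness flows from
    ``seed``; rerunning with the same inputs reproduces the result.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    if len(m.sample_ids) < 3:
        raise ValidationError("SIMPROF requires at least 3 samples")
    x = m.values.to_numpy(dtype=float)
    rm = spearman_matrix(m, axis="samples")
    if rm.excluded:
        raise ValidationError(
            f"constant sample profiles cannot be tested: {rm.excluded}")
    dendro = average_linkage(rm)
    sample_ids = dendro.leaves
    col_of = {sid: m.sample_ids.index(sid) for sid in sample_ids}
    rng = np.random.default_rng(seed)
    n = len(sample_ids)
    root = n + len(dendro.merges) - 1
    tested: list[SimprofNodeResult] = []
    groups: list[tuple[str, ...]] = []

    def visit(node_id: int) -> None:
        members = dendro.node_members(node_id)
        ids = tuple(sample_ids[i] for i in members)
        if len(members) < 3:
            groups.append(ids)
            return
        sub = x[:, [col_of[s] for s in ids]]
        pi, p = _simprof_node(sub, rng, n_perm_mean, n_perm_test)
        significant = p <= alpha
        tested.append(SimprofNodeResult(node_id=node_id, members=ids,
                                        pi=pi, p_value=p,
                                        significant=significant))
        if significant and node_id >= n:
            a, b, _, _ = dendro.merges[node_id - n]
            visit(a)
            visit(b)
        else:
            groups.append(ids)

    visit(root)
    return SimprofResult(tested=tested, groups=groups, alpha=alpha,
                         n_perm_mean=n_perm_mean, n_perm_test=n_perm_test,
                         seed=seed)


# ---------------------------------------------------------------------------
# query correlation


@dataclass
class CorrelationQueryResult:
    """Spearman correlation of one query feature against all features."""

    query: str
    n: int
    p_threshold: float
    #: indexed by feature id with columns rho, p_value, flagged
    stats: pd.DataFrame


def _spearman_p_t(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t-approximation with n - 2 df."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)


def query_correlation(m: AbundanceMatrix, query: str,
                      p_threshold: float = 0.05, method: str = "t",
                      bh: bool = False, n_mc: int = 10_000,
                      seed: int = 0) -> CorrelationQueryResult:
    """Correlate a query feature's abundance profile against all features.

    ``method="t"`` uses the two-sided t-approximation with n - 2 degrees
    of freedom; ``method="permutation"`` uses a seeded Monte-Carlo
    permutation test (``n_mc`` shuffles of the query ranks) suitable for
    the small sample counts typical here.  p-values are raw by default;
    set ``bh=True`` for Benjamini-Hochberg adjusted flags.
    """
    if query not in m.values.index:
        raise KeyError(f"query feature {query!r} not in matrix")
    if method not in ("t", "permutation"):
        raise ValidationError(f"unknown method {method!r}")
    x = m.values.to_numpy(dtype=float)
    n = x.shape[1]
    if n < 5:
        raise ValidationError("need at least 5 samples for p-values")
    ranks = _rank_rows(x)
    q = ranks[list(m.values.index).index(query)]
    qc = q - q.mean()
    qn = np.sqrt((qc ** 2).sum())
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    rn = np.sqrt((rc ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rc @ qc) / (rn * qn)
    rho = np.clip(rho, -1.0, 1.0)
    if method == "t":
        p = _spearman_p_t(rho, n)
    else:
        rng = np.random.default_rng(seed)
        exceed = np.zeros_like(rho)
        abs_obs = np.abs(rho)
        for _ in range(n_mc):
            qp = rng.permutation(qc)
            rho_b = (rc @ qp) / (rn * qn)
            exceed += np.abs(rho_b) >= abs_obs - 1e-12
        p = (exceed + 1.0) / (n_mc + 1.0)
    p = np.where(np.isfinite(rho), p, np.nan)
    if bh:
        flagged = _benjamini_hochberg(p) <= p_threshold
    else:
        flagged = p <= p_threshold
    frame = pd.DataFrame({"rho": rho, "p_value": p,
                          "flagged": flagged & np.isfinite(rho)},
                         index=m.values.index)
    return CorrelationQueryResult(query=query, n=n, p_threshold=p_threshold,
                                  stats=frame)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH adjusted p-values (NaNs passed through)."""
    p = np.asarray(p, dtype=float)
    adj = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    adj[ok] = stats.false_discovery_control(p[ok], method="bh")
    return adj
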
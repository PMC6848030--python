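"""Resemblance, UPGMA, SIMPROF and query-correlation statistics.

Brute-force oracles: Spearman rho is recomputed as Pearson correlation of
hand-assigned mid-ranks; UPGMA is recomputed by exhaustively re-averaging
all cross-pair leaf distances at every merge instead of using the
Lance-Williams update the implementation relies on.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sedprof.cluster import (
    ResemblanceMatrix,
    average_linkage,
    cluster_2d,
    query_correlation,
    simprof,
    spearman_matrix,
)
from sedprof.errors import ValidationError
from sedprof.profiling import AbundanceMatrix
from sedprof.simulate import simulate_null_table


def matrix_from(values, mode="genes_per_genome", features=None, samples=None):
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(values,
                      index=features or [f"F{i}" for i in range(values.shape[0])],
                      columns=samples or [f"S{j}" for j in range(values.shape[1])])
    return AbundanceMatrix(values=df, mode=mode)


# -- oracles -----------------------------------------------------------------


def midranks(x):
    """Mid-rank assignment by definition: average position of tied values."""
    x = np.asarray(x, dtype=float)
    out = np.empty(len(x))
    for i, v in enumerate(x):
        less = np.sum(x < v)
        ties = np.sum(x == v)
        out[i] = less + (ties + 1) / 2.0
    return out


def spearman_oracle(x, y):
    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def upgma_oracle(d):
    """Exhaustive UPGMA: recompute every cross-pair mean at every step."""
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    node_id = {i: i for i in range(n)}
    merges = []
    for t in range(n - 1):
        best = None
        keys = sorted(clusters, key=lambda c: min(clusters[c]))
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                h = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or h < best[0] - 1e-15:
                    best = (h, a, b)
        h, a, b = best
        merges.append((node_id[a], node_id[b], h,
                       len(clusters[a]) + len(clusters[b])))
        clusters[a] = clusters[a] + clusters[b]
        node_id[a] = n + t
        del clusters[b], node_id[b]
    return merges


# -- spearman ----------------------------------------------------------------


class TestSpearmanMatrix:
    def test_monotone_and_reversed(self):
        m = matrix_from([[1, 2, 3], [10, 20, 30], [3, 2, 1]])
        rm = spearman_matrix(m, axis="features")
        assert rm.rho[0, 1] == pytest.approx(1.0)
        assert rm.rho[0, 2] == pytest.approx(-1.0)
        assert np.allclose(np.diag(rm.rho), 1.0)

    def test_ties_match_midrank_oracle(self):
        x, y = [1, 2, 2, 4], [1, 3, 2, 4]
        m = matrix_from([x, y, [4, 1, 3, 2]])
        rm = spearman_matrix(m, axis="features")
        assert rm.rho[0, 1] == pytest.approx(spearman_oracle(x, y))

    def test_random_instances_match_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = rng.integers(4, 13)
            x = np.round(rng.lognormal(size=(3, n)), 1)  # rounding induces ties
            rm = spearman_matrix(matrix_from(x), axis="features")
            expected = stats.spearmanr(x[0], x[1]).statistic
            assert rm.rho[0, 1] == pytest.approx(expected)
            assert rm.rho[0, 1] == pytest.approx(spearman_oracle(x[0], x[1]))

    def test_constant_vector_excluded(self):
        m = matrix_from([[1, 2, 3], [5, 5, 5], [3, 1, 2]])
        rm = spearman_matrix(m, axis="features")
        assert rm.excluded == ["F1"]
        assert rm.ids == ["F0", "F2"]

    def test_distance_is_one_minus_rho(self):
        m = matrix_from(np.random.default_rng(2).lognormal(size=(4, 6)))
        rm = spearman_matrix(m, axis="features")
        assert np.allclose(rm.distance, 1 - rm.rho)
        assert np.allclose(np.diag(rm.distance), 0.0)


# -- UPGMA -------------------------------------------------------------------


def rm_from_distance(d):
    return ResemblanceMatrix(ids=[f"L{i}" for i in range(d.shape[0])],
                             rho=1.0 - d)


class TestAverageLinkage:
    def test_three_point_hand_example(self):
        d = np.array([[0.0, 0.1, 0.5], [0.1, 0.0, 0.7], [0.5, 0.7, 0.0]])
        dg = average_linkage(rm_from_distance(d))
        (a, b, h1, c1), (x, y, h2, c2) = dg.merges
        assert (a, b, h1, c1) == (0, 1, pytest.approx(0.1), 2)
        assert h2 == pytest.approx((0.5 + 0.7) / 2)
        assert c2 == 3

    def test_equidistant_ties_broken_by_lowest_index(self):
        d = np.full((4, 4), 0.3)
        np.fill_diagonal(d, 0.0)
        dg = average_linkage(rm_from_distance(d))
        assert dg.merges[0][:2] == (0, 1)
        assert all(h == pytest.approx(0.3) for _, _, h, _ in dg.merges)

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(3, 9))
            x = rng.normal(size=(n, n))
            d = np.abs(x - x.T)
            np.fill_diagonal(d, 0.0)
            dg = average_linkage(rm_from_distance(d))
            expected = upgma_oracle(d)
            for got, exp in zip(dg.merges, expected):
                assert got[3] == exp[3]
                assert got[2] == pytest.approx(exp[2])

    def test_cophenetic_matches_scipy_linkage(self):
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import squareform
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            d = np.abs(rng.normal(size=(n, n)))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            ours = average_linkage(rm_from_distance(d)).cophenetic()
            z = hierarchy.linkage(squareform(d), method="average")
            theirs = squareform(hierarchy.cophenet(z))
            assert np.allclose(ours, theirs)

    def test_ultrametric_three_point_condition(self):
        rng = np.random.default_rng(10)
        d = np.abs(rng.normal(size=(7, 7)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        c = average_linkage(rm_from_distance(d)).cophenetic()
        n = c.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert c[i, j] <= max(c[i, k], c[j, k]) + 1e-12

    def test_single_item_rejected(self):
        with pytest.raises(ValidationError):
            average_linkage(ResemblanceMatrix(ids=["a"], rho=np.ones((1, 1))))

    def test_newick_tip_distances_match_cophenetic(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(12)
        d = np.abs(rng.normal(size=(6, 6)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        dg = average_linkage(rm_from_distance(d))
        tree = dendropy.Tree.get(data=dg.to_newick(), schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        coph = dg.cophenetic()
        taxa = {t.label: i for i, t in enumerate(tree.taxon_namespace)}
        for la, ia in taxa.items():
            for lb, ib in taxa.items():
                if la >= lb:
                    continue
                got = pdm.distance(tree.taxon_namespace[ia],
                                   tree.taxon_namespace[ib])
                i, j = int(la[1:]), int(lb[1:])
                # tip-to-tip path length is twice the merge height
                assert got == pytest.approx(2 * coph[i, j], abs=1e-4)


# -- 2D clustering -----------------------------------------------------------


class TestCluster2d:
    def test_sample_order_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.lognormal(size=(20, 6))
        m = matrix_from(x)
        perm = [3, 0, 5, 1, 4, 2]
        m_perm = AbundanceMatrix(values=m.values.iloc[:, perm], mode=m.mode)
        _, cols1, _ = cluster_2d(m)
        _, cols2, _ = cluster_2d(m_perm)

        def partition(labels):
            groups = {}
            for sid, lbl in labels.items():
                groups.setdefault(lbl, set()).add(sid)
            return {frozenset(g) for g in groups.values()}

        assert partition(cols1.cut(3)) == partition(cols2.cut(3))

    def test_duplicate_sample_merges_at_zero(self):
        rng = np.random.default_rng(7)
        x = rng.lognormal(size=(15, 4))
        x = np.c_[x, x[:, 0]]  # S4 duplicates S0
        _, cols, _ = cluster_2d(matrix_from(x))
        first = cols.merges[0]
        assert first[2] == pytest.approx(0.0)
        assert {cols.leaves[first[0]], cols.leaves[first[1]]} == {"S0", "S4"}

    def test_reordered_matrix_preserves_values(self):
        rng = np.random.default_rng(8)
        m = matrix_from(rng.lognormal(size=(10, 5)))
        rows, cols, reordered = cluster_2d(m)
        assert sorted(reordered.values.index) == sorted(m.values.index)
        original = m.values.loc[reordered.values.index,
                                reordered.values.columns]
        pd.testing.assert_frame_equal(reordered.values, original)

    def test_monotone_transform_of_one_sample_is_neutral(self):
        rng = np.random.default_rng(13)
        x = rng.lognormal(size=(25, 6))
        m1 = matrix_from(x)
        x2 = x.copy()
        x2[:, 2] = np.exp(x2[:, 2] * 3.0) + 5.0  # strictly increasing
        m2 = matrix_from(x2)
        rm1 = spearman_matrix(m1, axis="samples")
        rm2 = spearman_matrix(m2, axis="samples")
        assert np.allclose(rm1.rho, rm2.rho)
        assert average_linkage(rm1).merges == average_linkage(rm2).merges


# -- SIMPROF -----------------------------------------------------------------


class TestSimprof:
    def test_deterministic_under_fixed_seed(self):
        m = simulate_null_table(8, 40, seed=21)
        r1 = simprof(m, n_perm_mean=100, n_perm_test=99, seed=5)
        r2 = simprof(m, n_perm_mean=100, n_perm_test=99, seed=5)
        assert r1.groups == r2.groups
        assert [(t.pi, t.p_value) for t in r1.tested] == \
            [(t.pi, t.p_value) for t in r2.tested]

    def test_two_separated_blocks_recovered(self):
        rng = np.random.default_rng(5)
        rows = [np.r_[rng.lognormal(1, 0.2, 6), rng.lognormal(0, 0.2, 5)]
                for _ in range(80)]
        rows += [np.r_[rng.lognormal(0, 0.2, 6), rng.lognormal(1, 0.2, 5)]
                 for _ in range(80)]
        res = simprof(matrix_from(rows), seed=3)
        assert res.root_p <= 0.005
        assert sorted(len(g) for g in res.groups) == [5, 6]
        left = {f"S{j}" for j in range(6)}
        assert {frozenset(g) for g in res.groups} == \
            {frozenset(left), frozenset(f"S{j}" for j in range(6, 11))}

    def test_groups_partition_the_samples(self):
        m = simulate_null_table(9, 30, seed=33)
        res = simprof(m, n_perm_mean=100, n_perm_test=99, seed=1)
        flat = [s for g in res.groups for s in g]
        assert sorted(flat) == sorted(m.sample_ids)

    def test_too_few_samples_rejected(self):
        m = matrix_from(np.random.default_rng(20).lognormal(size=(10, 2)))
        with pytest.raises(ValidationError):
            simprof(m)


# -- query correlation -------------------------------------------------------


class TestQueryCorrelation:
    def test_self_correlation(self):
        m = matrix_from(np.random.default_rng(14).lognormal(size=(6, 8)))
        res = query_correlation(m, "F2", p_threshold=0.001)
        assert res.stats.loc["F2", "rho"] == pytest.approx(1.0)
        assert bool(res.stats.loc["F2", "flagged"])

    def test_negation_symmetry(self):
        rng = np.random.default_rng(15)
        x = rng.lognormal(size=8)
        m = matrix_from([x, x.max() + 1 - x, rng.lognormal(size=8)])
        res = query_correlation(m, "F0")
        assert res.stats.loc["F1", "rho"] == pytest.approx(-1.0)
        assert res.stats.loc["F1", "p_value"] == \
            pytest.approx(res.stats.loc["F0", "p_value"])

    def test_p_matches_t_approximation_closed_form(self):
        rng = np.random.default_rng(16)
        x = rng.lognormal(size=(5, 11))
        m = matrix_from(x)
        res = query_correlation(m, "F0")
        for fid in m.feature_ids[1:]:
            rho = res.stats.loc[fid, "rho"]
            n = 11
            t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
            expected = 2 * stats.t.sf(abs(t), df=n - 2)
            assert res.stats.loc[fid, "p_value"] == pytest.approx(expected)
            # scipy's spearmanr uses the same approximation: cross-check
            sp = stats.spearmanr(x[0], x[int(fid[1:])])
            assert res.stats.loc[fid, "p_value"] == pytest.approx(sp.pvalue)

    def test_permutation_p_consistent_with_t(self):
        rng = np.random.default_rng(17)
        x = rng.lognormal(size=(4, 12))
        x[1] = x[0] * 2 + rng.lognormal(sigma=0.1, size=12)  # strong association
        m = matrix_from(x)
        p_t = query_correlation(m, "F0").stats.loc["F1", "p_value"]
        p_perm = query_correlation(m, "F0", method="permutation",
                                   seed=2).stats.loc["F1", "p_value"]
        assert p_perm <= 0.01
        assert abs(p_perm - p_t) < 0.01

    def test_bh_flags_are_subset_of_raw_flags(self):
        m = matrix_from(np.random.default_rng(18).lognormal(size=(30, 9)))
        raw = query_correlation(m, "F0", p_threshold=0.05)
        bh = query_correlation(m, "F0", p_threshold=0.05, bh=True)
        assert set(bh.stats.index[bh.stats.flagged]) <= \
            set(raw.stats.index[raw.stats.flagged])

    def test_unknown_query_raises_lookup_error(self):
        m = matrix_from(np.random.default_rng(19).lognormal(size=(4, 6)))
        with pytest.raises(KeyError):
            query_correlation(m, "missing")
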
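"""Kruskal-Wallis, Dunn's post-hoc, fold differences and BH adjustment,
checked against independent rank-formula and permutation oracles."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import fiscope as fs
from fiscope.de import dunns_test, fold_difference, kruskal_wallis


def oracle_kw_h(groups):
    """Direct evaluation of the tie-corrected rank formula."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    n = pooled.size
    ranks = stats.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie


def oracle_dunn_z(groups):
    """Independent evaluation of the rank-mean z formula."""
    arrays = [np.asarray(g, float) for g in groups]
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    means, start = [], 0
    for a in arrays:
        means.append(ranks[start : start + a.size].mean())
        start += a.size
    _, counts = np.unique(pooled, return_counts=True)
    var = n * (n + 1) / 12.0 - np.sum(counts**3 - counts) / (12.0 * (n - 1))
    out = {}
    for i, j in combinations(range(len(arrays)), 2):
        se = np.sqrt(var * (1 / arrays[i].size + 1 / arrays[j].size))
        out[(i, j)] = (means[i] - means[j]) / se
    return out


class TestKruskalWallis:
    def test_hand_evaluated_instance(self):
        h, p = kruskal_wallis([1, 2], [3, 4], [5, 6])
        assert h == pytest.approx(4.5714, abs=1e-3)
        assert h == pytest.approx(oracle_kw_h([[1, 2], [3, 4], [5, 6]]), abs=1e-9)

    def test_identical_groups_degenerate(self):
        h, p = kruskal_wallis([5, 5], [5, 5], [5, 5])
        assert h == 0.0 and p == 1.0

    def test_chi_square_close_to_exact_permutation_at_n8(self):
        """Two groups of 4: the chi-square p tracks the exhaustive
        permutation p over all C(8,4) rank splits. At N=8 the chi-square
        approximation carries up to ~0.1 absolute error mid-range, so the
        check is agreement at that magnitude for every achievable H plus
        strict order consistency between the two p-values."""
        pooled = list(range(1, 9))
        h_values = sorted(
            {
                round(kruskal_wallis([pooled[i] for i in idx],
                                     [pooled[i] for i in range(8) if i not in idx])[0], 10)
                for idx in combinations(range(8), 4)
            }
        )
        all_h = [
            kruskal_wallis([pooled[i] for i in idx],
                           [pooled[i] for i in range(8) if i not in idx])[0]
            for idx in combinations(range(8), 4)
        ]
        pairs = []
        for h_obs in h_values:
            p_ge = np.mean([h >= h_obs - 1e-9 for h in all_h])
            p_gt = np.mean([h > h_obs + 1e-9 for h in all_h])
            p_chi2 = float(stats.chi2.sf(h_obs, df=1))
            if h_obs > 0:  # H=0 is the degenerate lattice boundary
                # mid-p corrects for the discreteness of the exact law
                assert abs(p_chi2 - (p_ge + p_gt) / 2.0) < 0.05
            pairs.append((p_chi2, p_ge))
        pairs.sort()
        exact_sorted = [e for _, e in pairs]
        assert all(a <= b + 1e-12 for a, b in zip(exact_sorted, exact_sorted[1:]))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(size=n) for n in (6, 5, 7)]
        h1, p1 = kruskal_wallis(*groups)
        h2, p2 = kruskal_wallis(*[np.exp(g) for g in groups])
        assert h1 == pytest.approx(h2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_two_groups_equals_squared_rank_statistic(self):
        """For k=2, H equals the square of the standardized rank-sum z
        (tie-free instances)."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b = rng.normal(size=7), rng.normal(size=5)
            h, _ = kruskal_wallis(a, b)
            z = oracle_dunn_z([a, b])[(0, 1)]
            assert h == pytest.approx(z**2, abs=1e-9)

    def test_preconditions(self):
        with pytest.raises(fs.DomainError):
            kruskal_wallis([1, 2, 3])
        with pytest.raises(fs.DomainError):
            kruskal_wallis([1], [])
        with pytest.raises(fs.DomainError):
            kruskal_wallis([1], [2])


class TestDunn:
    def test_matches_independent_formula(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(size=3), rng.normal(size=3), rng.normal(size=3)]
        result = dunns_test(groups, adjust="none")
        oracle = oracle_dunn_z(groups)
        for pair, z in oracle.items():
            assert result[pair][0] == pytest.approx(z, abs=1e-9)

    def test_antisymmetry(self):
        g1, g2, g3 = [1, 2, 3], [2, 3, 9], [5, 6, 7]
        fwd = dunns_test([g1, g2, g3])
        swapped = dunns_test([g2, g1, g3])
        assert swapped[(0, 1)][0] == pytest.approx(-fwd[(0, 1)][0])
        assert swapped[(0, 1)][1] == pytest.approx(fwd[(0, 1)][1])

    def test_extreme_pair_has_largest_z(self):
        res = dunns_test([[1, 2, 3], [10, 20, 30], [100, 200, 300]])
        assert abs(res[(0, 2)][0]) >= abs(res[(0, 1)][0])
        assert abs(res[(0, 2)][0]) >= abs(res[(1, 2)][0])

    def test_bonferroni_adjustment(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        raw = dunns_test(groups, adjust="none")
        bonf = dunns_test(groups, adjust="bonferroni")
        for pair in raw:
            assert bonf[pair][1] == pytest.approx(min(1.0, 3 * raw[pair][1]))

    def test_tie_correction_in_denominator(self):
        tied = [[1, 1, 2], [2, 2, 3], [3, 3, 1]]
        oracle = oracle_dunn_z(tied)
        result = dunns_test(tied, adjust="none")
        for pair, z in oracle.items():
            assert result[pair][0] == pytest.approx(z, abs=1e-9)


class TestFoldDifference:
    def test_closed_forms(self):
        assert fold_difference([5, 5, 5], [5, 5, 5]) == 0.0
        assert fold_difference([31, 31], [7, 7], pseudocount=1) == pytest.approx(2.0)

    def test_planted_fold_recovery(self):
        cfg = fs.SimulationConfig(
            n_control=2, n_eoe_nofi=100, n_eoe_fi=100, seed=9,
            eoe_effect={}, fi_effect={"CPA3": 0.3}, lane_scale_sd=0.1,
        )
        raw, truth = fs.simulate_counts(cfg)
        norm = fs.normalize_lanes(raw)
        fi = truth.labels[truth.labels == "EoE_FI"].index
        nofi = truth.labels[truth.labels == "EoE_no_FI"].index
        fd = fold_difference(norm.values.loc[fi, "CPA3"],
                             norm.values.loc[nofi, "CPA3"])
        assert abs(fd - np.log2(0.3)) < 0.25


class TestAdjustPvalues:
    def test_step_up_examples(self):
        assert fs.adjust_pvalues([0.03])[0] == pytest.approx(0.03)
        np.testing.assert_allclose(
            fs.adjust_pvalues([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_q_dominates_p_and_stays_in_unit_interval(self, pvals):
        q = fs.adjust_pvalues(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-12)
        assert np.all((q >= 0) & (q <= 1))

    def test_rejects_out_of_range(self):
        with pytest.raises(fs.DomainError):
            fs.adjust_pvalues([0.5, 1.2])


class TestDifferentialExpression:
    def test_table_shape_and_columns(self, de_result, cohort):
        raw, _, _ = cohort
        assert len(de_result.table) == len(raw.annotation.endogenous)
        for col in ("H", "p_kw", "z_fi_vs_nofi", "p_dunn_fi_vs_nofi",
                    "log2fd_fi_vs_nofi", "q_fi_vs_nofi"):
            assert col in de_result.table.columns

    def test_planted_genes_rank_high_and_point_down(self, de_result):
        planted = ["CPA3", "FCER1B", "CCL2", "IL4", "IL5", "NOS2", "HIF1A"]
        top12 = de_result.table["z_fi_vs_nofi"].abs().nlargest(12).index
        assert sum(g in top12 for g in planted) >= 6
        assert (de_result.table.loc[planted, "log2fd_fi_vs_nofi"] < 0).all()

    def test_volcano_quantities(self, de_result):
        v = de_result.volcano()
        assert (v["minus_log10_q"] >= 0).all()
        assert len(v) == len(de_result.table)
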
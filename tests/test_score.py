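"""Transcript weights and the composite FI-score."""

import numpy as np
import pandas as pd
import pytest

import fiscope as fs
from fiscope.de import DEResult


def _de_from(genes, log2fd, q):
    table = pd.DataFrame({"log2fd_fi_vs_nofi": log2fd, "q_fi_vs_nofi": q},
                         index=genes)
    return DEResult(table=table)


class TestTranscriptWeights:
    def test_gate_zeroes_nonsignificant_genes(self):
        de = _de_from(["A", "B"], [-1.0, 2.0], [0.2, 0.01])
        w = fs.compute_transcript_weights(de, alpha=0.05)
        assert w.weights["A"] == 0.0
        assert w.weights["B"] != 0.0

    def test_single_gene_formula(self):
        # log2FD -1, q 0.01 -> raw weight -1 * (-log10 0.01) = -2, L1 -> -1
        de = _de_from(["A"], [-1.0], [0.01])
        w = fs.compute_transcript_weights(de, alpha=0.05)
        assert w.normalization_constant == pytest.approx(2.0)
        assert w.weights["A"] == pytest.approx(-1.0)

    def test_l1_normalization_and_signs(self):
        de = _de_from(["A", "B", "C"], [-1.0, 0.5, 3.0], [0.01, 0.04, 0.2])
        w = fs.compute_transcript_weights(de, alpha=0.05)
        assert w.weights.abs().sum() == pytest.approx(1.0)
        assert w.weights["A"] < 0 < w.weights["B"]
        assert w.weights["C"] == 0.0

    def test_empty_signature_raises(self):
        de = _de_from(["A"], [1.0], [0.5])
        with pytest.raises(fs.EmptySignatureError):
            fs.compute_transcript_weights(de, alpha=0.05)

    def test_planted_genes_weighted_negative(self, normalized, de_result):
        w = fs.compute_transcript_weights(de_result)
        planted = ["CPA3", "FCER1B", "CCL2", "IL4", "IL5", "NOS2", "HIF1A"]
        assert sum(w.weights[g] < 0 for g in planted) >= 6


def _toy_norm(values: pd.DataFrame) -> fs.NormalizedMatrix:
    ones = pd.Series(1.0, index=values.index)
    return fs.NormalizedMatrix(values=values, positive_factors=ones,
                               housekeeping_factors=ones, background=0.0 * ones)


class TestRawScore:
    def test_zero_weights_give_zero_scores(self):
        values = pd.DataFrame(np.random.default_rng(0).uniform(1, 100, (4, 3)),
                              index=list("wxyz"), columns=["A", "B", "C"])
        de = _de_from(["A", "B", "C"], [1.0, 1.0, 1.0], [0.01, 0.5, 0.5])
        w = fs.compute_transcript_weights(de)
        w.weights[:] = 0.0
        scores = fs.compute_raw_fi_score(_toy_norm(values), w, list("wxyz"))
        assert (scores == 0.0).all()

    def test_patient_at_cohort_mean_scores_zero(self):
        # patient z sits exactly at every gene's mean of the others
        base = np.array([[1.0, 10.0], [3.0, 30.0], [2.0, 20.0]])
        values = pd.DataFrame(base, index=["p1", "p2", "mid"], columns=["A", "B"])
        # log2(v+1) of mid must equal the cohort mean: construct directly
        logs = np.log2(base + 1)
        logs[2] = logs[:2].mean(axis=0)
        values = pd.DataFrame(2**logs - 1, index=values.index, columns=values.columns)
        de = _de_from(["A", "B"], [1.0, -1.0], [0.01, 0.01])
        w = fs.compute_transcript_weights(de)
        scores = fs.compute_raw_fi_score(_toy_norm(values), w, values.index)
        assert scores["mid"] == pytest.approx(0.0, abs=1e-12)

    def test_linearity_in_single_gene(self):
        rng = np.random.default_rng(2)
        values = pd.DataFrame(rng.uniform(5, 500, (5, 3)),
                              index=list("abcde"), columns=["A", "B", "C"])
        de = _de_from(["A", "B", "C"], [2.0, -1.0, 0.5], [0.01, 0.02, 0.03])
        w = fs.compute_transcript_weights(de)
        norm = _toy_norm(values)
        scores = fs.compute_raw_fi_score(norm, w, values.index)
        logs = np.log2(values + 1)
        z = (logs - logs.mean()) / logs.std(ddof=1)
        expected = (z * w.weights).sum(axis=1)
        pd.testing.assert_series_equal(scores, expected, check_names=False)
        # two patients differing only through gene A: score gap = w_A * z gap
        gap = scores["a"] - scores["b"]
        direct = (z.loc["a"] * w.weights - z.loc["b"] * w.weights).sum()
        assert gap == pytest.approx(direct)

    def test_cohort_too_small(self):
        values = pd.DataFrame([[1.0, 2.0]], index=["only"], columns=["A", "B"])
        de = _de_from(["A", "B"], [1.0, 1.0], [0.01, 0.01])
        w = fs.compute_transcript_weights(de)
        with pytest.raises(fs.DomainError):
            fs.compute_raw_fi_score(_toy_norm(values), w, ["only"])


class TestStandardize:
    def test_symmetric_triple_fixed_point(self):
        out = fs.standardize_scores(pd.Series([-1.0, 0.0, 1.0]))
        np.testing.assert_allclose(out.to_numpy(), [-1.0, 0.0, 1.0])

    def test_affine_invariance(self):
        s = pd.Series([0.3, -1.2, 2.5, 0.0])
        a = fs.standardize_scores(s)
        b = fs.standardize_scores(3.5 * s + 7.0)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_moments(self):
        s = pd.Series(np.random.default_rng(4).normal(5, 3, 20))
        out = fs.standardize_scores(s)
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_distribution(self):
        with pytest.raises(fs.DegenerateScoreError):
            fs.standardize_scores(pd.Series([2.0, 2.0, 2.0]))


class TestCalls:
    def test_boundary_is_positive(self):
        calls = fs.call_fi(pd.Series({"a": 0.04, "b": 0.03, "c": 0.029}), 0.03)
        assert calls["a"] and calls["b"] and not calls["c"]

    def test_sign_flip_symmetry(self, normalized, de_result, cohort):
        _, _, meta = cohort
        eoe = meta.samples_in("EoE_no_FI", "EoE_FI")
        w = fs.compute_transcript_weights(de_result)
        raw = fs.compute_raw_fi_score(normalized, w, eoe)
        std = fs.standardize_scores(raw)
        cutoff = 0.1
        flipped_w = fs.TranscriptWeights(weights=-w.weights, alpha=w.alpha,
                                         normalization_constant=w.normalization_constant)
        flipped_raw = fs.compute_raw_fi_score(normalized, flipped_w, eoe)
        flipped_std = fs.standardize_scores(flipped_raw)
        orig = fs.call_fi(std, cutoff)
        # scores negate exactly; > boundary cases are absent for generic data
        np.testing.assert_allclose(flipped_std.to_numpy(), -std.to_numpy(),
                                   atol=1e-12)
        inverted = fs.call_fi(flipped_std, -cutoff)
        boundary_free = (std - cutoff).abs() > 1e-9
        assert (orig[boundary_free] == ~inverted[boundary_free]).all()


class TestEndToEnd:
    def test_in_sample_discrimination(self, normalized, de_result, cohort):
        _, _, meta = cohort
        eoe = meta.samples_in("EoE_no_FI", "EoE_FI")
        fi = meta.groups.loc[eoe] == "EoE_FI"
        w, result, roc = fs.score_cohort(normalized, de_result, fi)
        assert roc.auc >= 0.90
        assert result.standardized.mean() == pytest.approx(0.0, abs=1e-9)
        assert result.standardized.std(ddof=1) == pytest.approx(1.0, abs=1e-9)
        # calls are a pure function of score and cutoff
        recomputed = fs.call_fi(result.standardized, result.cutoff)
        assert (recomputed == result.calls).all()

    def test_loo_not_better_than_in_sample(self, normalized, cohort, de_result):
        _, _, meta = cohort
        eoe = meta.samples_in("EoE_no_FI", "EoE_FI")
        fi = meta.groups.loc[eoe] == "EoE_FI"
        _, _, roc = fs.score_cohort(normalized, de_result, fi)
        loo = fs.loo_scores(normalized, meta.groups, fi)
        loo_auc = fs.auc(loo.loc[eoe], fi.loc[eoe])
        assert loo_auc <= roc.auc + 1e-9
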
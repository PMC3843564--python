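"""Reconstruction R^2, min-max parity series, and pairwise Welch contrasts."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ncakit import (
    TFExpressionTable,
    minmax_normalize,
    pairwise_condition_test,
    reconstruction_r2,
    simulate_expression,
    tfa_mrna_parity,
)
from ncakit.exceptions import (
    AlignmentError,
    DegenerateVarianceError,
    DimensionError,
    DomainError,
    InsufficientReplicationError,
)

from _oracles import pooled_r2_textbook, triple_loop_product, welch_t_p


class TestSimulateExpression:
    def test_zero_cs_annihilates(self):
        assert np.all(simulate_expression(np.zeros((3, 2)), np.ones((2, 4))) == 0)

    def test_scalar_product(self):
        assert simulate_expression([[2.0]], [[0.3]])[0, 0] == pytest.approx(0.6)

    @given(st.integers(0, 100))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cs = rng.normal(size=(4, 3))
        tfa = rng.normal(size=(3, 5))
        assert np.allclose(simulate_expression(cs, tfa),
                           triple_loop_product(cs, tfa), atol=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            simulate_expression(np.zeros((3, 2)), np.zeros((3, 4)))


class TestReconstructionR2:
    def test_perfect_fit_scores_one(self):
        x = np.random.default_rng(0).normal(size=(5, 4))
        assert reconstruction_r2(x, x) == pytest.approx(1.0)

    def test_grand_mean_simulation_scores_zero(self):
        x = np.random.default_rng(1).normal(size=(5, 4))
        sim = np.full_like(x, x.mean())
        assert reconstruction_r2(x, sim) == pytest.approx(0.0, abs=1e-12)

    @given(st.integers(0, 100))
    def test_matches_textbook_formula(self, seed):
        rng = np.random.default_rng(seed)
        meas, sim = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        assert reconstruction_r2(meas, sim) == pytest.approx(
            pooled_r2_textbook(meas, sim), rel=1e-10)

    def test_replicates_averaged_before_comparison(self):
        rng = np.random.default_rng(2)
        reps = [rng.normal(size=(4, 3)) for _ in range(3)]
        sim = rng.normal(size=(4, 3))
        assert reconstruction_r2(reps, sim) == pytest.approx(
            reconstruction_r2(np.mean(reps, axis=0), sim))

    @given(st.integers(0, 50))
    def test_invariant_under_common_affine_rescaling(self, seed):
        rng = np.random.default_rng(seed)
        meas, sim = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        a, b = 2.5, -0.7
        assert reconstruction_r2(a * meas + b, a * sim + b) == pytest.approx(
            reconstruction_r2(meas, sim), rel=1e-9)

    def test_constant_measurement_is_degenerate(self):
        with pytest.raises(DegenerateVarianceError):
            reconstruction_r2(np.ones((3, 2)), np.zeros((3, 2)))


class TestMinMaxNormalize:
    def test_affine_map_endpoints(self):
        out, degenerate = minmax_normalize(np.array([2.0, 4.0, 6.0, 8.0]))
        assert np.allclose(out, [0, 1 / 3, 2 / 3, 1])
        assert not degenerate

    def test_constant_series_is_half_with_flag(self):
        out, degenerate = minmax_normalize(np.array([3.0, 3.0, 3.0, 3.0]))
        assert np.all(out == 0.5) and degenerate

    @given(st.integers(0, 100))
    def test_idempotent_and_affine_invariant(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=5)
        if np.ptp(x) == 0:
            return
        once, _ = minmax_normalize(x)
        twice, _ = minmax_normalize(once)
        assert np.allclose(once, twice, atol=1e-12)
        scaled, _ = minmax_normalize(3.0 * x + 11.0)
        assert np.allclose(once, scaled, atol=1e-12)

    def test_too_short_series_rejected(self):
        with pytest.raises(DomainError):
            minmax_normalize(np.array([1.0]))


def _tf_table(tf_ids, data):
    data = np.asarray(data, float)
    return TFExpressionTable(tuple(tf_ids),
                             tuple(f"c{j}" for j in range(data.shape[1])),
                             (10.0 ** data,))


class TestParity:
    def test_identical_series_gives_unit_correlation(self):
        series = np.array([[0.1, 0.4, -0.2, 0.3]])
        table = _tf_table(["tA"], series)
        (entry,) = tfa_mrna_parity(series, ["tA"], table)
        assert entry.pearson_r == pytest.approx(1.0)

    def test_negated_series_gives_anti_parity(self):
        series = np.array([[0.1, 0.4, -0.2, 0.3]])
        table = _tf_table(["tA"], -series)
        (entry,) = tfa_mrna_parity(series, ["tA"], table)
        assert entry.pearson_r == pytest.approx(-1.0)

    @given(st.integers(0, 50))
    def test_matches_direct_covariance_formula(self, seed):
        rng = np.random.default_rng(seed)
        tfa = rng.normal(size=(1, 4))
        mrna = rng.normal(size=(1, 4))
        if np.ptp(tfa) == 0 or np.ptp(mrna) == 0:
            return
        table = _tf_table(["tA"], mrna)
        (entry,) = tfa_mrna_parity(tfa, ["tA"], table)
        a, _ = minmax_normalize(tfa[0])
        b, _ = minmax_normalize(np.asarray(mrna[0]))
        cov = np.mean((a - a.mean()) * (b - b.mean()))
        r = cov / (a.std() * b.std())
        assert entry.pearson_r == pytest.approx(r, rel=1e-9)

    def test_composite_regulator_compared_per_constituent(self):
        tfa = np.array([[0.1, 0.2, 0.3, 0.4]])
        table = _tf_table(["AP3", "PI"],
                          [[0.1, 0.2, 0.3, 0.4], [-0.4, -0.3, -0.2, -0.1]])
        entries = tfa_mrna_parity(tfa, ["AP3/PI"], table)
        assert [e.gene for e in entries] == ["AP3", "PI"]
        assert entries[0].pearson_r == pytest.approx(1.0)

    def test_flat_activity_still_rendered(self):
        tfa = np.array([[0.2, 0.2, 0.2, 0.2]])
        table = _tf_table(["tA"], [[0.1, 0.2, 0.3, 0.4]])
        (entry,) = tfa_mrna_parity(tfa, ["tA"], table)
        assert entry.tfa_degenerate
        assert np.all(entry.norm_tfa == 0.5)
        assert np.isnan(entry.pearson_r)

    def test_unmatched_tf_label(self):
        table = _tf_table(["tA"], [[0.1, 0.2, 0.3, 0.4]])
        with pytest.raises(AlignmentError):
            tfa_mrna_parity(np.zeros((1, 4)), ["tX"], table)


class TestPairwiseConditionTest:
    def test_identical_samples_not_significant(self):
        stack = np.zeros((3, 1, 2))
        stack[:, 0, 0] = stack[:, 0, 1] = [0.1, 0.2, 0.3]
        out = pairwise_condition_test(stack, ["tA"], ["c1", "c2"])
        assert out.loc[0, "p"] == pytest.approx(1.0)
        assert not out.loc[0, "significant"]

    @given(st.integers(0, 50))
    def test_matches_closed_form_welch(self, seed):
        rng = np.random.default_rng(seed)
        stack = rng.normal(size=(3, 1, 2))
        out = pairwise_condition_test(stack, ["tA"], ["c1", "c2"])
        t, p = welch_t_p(stack[:, 0, 0], stack[:, 0, 1])
        assert out.loc[0, "t"] == pytest.approx(t, rel=1e-9)
        assert out.loc[0, "p"] == pytest.approx(p, rel=1e-9)

    def test_strict_alpha_inequality_and_all_pairs(self):
        rng = np.random.default_rng(7)
        stack = rng.normal(size=(4, 2, 3))
        out = pairwise_condition_test(stack, ["tA", "tB"], ["c1", "c2", "c3"],
                                      alpha=0.05)
        assert len(out) == 2 * 3  # p TFs x C(n,2) pairs
        assert (out["significant"] == (out["p"] < 0.05)).all()

    def test_insufficient_replication(self):
        with pytest.raises(InsufficientReplicationError):
            pairwise_condition_test(np.zeros((1, 1, 2)), ["tA"], ["c1", "c2"])
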
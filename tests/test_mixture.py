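"""Mixture-effect models, interaction classification, and the
binary-prediction consistency reconstruction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from mixtox.dose_response import DoseResponseCurve
from mixtox.mixture import (
    IndeterminateVarianceError,
    LoeweNoSolutionError,
    MixtureComponent,
    MixtureDesign,
    classify_interaction,
    predict_bliss,
    predict_effect_summation,
    predict_loewe,
    reconstruct_singles_from_binaries,
)
from mixtox.reference import binary_predictions, higher_order_predictions

viab = st.floats(0.0, 100.0)


def _curve(name, bottom=0.0, top=100.0, hill=1.7, ic50=2.0):
    return DoseResponseCurve(
        compound=name, exposure_h=24.0, bottom=bottom, top=top, hill=hill,
        ic50=ic50, ic50_ci95=(ic50, ic50), r2=1.0, n_points=48, converged=True,
    )


class TestEffectSummation:
    def test_hand_example(self):
        assert predict_effect_summation(
            {"A": 80.0, "B": 70.0}).predicted_viability == pytest.approx(50.0)

    @given(v=st.floats(-50.0, 150.0))
    def test_single_component_identity(self, v):
        assert predict_effect_summation([v]).predicted_viability == pytest.approx(v)

    @given(vs=st.lists(viab, min_size=2, max_size=5))
    def test_permutation_invariant_and_associative(self, vs):
        direct = predict_effect_summation(vs).predicted_viability
        shuffled = predict_effect_summation(vs[::-1]).predicted_viability
        assert direct == pytest.approx(shuffled)
        # fold the first two into a sub-mixture, then add the rest
        sub = predict_effect_summation(vs[:2]).predicted_viability
        nested = predict_effect_summation([sub] + vs[2:]).predicted_viability
        assert nested == pytest.approx(direct)

    def test_below_zero_flagged_not_clamped(self):
        pred = predict_effect_summation([30.0, 20.0, 10.0])
        assert pred.predicted_viability == pytest.approx(-140.0)
        assert pred.below_zero

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            predict_effect_summation([])

    def test_reconstructed_ternary_matches_published_value(self):
        rec = reconstruct_singles_from_binaries(binary_predictions(24))
        singles = {c: rec.implied_viabilities[c] for c in ("CLO", "IMI", "ENR")}
        pred = predict_effect_summation(singles)
        assert pred.predicted_viability == pytest.approx(57.715, abs=0.01)


class TestBliss:
    def test_hand_example(self):
        assert predict_bliss([50.0, 50.0]).predicted_viability == pytest.approx(25.0)

    def test_absorbing_zero(self):
        assert predict_bliss([0.0, 73.0, 88.0]).predicted_viability == 0.0

    def test_identity_at_full_viability(self):
        assert predict_bliss([100.0, 100.0]).predicted_viability == pytest.approx(
            100.0)

    def test_out_of_range_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clipped"):
            pred = predict_bliss([120.0, 50.0])
        assert pred.predicted_viability == pytest.approx(50.0)

    @given(vs=st.lists(st.floats(99.0, 100.0), min_size=2, max_size=2))
    def test_agrees_with_summation_for_tiny_binary_inhibitions(self, vs):
        # first-order agreement: the binary gap is I1*I2/100 <= 0.01 pp
        s = predict_effect_summation(vs).predicted_viability
        b = predict_bliss(vs).predicted_viability
        assert abs(s - b) < 0.02

    @given(vs=st.lists(st.floats(99.0, 100.0), min_size=2, max_size=5))
    def test_gap_bounded_by_pairwise_products(self, vs):
        inhib = [100.0 - v for v in vs]
        bound = sum(
            inhib[i] * inhib[j] for i in range(len(vs)) for j in range(i)
        ) / 100.0
        s = predict_effect_summation(vs).predicted_viability
        b = predict_bliss(vs).predicted_viability
        assert abs(s - b) <= bound + 1e-9


class TestLoewe:
    @given(
        hill=st.floats(0.5, 4.0),
        ic50=st.floats(0.5, 6.0),
        dose=st.floats(0.2, 10.0),
        split=st.floats(0.05, 0.95),
    )
    def test_sham_combination_axiom(self, hill, ic50, dose, split):
        # a compound combined with itself predicts its own curve, however
        # the dose is split
        curve_a = _curve("A", hill=hill, ic50=ic50)
        curve_b = _curve("B", hill=hill, ic50=ic50)
        design = MixtureDesign((
            MixtureComponent("A", dose * split),
            MixtureComponent("B", dose * (1 - split)),
        ))
        pred = predict_loewe({"A": curve_a, "B": curve_b}, design)
        assert pred.predicted_viability == pytest.approx(
            float(curve_a.predict(dose)), abs=1e-6
        )

    def test_hill_one_case_matches_bisection_oracle(self):
        curves = {"A": _curve("A", hill=1.0, ic50=2.0),
                  "B": _curve("B", hill=1.0, ic50=4.0)}
        design = MixtureDesign((MixtureComponent("A", 1.0),
                                MixtureComponent("B", 3.0)))
        pred = predict_loewe(curves, design)

        # dense-grid oracle: a million candidate effect levels
        y = np.linspace(1e-9, 100 - 1e-9, 1_000_000)

        def ec(curve, y):
            return curve.ic50 * ((curve.top - y) / (y - curve.bottom)) ** (
                1.0 / curve.hill)

        cond = 1.0 / ec(curves["A"], y) + 3.0 / ec(curves["B"], y) - 1.0
        i = np.argmin(np.abs(cond))
        assert pred.predicted_viability == pytest.approx(y[i], abs=1e-4)
        # and satisfies the condition itself far more tightly
        assert abs(1.0 / ec(curves["A"], pred.predicted_viability)
                   + 3.0 / ec(curves["B"], pred.predicted_viability) - 1.0) < 1e-8

    def test_missing_curve_raises(self):
        design = MixtureDesign((MixtureComponent("A", 1.0),
                                MixtureComponent("B", 1.0)))
        with pytest.raises(KeyError, match="B"):
            predict_loewe({"A": _curve("A")}, design)

    def test_no_overlap_raises(self):
        lo = _curve("A", bottom=0.0, top=40.0)
        hi = _curve("B", bottom=60.0, top=100.0)
        design = MixtureDesign((MixtureComponent("A", 1.0),
                                MixtureComponent("B", 1.0)))
        with pytest.raises(LoeweNoSolutionError):
            predict_loewe({"A": lo, "B": hi}, design)


class TestClassifyInteraction:
    def test_symmetric_noise_around_prediction_is_additive(self):
        observed = [49.0, 51.0, 50.5, 49.5, 50.0]
        call = classify_interaction(observed, 50.0)
        assert call.label == "additive"
        assert call.mean_difference == pytest.approx(0.0)

    def test_published_strongest_synergy_row(self):
        # observed far below the effect-summation prediction of 82.368
        observed = [6.0, 7.0, 7.0, 8.0, 7.69]
        call = classify_interaction(observed, 82.368)
        assert call.label == "synergistic"
        assert np.mean(observed) == pytest.approx(7.138)
        assert call.p_value < 0.001

    def test_antagonistic_with_hand_computed_t(self):
        observed = np.array([90.0, 91.0, 89.0, 92.0, 88.0])
        call = classify_interaction(observed, 70.0)
        diff = observed - 70.0
        t_hand = diff.mean() / (diff.std(ddof=1) / np.sqrt(len(diff)))
        assert call.label == "antagonistic"
        assert call.t_stat == pytest.approx(t_hand)
        assert call.p_value == pytest.approx(
            2 * stats.t.sf(abs(t_hand), len(diff) - 1))

    def test_zero_variance_equal_mean_is_additive(self):
        call = classify_interaction([50.0, 50.0, 50.0], 50.0)
        assert call.label == "additive" and call.p_value == 1.0

    def test_zero_variance_nonzero_difference_is_indeterminate(self):
        with pytest.raises(IndeterminateVarianceError):
            classify_interaction([50.0, 50.0, 50.0], 60.0)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            classify_interaction([50.0], 50.0)

    @given(shift=st.floats(0.0, 40.0))
    def test_lowering_observed_preserves_synergy(self, shift):
        base = np.array([40.0, 42.0, 38.0, 41.0, 39.0, 40.0])
        first = classify_interaction(base, 60.0)
        assert first.label == "synergistic"
        shifted = classify_interaction(base - shift, 60.0)
        assert shifted.label == "synergistic"


class TestReconstruction:
    def test_consistent_system_recovered_exactly(self):
        true_inhib = {"A": 10.0, "B": 20.0, "C": 30.0, "D": 40.0}
        pairs = {
            frozenset((i, j)): 100.0 - (true_inhib[i] + true_inhib[j])
            for i in true_inhib for j in true_inhib if i < j
        }
        rec = reconstruct_singles_from_binaries(pairs)
        for c, i_true in true_inhib.items():
            assert rec.inhibitions[c] == pytest.approx(i_true, abs=1e-9)
        assert rec.residual_norm == pytest.approx(0.0, abs=1e-9)

    def test_published_24h_block_is_consistent(self):
        rec = reconstruct_singles_from_binaries(binary_predictions(24))
        assert rec.residual_norm < 0.01
        expected = {"CLO": 85.40, "IMI": 83.69, "ENR": 88.63, "OFX": 85.24}
        for c, v in expected.items():
            assert rec.implied_viabilities[c] == pytest.approx(v, abs=0.01)

    def test_published_48h_block_is_inconsistent(self):
        rec = reconstruct_singles_from_binaries(binary_predictions(48))
        assert rec.residual_norm > 1.0

    def test_published_24h_quaternary_disagrees_with_binaries(self):
        rec = reconstruct_singles_from_binaries(binary_predictions(24))
        quaternary = next(
            v for k, v in higher_order_predictions(24).items() if len(k) == 4
        )
        implied = rec.predict_effect_summation(rec.compounds)
        assert abs(implied - quaternary) > 10.0  # reported, not corrected

    def test_rank_deficient_coverage_rejected(self):
        pairs = {frozenset(("A", "B")): 70.0, frozenset(("C", "D")): 60.0,
                 frozenset(("A", "C")): 65.0, frozenset(("B", "D")): 65.0}
        # rank 3 < 4 compounds even though there are 4 equations
        with pytest.raises(ValueError, match="rank"):
            reconstruct_singles_from_binaries(pairs)

    def test_too_few_equations_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_singles_from_binaries(
                {frozenset(("A", "B")): 70.0, frozenset(("B", "C")): 60.0})
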
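"""4PL fitting, IC50 confidence intervals, and potency ranking."""

import numpy as np
import pytest

from mixtox.dose_response import (
    DegenerateFitError,
    DoseResponseCurve,
    DoseResponseDataset,
    FourParamLogistic,
    fit_4pl,
    four_pl,
    ic50_confidence_interval,
    rank_potency,
)

TRUE = dict(bottom=0.0, top=100.0, hill=1.5, ic50=2.0)


def _noise_free_dataset(n_rep=3) -> DoseResponseDataset:
    doses = np.repeat(np.geomspace(0.2, 8.0, 8), n_rep)
    v = four_pl(doses, **TRUE)
    return DoseResponseDataset("X", 24.0, doses, v)


def _noisy_dataset(seed, sd=5.0, n_rep=6) -> DoseResponseDataset:
    rng = np.random.default_rng(seed)
    doses = np.repeat(np.geomspace(0.2, 8.0, 8), n_rep)
    v = four_pl(doses, **TRUE) + rng.normal(0, sd, doses.size)
    return DoseResponseDataset("X", 24.0, doses, v)


class TestFit:
    def test_noise_free_identifiability(self):
        curve = fit_4pl(_noise_free_dataset())
        assert curve.ic50 == pytest.approx(TRUE["ic50"], abs=1e-6)
        assert curve.hill == pytest.approx(TRUE["hill"], rel=1e-5)
        assert curve.converged

    def test_r2_is_one_for_noise_free_data(self):
        assert fit_4pl(_noise_free_dataset()).r2 == pytest.approx(1.0, abs=1e-9)

    def test_midpoint_parameterization(self):
        curve = fit_4pl(_noisy_dataset(seed=7))
        at_ic50 = curve.predict(curve.ic50)
        assert at_ic50 == pytest.approx((curve.top + curve.bottom) / 2, abs=1e-9)

    def test_zero_dose_evaluates_to_top(self):
        curve = fit_4pl(_noise_free_dataset())
        assert curve.predict(0.0) == pytest.approx(curve.top)

    def test_point_order_irrelevant(self):
        ds = _noisy_dataset(seed=3)
        perm = np.random.default_rng(0).permutation(ds.dose_mM.size)
        shuffled = DoseResponseDataset("X", 24.0, ds.dose_mM[perm],
                                       ds.viability_pct[perm])
        a, b = fit_4pl(ds), fit_4pl(shuffled)
        # same objective, so the same optimum up to optimizer termination
        assert a.ic50 == pytest.approx(b.ic50, rel=1e-6)
        assert a.hill == pytest.approx(b.hill, rel=1e-5)

    def test_sse_beats_brute_force_grid(self):
        # independent grid-search oracle over the 4 parameters
        ds = _noisy_dataset(seed=11)
        d, v = ds.dose_mM, ds.viability_pct

        def sse(bottom, top, hill, ic50):
            return np.sum((four_pl(d, bottom, top, hill, ic50) - v) ** 2)

        grid_best = min(
            sse(bottom, top, hill, ic50)
            for bottom in range(0, 21, 5)
            for top in range(90, 111, 5)
            for hill in np.arange(0.5, 4.01, 0.25)
            for ic50 in np.geomspace(d.min(), d.max(), 60)
        )
        est = FourParamLogistic().fit(d, v)
        fitted_sse = np.sum((est.predict(d) - v) ** 2)
        assert fitted_sse <= grid_best + 1e-9

    def test_fixed_asymptotes_respected(self):
        ds = _noisy_dataset(seed=5)
        curve = fit_4pl(ds, fix_bottom=0.0, fix_top=100.0)
        assert curve.bottom == 0.0 and curve.top == 100.0

    @pytest.mark.parametrize(
        "doses, viab, err",
        [
            (np.repeat([1, 2, 3, 4], 3), None, DegenerateFitError),  # < 5 doses
            (np.zeros(12), None, DegenerateFitError),  # no positive doses
            (np.repeat(np.geomspace(0.2, 8, 8), 2), 50.0, DegenerateFitError),
        ],
    )
    def test_degenerate_inputs_rejected(self, doses, viab, err):
        v = np.full(doses.size, viab) if viab is not None else four_pl(
            doses, **TRUE)
        with pytest.raises(err):
            FourParamLogistic().fit(doses, v)


class TestConfidenceInterval:
    def test_noise_free_interval_collapses(self):
        curve = fit_4pl(_noise_free_dataset())
        lo, hi = curve.ic50_ci95
        assert lo == pytest.approx(curve.ic50, rel=1e-5)
        assert hi == pytest.approx(curve.ic50, rel=1e-5)

    def test_interval_brackets_ic50(self):
        curve = fit_4pl(_noisy_dataset(seed=2))
        lo, hi = curve.ic50_ci95
        assert lo <= curve.ic50 <= hi

    def test_bootstrap_reproducible_under_seed(self):
        ds = _noisy_dataset(seed=9)
        a = fit_4pl(ds, ci_method="bootstrap", n_boot=999, random_state=42)
        b = fit_4pl(ds, ci_method="bootstrap", n_boot=999, random_state=42)
        assert a.ic50_ci95 == b.ic50_ci95

    def test_methods_roughly_agree(self):
        ds = _noisy_dataset(seed=4)
        curve = fit_4pl(ds, random_state=0)
        asym = ic50_confidence_interval(curve, ds, method="asymptotic_log")
        boot = ic50_confidence_interval(curve, ds, method="bootstrap")
        # same order of magnitude of uncertainty
        assert np.log(asym[1] / asym[0]) == pytest.approx(
            np.log(boot[1] / boot[0]), rel=0.6
        )


def _curve(compound, ic50, exposure_h=24.0):
    return DoseResponseCurve(
        compound=compound, exposure_h=exposure_h, bottom=0.0, top=100.0,
        hill=2.0, ic50=ic50, ic50_ci95=(ic50, ic50), r2=1.0, n_points=48,
        converged=True,
    )


class TestRankPotency:
    def test_published_24h_order(self):
        curves = [_curve("CLO", 5.356), _curve("IMI", 4.754),
                  _curve("ENR", 1.446), _curve("OFX", 2.742)]
        ranking = rank_potency(curves)
        assert ranking.compounds == ("ENR", "OFX", "IMI", "CLO")
        assert not ranking.ties

    def test_single_curve(self):
        assert rank_potency([_curve("A", 1.0)]).compounds == ("A",)

    def test_tie_flagged_and_lexicographic(self):
        ranking = rank_potency([_curve("B", 2.0), _curve("A", 2.0)])
        assert ranking.compounds == ("A", "B")
        assert ranking.ties == (("A", "B"),)

    def test_mixed_exposures_rejected_unless_allowed(self):
        curves = [_curve("A", 1.0, 24.0), _curve("B", 2.0, 48.0)]
        with pytest.raises(ValueError, match="exposure"):
            rank_potency(curves)
        assert rank_potency(curves, allow_mixed_exposure=True).compounds == (
            "A", "B")
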
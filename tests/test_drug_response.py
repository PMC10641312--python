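"""GI50 fitting, median-effect model and combination indices."""

import math

import numpy as np
import pytest

from cdk4prof.drug_response import (
    classify_synergy,
    combination_index,
    fit_gi50,
    fit_median_effect,
    median_effect_from_responses,
    response_to_fa,
)
from cdk4prof.synthetic_data import simulate_combination, simulate_dose_response


def me_series(dm, m, doses):
    doses = np.asarray(doses, dtype=float)
    return doses, 1.0 / (1.0 + (dm / doses) ** m)


class TestGI50:
    def test_noiseless_inversion(self):
        d = 0.1 * 2.0 ** np.arange(-3, 5)
        y = 100.0 / (1.0 + d / 0.1)
        fit = fit_gi50(d, y)
        assert fit.gi50 == pytest.approx(0.1, rel=1e-6)
        # the fitted curve passes 50 at GI50 by construction
        assert 100.0 / (1.0 + fit.gi50 / fit.gi50) == pytest.approx(50.0)

    def test_flat_response_flagged_infinite(self):
        fit = fit_gi50([0.01, 0.1, 1, 10], [100, 100, 100, 100])
        assert math.isinf(fit.gi50)
        assert "no_inhibition" in fit.flags

    def test_too_few_doses(self):
        with pytest.raises(ValueError):
            fit_gi50([1, 2, 3], [90, 50, 10])

    def test_noisy_recovery_is_unbiased(self):
        rel = []
        for seed in range(30):
            sim = simulate_dose_response(seed, dm=0.1, m=1.0, noise_sd=5.0)
            mean = sim.data.groupby("dose", as_index=False)["response"].mean()
            rel.append(fit_gi50(mean["dose"], mean["response"]).gi50 / 0.1 - 1)
        assert abs(np.median(rel)) < 0.05


class TestMedianEffect:
    def test_closed_form_recovery(self):
        d, fa = me_series(2.0, 1.5, [0.5, 1, 2, 4, 8])
        fit = fit_median_effect(d, fa)
        assert fit.dm == pytest.approx(2.0, rel=1e-9)
        assert fit.m == pytest.approx(1.5, rel=1e-9)
        assert fit.r == pytest.approx(1.0)

    def test_fa_half_at_dm_for_any_slope(self):
        for m in (0.5, 1.0, 2.7):
            d, fa = me_series(3.0, m, [1, 2, 3, 6, 9])
            fit = fit_median_effect(d, fa)
            assert fit.fa(fit.dm) == pytest.approx(0.5, abs=1e-12)

    def test_extreme_fa_points_dropped_with_warning(self):
        d = np.array([0.1, 1, 2, 4, 1000.0])
        fa = np.array([0.001, 0.3, 0.5, 0.7, 0.9999])
        with pytest.warns(UserWarning, match="excluding"):
            fit = fit_median_effect(d, fa)
        assert fit.n_points == 3

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            fit_median_effect([1, 2, 4], [0.8, 0.5, 0.2])

    def test_round_trip_to_machine_precision(self):
        fit = fit_median_effect(*me_series(0.7, 2.0, [0.2, 0.5, 1, 2, 5]))
        grid = np.geomspace(0.1, 10, 12)
        refit = fit_median_effect(grid, fit.fa(grid))
        assert refit.dm == pytest.approx(fit.dm, rel=1e-12)
        assert refit.m == pytest.approx(fit.m, rel=1e-12)


class TestCombinationIndex:
    def sham(self):
        d, fa = me_series(0.1, 1.0, [0.0125, 0.025, 0.05, 0.1, 0.2, 0.4, 0.8])
        return fit_median_effect(d, fa)

    def test_sham_self_combination(self):
        """A drug combined 1:1 with itself is exactly Loewe-additive: the
        exclusive sum is 1 and the nonexclusive CI is 1 + 1/4 at every fa."""
        fit = self.sham()
        for res in combination_index(fit, [fit, fit], [1, 1], [0.25, 0.5, 0.9]):
            assert res.exclusive_sum == pytest.approx(1.0, abs=1e-9)
            assert res.ci == pytest.approx(1.25, abs=1e-9)

    def test_vanishing_component_limit(self):
        fit = self.sham()
        res = combination_index(fit, [fit, fit], [1, 0], [0.5])[0]
        assert res.ci == pytest.approx(1.0, abs=1e-9)  # product term vanishes

    def test_scale_invariance_under_dose_rescaling(self):
        c = 37.0
        d, fa = me_series(0.1, 1.3, [0.02, 0.05, 0.1, 0.3, 0.8])
        f1 = fit_median_effect(d, fa)
        f1s = fit_median_effect(d * c, fa)
        d2, fa2 = me_series(0.25, 1.3, [0.05, 0.12, 0.25, 0.6, 1.5])
        f2 = fit_median_effect(d2, fa2)
        f2s = fit_median_effect(d2 * c, fa2)
        dc, fac = me_series(0.15, 1.3, [0.03, 0.08, 0.15, 0.4, 1.0])
        fc = fit_median_effect(dc, fac)
        fcs = fit_median_effect(dc * c, fac)
        a = combination_index(fc, [f1, f2], [1, 2], [0.5, 0.75])
        b = combination_index(fcs, [f1s, f2s], [1, 2], [0.5, 0.75])
        for x, y in zip(a, b):
            assert x.ci == pytest.approx(y.ci, abs=1e-9)

    def test_simulated_synergy_gives_ci_below_one(self):
        sim = simulate_combination(3, synergy_factor=2.0, noise_sd=0.0)
        singles = [
            median_effect_from_responses(sim.singles[k].data)
            for k in sorted(sim.singles)
        ]
        combo = median_effect_from_responses(sim.combination.data)
        res = combination_index(combo, singles, list(sim.ratio), [0.5])[0]
        assert res.ci < 1.0

    def test_three_drug_nonexclusive_terms(self):
        fit = self.sham()
        res = combination_index(fit, [fit] * 3, [1, 1, 1], [0.5])[0]
        # terms: 3*(1/3) + 3*(1/9) + 1/27
        assert res.exclusive_sum == pytest.approx(1.0, abs=1e-9)
        assert res.ci == pytest.approx(1.0 + 3 / 9 + 1 / 27, abs=1e-9)

    def test_invalid_effect_level(self):
        fit = self.sham()
        with pytest.raises(ValueError):
            combination_index(fit, [fit, fit], [1, 1], [1.0])


class TestSynergyBands:
    @pytest.mark.parametrize(
        "ci,label",
        [(1.0, "additive"), (0.3, "synergism"), (3.3, "antagonism")],
    )
    def test_default_bands(self, ci, label):
        assert classify_synergy(ci) == label

    def test_custom_fine_bands(self):
        bands = {"strong synergism": (0.1, 0.3), "synergism": (0.3, 0.7)}
        assert classify_synergy(0.3, {"bands": bands}) == "synergism"
        assert classify_synergy(0.15, {"bands": bands}) == "strong synergism"

    def test_invalid_ci(self):
        with pytest.raises(ValueError):
            classify_synergy(-1.0)


def test_response_to_fa_conversion():
    assert response_to_fa([100, 50, 0]).tolist() == [0.0, 0.5, 1.0]
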
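"""Parametric survival families: evaluation, medians, occupancy, fitting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import optimize

from psmcea.survival import (
    DigitizedCurve,
    Family,
    ParametricSurvival,
    fit_parametric,
    median_survival,
    quantile,
    rank_fits,
    reconstruct_interval_counts,
    select_distribution,
    state_occupancy,
    survival_probability,
)

TIS_OS = ParametricSurvival("loglogistic", 1.78, 0.0068)
TIS_PFS = ParametricSurvival("loglogistic", 1.92, 0.035)
CHEMO_PFS = ParametricSurvival("loglogistic", 3.97, 0.0022)

# one representative parameter set per family, used across property checks
FAMILY_EXAMPLES = {
    Family.EXPONENTIAL: ParametricSurvival("exponential", None, 0.08),
    Family.WEIBULL: ParametricSurvival("weibull", 1.4, 0.02),
    Family.GOMPERTZ: ParametricSurvival("gompertz", 0.15, 0.03),
    Family.GAMMA: ParametricSurvival("gamma", 2.0, 0.12),
    Family.LOGNORMAL: ParametricSurvival("lognormal", 0.8, 12.0),
    Family.LOGLOGISTIC: TIS_PFS,
}


class TestSurvivalProbability:
    @pytest.mark.parametrize(
        "dist, t, expected",
        [
            (TIS_OS, 0.0, 1.0),
            (TIS_OS, 12.0, 0.6382320228),  # hand-evaluated 1/(1+0.0068*12**1.78)
        ],
    )
    def test_loglogistic_values(self, dist, t, expected):
        assert survival_probability(dist, t) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("dist", FAMILY_EXAMPLES.values(), ids=lambda d: d.family.value)
    def test_survival_function_axioms(self, dist):
        """S(0)=1, monotone non-increasing, bounded in [0,1], vanishing tail."""
        grid = np.linspace(0.0, 400.0, 2000)
        s = survival_probability(dist, grid)
        assert s[0] == pytest.approx(1.0)
        assert np.all(np.diff(s) <= 1e-15)
        assert np.all((s >= 0.0) & (s <= 1.0))
        assert s[-1] < 0.05

    @pytest.mark.parametrize("dist", FAMILY_EXAMPLES.values(), ids=lambda d: d.family.value)
    def test_median_is_half_survival(self, dist):
        assert survival_probability(dist, median_survival(dist)) == pytest.approx(0.5, abs=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            survival_probability(TIS_OS, -1.0)

    @pytest.mark.parametrize("shape, scale", [(-1.0, 0.01), (1.5, 0.0), (1.5, -2.0)])
    def test_invalid_parameters_rejected(self, shape, scale):
        with pytest.raises(ValueError):
            ParametricSurvival("loglogistic", shape, scale)

    @pytest.mark.parametrize("dist", FAMILY_EXAMPLES.values(), ids=lambda d: d.family.value)
    def test_quantile_inverts_survival(self, dist):
        p = np.array([0.05, 0.25, 0.5, 0.9])
        t = quantile(dist, p)
        assert survival_probability(dist, t) == pytest.approx(1.0 - p, abs=1e-9)


class TestMedianSurvival:
    @pytest.mark.parametrize(
        "dist, expected",
        [
            (TIS_OS, 16.5078921),     # (1/lambda)**(1/gamma)
            (CHEMO_PFS, 4.6710546),
            (ParametricSurvival("exponential", None, np.log(2.0)), 1.0),
        ],
    )
    def test_known_medians(self, dist, expected):
        assert median_survival(dist) == pytest.approx(expected, rel=1e-6)

    @given(
        shape=st.floats(0.5, 6.0),
        scale=st.floats(1e-4, 0.5),
    )
    def test_loglogistic_closed_form_matches_numeric_root(self, shape, scale):
        dist = ParametricSurvival("loglogistic", shape, scale)
        closed = median_survival(dist)
        numeric = optimize.brentq(
            lambda t: survival_probability(dist, t) - 0.5, 0.0, closed * 10 + 1.0,
            xtol=1e-13, rtol=1e-15,
        )
        assert closed == pytest.approx(numeric, rel=1e-9)


class TestStateOccupancy:
    def test_everyone_progression_free_at_entry(self):
        occ = state_occupancy(TIS_PFS, TIS_OS, 0.0)
        assert (occ.pf, occ.pd, occ.dead) == (1.0, 0.0, 0.0)

    def test_published_pair_at_one_year(self):
        occ = state_occupancy(TIS_PFS, TIS_OS, 12.0)
        assert occ.pf == pytest.approx(0.19487903, rel=1e-6)
        assert occ.pd == pytest.approx(0.44335300, rel=1e-6)
        assert occ.dead == pytest.approx(0.36176798, rel=1e-6)

    def test_identical_curves_leave_no_progressed_state(self):
        for t in np.linspace(0, 60, 13):
            occ = state_occupancy(TIS_OS, TIS_OS, t)
            assert occ.pd == 0.0

    @given(
        g1=st.floats(0.5, 5.0), l1=st.floats(1e-4, 0.1),
        g2=st.floats(0.5, 5.0), l2=st.floats(1e-4, 0.1),
    )
    def test_simplex_even_when_pfs_crosses_os(self, g1, l1, g2, l2):
        """Clipping keeps the partition valid for arbitrary curve pairs."""
        pfs = ParametricSurvival("loglogistic", g1, l1)
        os_ = ParametricSurvival("loglogistic", g2, l2)
        occ = state_occupancy(pfs, os_, np.linspace(0.0, 120.0, 241))
        for comp in (occ.pf, occ.pd, occ.dead):
            assert np.all((comp >= 0.0) & (comp <= 1.0))
        np.testing.assert_allclose(occ.pf + occ.pd + occ.dead, 1.0, atol=1e-12)


class TestDigitizedCurve:
    def test_anchor_inserted_and_monotonicity_repaired(self):
        curve = DigitizedCurve([3.0, 6.0, 9.0], [0.8, 0.85, 0.5])
        assert curve.times[0] == 0.0 and curve.survival[0] == 1.0
        assert curve.repaired
        assert np.all(np.diff(curve.survival) <= 0.0)

    def test_csv_round_trip(self, tmp_path):
        curve = DigitizedCurve([0, 6, 12], [1.0, 0.5, 0.25], label="toy")
        path = tmp_path / "toy.csv"
        curve.to_csv(path)
        back = DigitizedCurve.read_csv(path)
        np.testing.assert_array_equal(back.times, curve.times)
        np.testing.assert_array_equal(back.survival, curve.survival)


class TestReconstruction:
    def test_halving_curve_counts(self):
        curve = DigitizedCurve([0, 6, 12], [1.0, 0.5, 0.25], assumed_cohort_size=100)
        counts = reconstruct_interval_counts(curve)
        assert counts.table["events"].tolist() == [50, 25]
        assert counts.n_censored == 25
        assert counts.censor_time == 12.0

    def test_flat_curve_all_censored(self):
        curve = DigitizedCurve([0, 12], [1.0, 1.0], assumed_cohort_size=100)
        counts = reconstruct_interval_counts(curve)
        assert counts.table["events"].sum() == 0
        assert counts.n_censored == 100

    def test_degenerate_curve_rejected(self):
        curve = DigitizedCurve([], [], assumed_cohort_size=100)  # anchor only
        with pytest.raises(ValueError):
            reconstruct_interval_counts(curve)


def _noiseless_curve(dist, n=5000, stop=36.0, step=0.5):
    grid = np.arange(0.0, stop + step / 2, step)
    return DigitizedCurve(grid, survival_probability(dist, grid), assumed_cohort_size=n)


class TestFitting:
    @pytest.mark.parametrize("family", list(Family), ids=lambda f: f.value)
    def test_noiseless_parameter_recovery(self, family):
        """MLE on a noiseless curve recovers the truth within 5% relative."""
        truth = FAMILY_EXAMPLES[family]
        fit = fit_parametric(_noiseless_curve(truth), family)
        assert fit.converged
        assert fit.distribution.scale == pytest.approx(truth.scale, rel=0.05)
        if truth.shape is not None:
            assert fit.distribution.shape == pytest.approx(truth.shape, rel=0.05)

    def test_true_family_wins_model_selection(self):
        """Exponential truth: exponential AIC beats log-logistic at large n."""
        truth = FAMILY_EXAMPLES[Family.EXPONENTIAL]
        curve = _noiseless_curve(truth)
        fits = [fit_parametric(curve, f) for f in (Family.EXPONENTIAL, Family.LOGLOGISTIC)]
        assert fits[0].aic <= fits[1].aic
        assert select_distribution(fits).distribution.family is Family.EXPONENTIAL

    def test_aic_bic_identities(self):
        fit = fit_parametric(_noiseless_curve(TIS_PFS), "loglogistic")
        n_eff = 5000
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.log_likelihood)
        assert fit.bic == pytest.approx(fit.n_params * np.log(n_eff) - 2 * fit.log_likelihood)

    def test_degenerate_curve_rejected(self):
        with pytest.raises(ValueError):
            fit_parametric(DigitizedCurve([0, 6], [1.0, 0.5], assumed_cohort_size=100),
                           "loglogistic")

    def test_cross_check_against_lifelines_interval_fitter(self):
        """Independent route: lifelines' log-logistic interval-censored MLE on
        the expanded pseudo-data agrees with the package's fitter."""
        from lifelines import LogLogisticFitter

        from psmcea.survival import reconstruct_interval_counts

        curve = _noiseless_curve(TIS_PFS, n=2000, step=1.0)
        counts = reconstruct_interval_counts(curve)
        lo, hi = [], []
        for row in counts.table.itertuples():
            lo.extend([row.t_start] * row.events)
            hi.extend([row.t_end] * row.events)
        lo.extend([counts.censor_time] * counts.n_censored)
        hi.extend([np.inf] * counts.n_censored)
        llf = LogLogisticFitter()
        llf.fit_interval_censoring(np.maximum(np.array(lo), 1e-6), np.array(hi))
        # lifelines: S(t) = 1/(1+(t/alpha)^beta)  ->  gamma=beta, lambda=alpha^-beta
        gamma_ll = llf.beta_
        lambda_ll = llf.alpha_ ** -llf.beta_
        fit = fit_parametric(curve, "loglogistic")
        assert fit.distribution.shape == pytest.approx(gamma_ll, rel=0.02)
        assert fit.distribution.scale == pytest.approx(lambda_ll, rel=0.05)


class TestSelection:
    def _fit(self, aic, bic, n_params=2):
        return type("F", (), {
            "converged": True, "aic": aic, "bic": bic, "n_params": n_params,
            "distribution": TIS_PFS, "log_likelihood": 0.0,
        })()

    def test_minimum_aic_wins(self):
        fits = [self._fit(101.2, 0), self._fit(99.8, 0), self._fit(103.4, 0)]
        assert select_distribution(fits) is fits[1]

    def test_aic_tie_broken_by_bic(self):
        fits = [self._fit(100.0, 210.0), self._fit(100.0, 205.5)]
        assert select_distribution(fits) is fits[1]

    def test_single_fit_returned(self):
        fits = [self._fit(50.0, 55.0)]
        assert select_distribution(fits) is fits[0]

    def test_all_failed_raises(self):
        bad = self._fit(float("inf"), float("inf"))
        bad.converged = False
        with pytest.raises(ValueError):
            select_distribution([bad])

    def test_ranking_table_sorted(self):
        curve = _noiseless_curve(TIS_PFS, n=1000, step=1.0)
        table = rank_fits([fit_parametric(curve, f) for f in Family])
        assert list(table.columns[:1]) == ["family"]
        assert table["aic"].is_monotonic_increasing
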
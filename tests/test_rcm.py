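"""Reactive continuum model: evaluation, plateau rule, calibration, algebra."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fjordfe import (
    DissolutionCurve,
    FitOptions,
    PlateauRule,
    RCMFit,
    RCMParams,
    derive_params,
    estimate_m0,
    fit_rcm,
    grid_search_rcm,
    rcm_dissolved,
    rcm_rate,
    rcm_remaining,
)
from fjordfe.rcm import plateau_onset

from conftest import curve_from_truth

params_strategy = st.builds(
    RCMParams,
    m0=st.floats(0.1, 100.0),
    a=st.floats(10.0, 1e6),
    v=st.floats(0.05, 50.0),
)
time_strategy = st.floats(0.0, 1e8)


# ---------------------------------------------------------------------------
# Model evaluation
# ---------------------------------------------------------------------------

class TestModelEvaluation:
    def test_remaining_worked_values(self):
        p = RCMParams(10, 1000, 2)
        assert rcm_remaining(p, 0) == 10
        assert rcm_remaining(p, 1000) == pytest.approx(2.5)
        assert rcm_remaining(p, 1e9) < 1e-5  # asymptotic limit

    def test_dissolved_worked_values(self):
        p = RCMParams(10, 1000, 2)
        assert rcm_dissolved(p, 0) == 0
        assert rcm_dissolved(p, 1000) == pytest.approx(7.5)

    def test_rate_worked_values(self):
        assert rcm_rate(RCMParams(10, 1000, 2), 0) == pytest.approx(0.02)
        assert rcm_rate(RCMParams(10, 1000, 1), 1000) == pytest.approx(0.0025)

    def test_vectorizes_over_time(self):
        p = RCMParams(10, 1000, 2)
        t = np.array([0.0, 500.0, 1000.0])
        assert rcm_remaining(p, t).shape == (3,)
        np.testing.assert_allclose(
            rcm_dissolved(p, t), p.m0 - rcm_remaining(p, t)
        )

    @pytest.mark.parametrize("fn", [rcm_remaining, rcm_dissolved, rcm_rate])
    def test_negative_time_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(RCMParams(10, 1000, 2), -1.0)

    @pytest.mark.parametrize("bad", [dict(m0=0), dict(a=-1), dict(v=0), dict(m0=float("nan"))])
    def test_invalid_params_rejected(self, bad):
        kw = dict(m0=10.0, a=1000.0, v=2.0) | bad
        with pytest.raises(ValueError):
            RCMParams(**kw)

    @settings(deadline=None, derandomize=True)
    @given(p=params_strategy, t=time_strategy)
    def test_conservation(self, p, t):
        """Fe_d(t) + M(t) = M0 to machine precision for all t."""
        total = rcm_dissolved(p, t) + rcm_remaining(p, t)
        assert total == pytest.approx(p.m0, rel=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(p=params_strategy)
    def test_monotonicity(self, p):
        """Dissolved Fe non-decreasing, dissolution rate strictly decreasing."""
        t = np.linspace(0, 10 * p.a, 50)
        assert np.all(np.diff(rcm_dissolved(p, t)) >= 0)
        assert np.all(np.diff(rcm_rate(p, t)) < 0)

    @settings(deadline=None, derandomize=True)
    @given(p=params_strategy, t=st.floats(1.0, 1e6))
    def test_rate_is_negative_stock_derivative(self, p, t):
        """J(t) matches −dM/dt by central finite differences (rel err < 1e-6)."""
        # step on the curvature scale keeps cancellation ≪ truncation,
        # capped at t so the stencil stays inside the domain
        h = min(1e-5 * (p.a + t), t)
        dMdt = (rcm_remaining(p, t + h) - rcm_remaining(p, t - h)) / (2 * h)
        assert rcm_rate(p, t) == pytest.approx(-dMdt, rel=1e-6)

    def test_first_order_limit(self):
        """With k = v/a fixed and v large, M(t) approaches M0·exp(−kt)."""
        k, v = 1e-3, 1000.0
        p = RCMParams(m0=1.0, a=v / k, v=v)
        t = 1000.0
        expected = math.exp(-k * t)
        assert abs(rcm_remaining(p, t) - expected) / expected < 1e-3


# ---------------------------------------------------------------------------
# M0 from the plateau
# ---------------------------------------------------------------------------

def _curve(fe, times=None):
    fe = np.asarray(fe, dtype=float)
    t = np.arange(len(fe), dtype=float) * 600 if times is None else np.asarray(times)
    return DissolutionCurve(times=t, cumulative_fe=fe, dry_mass=1.0, volume=0.1)


class TestPlateauRule:
    def test_constant_tail_is_stable(self):
        m0, stable = estimate_m0(_curve([0, 5, 9, 10, 10, 10]))
        assert m0 == 10 and stable

    def test_rising_tail_is_unstable_but_still_reports_max(self):
        m0, stable = estimate_m0(_curve([0, 2, 5, 9.0, 9.5, 10.2]))
        assert m0 == pytest.approx(10.2)
        assert not stable

    def test_noiseless_curve_plateau_near_truncated_asymptote(
        self, reference_truth, schedule, noiseless_curve
    ):
        """Observed plateau sits within 2% of M0·(1−(a/(a+T))^v), and matches
        the maximum observed value exactly under the default rule."""
        m0, stable = estimate_m0(noiseless_curve)
        expected = rcm_dissolved(reference_truth, schedule[-1])
        assert m0 == pytest.approx(float(expected), rel=0.02)
        assert m0 == float(noiseless_curve.cumulative_fe.max())
        assert stable

    def test_tail_mean_rule(self):
        m0, stable = estimate_m0(
            _curve([0, 5, 9, 9.9, 10.1, 10.0]),
            PlateauRule(method="tail_mean", k=3, rel_window=0.05),
        )
        assert stable
        assert m0 == pytest.approx((9.9 + 10.1 + 10.0) / 3)

    def test_m0_at_least_max_observed_under_default_rule(self):
        fe = [0, 3, 7, 8, 8.2, 8.1]
        m0, _ = estimate_m0(_curve(fe))
        assert m0 >= max(fe)

    def test_too_short_curve_rejected(self):
        with pytest.raises(ValueError):
            estimate_m0(_curve([0, 1]))

    def test_plateau_onset_breaks_ties_at_earliest_time(self):
        c = _curve([0, 5, 10, 10, 10])
        assert plateau_onset(c) == 2 * 600


# ---------------------------------------------------------------------------
# Calibration of (a, v)
# ---------------------------------------------------------------------------

class TestFitRCM:
    def test_noiseless_recovery_on_field_schedule(self, reference_truth, noiseless_curve):
        """a and v recovered within 0.5% from a noiseless curve."""
        fit = fit_rcm(noiseless_curve, reference_truth.m0)
        assert fit.converged
        assert fit.params.a == pytest.approx(reference_truth.a, rel=0.005)
        assert fit.params.v == pytest.approx(reference_truth.v, rel=0.005)

    def test_residual_vector_length(self, reference_truth, noiseless_curve):
        fit = fit_rcm(noiseless_curve, reference_truth.m0)
        assert fit.residuals.shape == (fit.n_points,) == (len(noiseless_curve),)

    @pytest.mark.parametrize(
        "truth",
        [RCMParams(30, 5000, 1.5), RCMParams(8, 20000, 0.8), RCMParams(60, 1500, 3.0)],
        ids=["mid", "slow-heterogeneous", "fast-uniform"],
    )
    def test_matches_grid_search_oracle(self, truth, schedule):
        """NLS agrees with a 200×200 log-grid brute-force minimizer to within
        the grid resolution on noiseless instances."""
        curve = curve_from_truth(truth, schedule)
        fit = fit_rcm(curve, truth.m0)
        grid = grid_search_rcm(
            curve, truth.m0, a_bounds=(1e2, 1e6), v_bounds=(0.1, 10.0), n=200
        )
        step_a = (6 - 2) / 199  # log10 grid spacing
        step_v = 2 / 199
        assert abs(math.log10(fit.params.a) - math.log10(grid.a)) <= step_a
        assert abs(math.log10(fit.params.v) - math.log10(grid.v)) <= step_v

    def test_fit_idempotence(self, reference_truth, noiseless_curve):
        """Refitting a noiseless model curve from the recovered parameters
        reproduces them."""
        fit1 = fit_rcm(noiseless_curve, reference_truth.m0)
        model_curve = DissolutionCurve(
            times=noiseless_curve.times,
            cumulative_fe=np.asarray(rcm_dissolved(fit1.params, noiseless_curve.times)),
            dry_mass=noiseless_curve.dry_mass,
            volume=noiseless_curve.volume,
        )
        fit2 = fit_rcm(model_curve, fit1.params.m0)
        assert fit2.params.a == pytest.approx(fit1.params.a, rel=1e-6)
        assert fit2.params.v == pytest.approx(fit1.params.v, rel=1e-6)

    def test_deterministic(self, reference_truth, schedule):
        curve = curve_from_truth(reference_truth, schedule, noise_sd=0.05, seed=7)
        f1 = fit_rcm(curve, reference_truth.m0)
        f2 = fit_rcm(curve, reference_truth.m0)
        assert f1.params == f2.params

    def test_degenerate_all_zero_curve_rejected(self, schedule):
        zero = DissolutionCurve(
            times=schedule, cumulative_fe=np.zeros_like(schedule),
            dry_mass=1.0, volume=0.1,
        )
        with pytest.raises(ValueError):
            fit_rcm(zero, 10.0)

    def test_too_few_points_rejected(self):
        c = DissolutionCurve(
            times=np.array([0.0, 300, 600]),
            cumulative_fe=np.array([0.0, 1, 2]),
            dry_mass=1.0, volume=0.1,
        )
        with pytest.raises(ValueError):
            fit_rcm(c, 10.0)

    def test_noisy_recovery_of_reducibility(self, reference_truth, schedule):
        """5% multiplicative noise, 100 seeds: median relative error of the
        apparent rate constant v/a stays below 20%."""
        true_red = reference_truth.v / reference_truth.a
        errs = []
        for seed in range(100):
            curve = curve_from_truth(reference_truth, schedule, 0.05, seed)
            m0, _ = estimate_m0(curve)
            fit = fit_rcm(curve, m0)
            red = fit.params.v / fit.params.a
            errs.append(abs(red - true_red) / true_red)
        assert np.median(errs) < 0.2


# ---------------------------------------------------------------------------
# Derived parameters
# ---------------------------------------------------------------------------

class TestDerivedParams:
    @staticmethod
    def _fit_for(p: RCMParams) -> RCMFit:
        return RCMFit(
            params=p, m0_source="max", residuals=np.zeros(5),
            converged=True, n_points=5,
        )

    @pytest.mark.parametrize(
        "p, red, comp, lab",
        [
            (RCMParams(10, 1000, 2), 0.002, 1.5, 0.02),
            (RCMParams(10, 1000, 1), 0.001, 2.0, 0.01),
            (RCMParams(5, 2500, 1e4), 4.0, 1.0001, 20.0),  # uniform-pool limit
        ],
    )
    def test_formulas(self, p, red, comp, lab):
        d = derive_params(self._fit_for(p))
        assert d.reducibility == pytest.approx(red)
        assert d.composition == pytest.approx(comp)
        assert d.lability == pytest.approx(lab)

    @settings(deadline=None, derandomize=True)
    @given(p=params_strategy)
    def test_lability_identity(self, p):
        """lability = reducibility × M0 exactly; composition > 1."""
        d = derive_params(self._fit_for(p))
        assert d.lability == d.reducibility * p.m0
        assert d.composition > 1
        assert d.reducibility > 0

    def test_nonconverged_fit_refused(self):
        fit = RCMFit(
            params=RCMParams(10, 1000, 2), m0_source="max",
            residuals=np.zeros(5), converged=False, n_points=5,
        )
        with pytest.raises(ValueError):
            derive_params(fit)
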
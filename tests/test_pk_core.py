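"""One-compartment infusion model: closed form vs. ODE oracle and structure."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

from tigepk.pk_core import (
    CovariateError,
    DoseEvent,
    DosingRegimen,
    PatientCovariates,
    PKParameters,
    PopulationPriors,
    SAMPLING_TIMES_H,
    concentration_profile,
    default_regimen,
    individualize,
    simulate_standard_grid,
    steady_state_trough,
    typical_clearance,
    typical_volume,
)


def ode_profile(regimen, params, times):
    """Numerical oracle: integrate dC/dt = R(t)/V - (CL/V) C."""

    def rate_in(t):
        total = 0.0
        for ev in regimen.dose_events:
            if ev.start_time_h <= t < ev.start_time_h + ev.infusion_duration_h:
                total += ev.amount_mg / ev.infusion_duration_h
        return total

    def rhs(t, c):
        return [rate_in(t) / params.v - params.k_elim * c[0]]

    # integrate piecewise between infusion switch points for accuracy
    switch = sorted(
        {0.0, *[ev.start_time_h for ev in regimen.dose_events],
         *[ev.start_time_h + ev.infusion_duration_h for ev in regimen.dose_events],
         *times}
    )
    c, out = 0.0, {}
    for a, b in zip(switch, switch[1:]):
        sol = solve_ivp(rhs, (a, b), [c], rtol=1e-10, atol=1e-12, dense_output=True)
        c = sol.y[0, -1]
        for t in times:
            if a < t <= b:
                out[t] = sol.sol(t)[0]
    out.setdefault(0.0, 0.0)
    return np.array([out.get(t, 0.0) for t in times]) * 1000.0


class TestTypicalValues:
    @pytest.mark.parametrize(
        "apache2,expected", [(0, 11.30), (10, 9.90), (15, 9.20)]
    )
    def test_clearance_linear_in_apache(self, apache2, expected):
        assert typical_clearance(apache2) == pytest.approx(expected)

    @pytest.mark.parametrize("age,expected", [(0, 105.00), (50, 74.025), (62, 66.591)])
    def test_volume_linear_in_age(self, age, expected):
        assert typical_volume(age) == pytest.approx(expected, abs=1e-3)

    def test_out_of_range_covariates_raise(self):
        with pytest.raises(CovariateError, match="clearance"):
            typical_clearance(81)
        with pytest.raises(CovariateError, match="volume"):
            typical_volume(170)
        with pytest.raises(CovariateError):
            typical_clearance(-1)

    def test_covariate_container_bounds(self):
        with pytest.raises(CovariateError):
            PatientCovariates(age=12, apache2=10, first_dose_mg=100)
        with pytest.raises(CovariateError):
            PatientCovariates(age=60, apache2=75, first_dose_mg=100)
        with pytest.raises(CovariateError):
            PatientCovariates(age=60, apache2=10, first_dose_mg=0)


class TestIndividualize:
    def test_zero_etas_give_typical_values(self):
        cov = PatientCovariates(50, 10, 100)
        p = individualize(PopulationPriors(), cov, 0.0, 0.0)
        assert p.cl == pytest.approx(9.90)
        assert p.v == pytest.approx(74.025)

    def test_exponential_scaling(self):
        cov = PatientCovariates(50, 10, 100)
        p = individualize(PopulationPriors(), cov, np.log(2.0), 0.0)
        assert p.cl == pytest.approx(2 * 9.90)

    def test_log_scale_variance_matches_prior(self, rng):
        """Monte-Carlo: var(log CL) over prior draws equals omega2_cl within 3 SE."""
        n = 100_000
        priors = PopulationPriors()
        etas = rng.normal(0, np.sqrt(priors.omega2_cl), n)
        cov = PatientCovariates(50, 10, 100)
        log_cl = np.log([individualize(priors, cov, e).cl for e in etas[:1000]])
        # analytic shortcut for the full draw: log CL = log(typical) + eta
        var_full = np.var(np.log(typical_clearance(10)) + etas, ddof=1)
        se = priors.omega2_cl * np.sqrt(2.0 / (n - 1))
        assert abs(var_full - priors.omega2_cl) < 3 * se
        assert np.var(log_cl, ddof=1) == pytest.approx(np.var(etas[:1000], ddof=1), rel=1e-9)


class TestConcentrationProfile:
    def test_single_dose_closed_form_value(self):
        regimen = DosingRegimen((DoseEvent(0.0, 100.0, 1.0),))
        params = PKParameters(cl=10.0, v=100.0)
        prof = concentration_profile(regimen, params, [1.0])
        assert prof.conc_ng_ml[0] == pytest.approx(951.6258, abs=1e-3)

    def test_matches_ode_oracle(self, rng):
        regimen = default_regimen(100.0)
        for _ in range(10):
            params = PKParameters(cl=rng.uniform(3, 15), v=rng.uniform(30, 120))
            times = np.sort(rng.uniform(0.5, 90, 6))
            closed = concentration_profile(regimen, params, times).conc_ng_ml
            numeric = ode_profile(regimen, params, list(times))
            np.testing.assert_allclose(closed, numeric, rtol=1e-6)

    def test_superposition(self):
        params = PKParameters(cl=8.0, v=70.0)
        times = np.linspace(0, 48, 97)
        both = DosingRegimen((DoseEvent(0, 50, 1), DoseEvent(12, 50, 1)))
        first = DosingRegimen((DoseEvent(0, 50, 1),))
        second = DosingRegimen((DoseEvent(12, 50, 1),))
        c_both = concentration_profile(both, params, times).conc_ng_ml
        c_sum = (concentration_profile(first, params, times).conc_ng_ml
                 + concentration_profile(second, params, times).conc_ng_ml)
        np.testing.assert_allclose(c_both, c_sum, rtol=1e-10, atol=1e-12)

    @given(scale=st.floats(0.1, 10.0))
    def test_dose_linearity(self, scale):
        params = PKParameters(cl=8.0, v=70.0)
        times = np.array([2.0, 13.0, 30.0])
        base = DosingRegimen((DoseEvent(0, 100, 1), DoseEvent(12, 50, 1)))
        scaled = DosingRegimen((DoseEvent(0, 100 * scale, 1), DoseEvent(12, 50 * scale, 1)))
        c0 = concentration_profile(base, params, times).conc_ng_ml
        c1 = concentration_profile(scaled, params, times).conc_ng_ml
        np.testing.assert_allclose(c1, scale * c0, rtol=1e-9)

    def test_zero_before_first_dose_and_zero_doses(self):
        params = PKParameters(cl=8.0, v=70.0)
        regimen = DosingRegimen((DoseEvent(10.0, 100.0, 1.0),))
        prof = concentration_profile(regimen, params, [0.0, 5.0, 9.99])
        assert np.all(prof.conc_ng_ml == 0.0)
        zero = DosingRegimen((DoseEvent(0.0, 0.0, 1.0),))
        assert np.all(concentration_profile(zero, params, [1.0, 5.0]).conc_ng_ml == 0.0)

    def test_empty_times_and_negative_time(self):
        params = PKParameters(cl=8.0, v=70.0)
        regimen = default_regimen(100.0)
        assert concentration_profile(regimen, params, []).conc_ng_ml.size == 0
        with pytest.raises(ValueError):
            concentration_profile(regimen, params, [-1.0])

    def test_regimen_validation(self):
        with pytest.raises(ValueError):
            DosingRegimen((DoseEvent(12, 50, 1), DoseEvent(0, 50, 1)))
        with pytest.raises(ValueError):
            DoseEvent(0, 50, 0.0)


class TestSteadyStateTrough:
    def test_matches_long_run_simulation(self):
        params = PKParameters(cl=9.2, v=66.6)
        dose, tau, dur = 50.0, 12.0, 1.0
        n_dose = 200
        events = tuple(DoseEvent(i * tau, dose, dur) for i in range(n_dose))
        regimen = DosingRegimen(events, observation_horizon_h=n_dose * tau + tau)
        t_probe = n_dose * tau - 1e-9
        sim = concentration_profile(regimen, params, [t_probe]).conc_ng_ml[0]
        assert steady_state_trough(dose, tau, dur, params) == pytest.approx(sim, rel=1e-3)

    def test_fast_elimination_limit_and_linearity(self):
        params = PKParameters(cl=10.0, v=0.001)
        assert steady_state_trough(50, 12, 1, params) == pytest.approx(0.0, abs=1e-9)
        params = PKParameters(cl=9.0, v=70.0)
        single = steady_state_trough(50, 12, 1, params)
        assert steady_state_trough(100, 12, 1, params) == pytest.approx(2 * single)

    def test_interval_must_exceed_infusion(self):
        with pytest.raises(ValueError):
            steady_state_trough(50, 1.0, 1.0, PKParameters(cl=9, v=70))


class TestStandardGrid:
    def test_trough_sequence_approaches_steady_state(self):
        cov = PatientCovariates(age=62, apache2=15, first_dose_mg=100)
        prof = simulate_standard_grid(cov)
        grid = dict(zip(prof.times_h, prof.conc_ng_ml))
        troughs = [grid[t] for t in (12, 24, 36, 48, 60, 72)]
        assert all(a > b for a, b in zip(troughs, troughs[1:]))
        # geometric approach: successive 12-h differences shrink strictly
        diffs = [abs(b - a) for a, b in zip(troughs, troughs[1:])]
        assert all(d1 > d2 for d1, d2 in zip(diffs, diffs[1:]))
        # asymptote equals the closed-form steady-state trough within 0.1%
        params = individualize(PopulationPriors(), cov)
        ss = steady_state_trough(50.0, 12.0, 1.0, params)
        assert grid[72] == pytest.approx(ss, rel=1e-3)
        # rebound 2 h into the post-72-h dose, partial washout at 78 h
        assert grid[74] > grid[72]
        assert grid[74] > grid[78] > grid[72]

    def test_grid_is_the_ten_point_design(self):
        assert SAMPLING_TIMES_H == (4, 8, 12, 24, 36, 48, 60, 72, 74, 78)
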
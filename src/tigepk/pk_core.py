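"""Covariate-parameterized one-compartment IV-infusion pharmacokinetics.

Tigecycline disposition is described by a one-compartment model with
zero-order (constant-rate) infusion input and first-order elimination.
The population model carries two fixed-effect covariate relationships:

    CL (L/h) = (11.30 - 0.14 * APACHEII) * exp(eta_CL),  eta_CL ~ N(0, 0.065)
    V  (L)   = 105.00 * (1 - 0.0059 * AGE) * exp(eta_V), eta_V  ~ N(0, 0.160)

i.e. a linear covariate effect on the typical value and log-normal
inter-individual variability, the standard NONMEM-style parameterization.
Clearance falls with illness severity (APACHE II score) and the apparent
volume of distribution falls with age.

Concentrations are computed in closed form by superposition of
single-infusion solutions.  For one dose of rate ``R = amount / T_inf``
starting at time 0, with ``k = CL/V``::

    C(t) = (R/CL) * (1 - exp(-k*t))                          0 <= t <= T_inf
    C(t) = (R/CL) * (1 - exp(-k*T_inf)) * exp(-k*(t-T_inf))  t > T_inf

Internal units are mg and L (so mg/L); reported concentrations are ng/mL
(mg/L x 1000), the scale on which clinical tigecycline levels are quoted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SAMPLING_TIMES_H",
    "CovariateError",
    "PatientCovariates",
    "PopulationPriors",
    "PKParameters",
    "DoseEvent",
    "DosingRegimen",
    "ConcentrationProfile",
    "typical_clearance",
    "typical_volume",
    "individualize",
    "default_regimen",
    "concentration_matrix",
    "concentration_profile",
    "steady_state_trough",
    "simulate_standard_grid",
]

#: Post-first-dose sampling grid (hours) used throughout the analysis:
#: early distribution phase, successive 12-h troughs approaching steady
#: state, and two samples 2 h / 6 h after the 72-h maintenance dose.
SAMPLING_TIMES_H: tuple[float, ...] = (4.0, 8.0, 12.0, 24.0, 36.0, 48.0, 60.0, 72.0, 74.0, 78.0)

MG_PER_L_TO_NG_PER_ML = 1000.0


class CovariateError(ValueError):
    """A covariate value puts a structural parameter outside its valid range."""


@dataclass(frozen=True)
class PatientCovariates:
    """Covariates entering the population model.

    Parameters
    ----------
    age : int
        Age in years, 14-120 (adult/adolescent use only).
    apache2 : int
        APACHE II severity-of-illness score, 0-71 (the score's defined range).
    first_dose_mg : float
        Initial (loading) tigecycline dose in mg.
    """

    age: float
    apache2: float
    first_dose_mg: float

    def __post_init__(self) -> None:
        if not 14 <= self.age <= 120:
            raise CovariateError(f"age must be in [14, 120] years, got {self.age}")
        if not 0 <= self.apache2 <= 71:
            raise CovariateError(f"APACHE II score must be in [0, 71], got {self.apache2}")
        if not self.first_dose_mg > 0:
            raise CovariateError(f"first dose must be positive, got {self.first_dose_mg}")


@dataclass(frozen=True)
class PopulationPriors:
    """Population fixed effects and random-effect variances.

    ``omega2_*`` are variances of the log-scale inter-individual random
    effects; ``sigma_prop`` is the proportional residual-error CV used by
    the MAP individualization step.
    """

    theta_cl_intercept: float = 11.30       # L/h at APACHE II = 0
    theta_cl_apache_slope: float = 0.14     # L/h lost per APACHE II point
    theta_v_intercept: float = 105.00       # L at age 0 (extrapolated intercept)
    theta_v_age_slope: float = 0.0059       # fractional volume loss per year
    omega2_cl: float = 0.065
    omega2_v: float = 0.160
    sigma_prop: float = 0.20

    def __post_init__(self) -> None:
        if self.omega2_cl <= 0 or self.omega2_v <= 0:
            raise ValueError("random-effect variances must be positive")
        if self.theta_cl_intercept <= 0 or self.theta_v_intercept <= 0:
            raise ValueError("typical-value intercepts must be positive")
        if self.sigma_prop <= 0:
            raise ValueError("proportional residual CV must be positive")


@dataclass(frozen=True)
class PKParameters:
    """Individual clearance/volume with the random effects that produced them."""

    cl: float
    v: float
    eta_cl: float = 0.0
    eta_v: float = 0.0

    def __post_init__(self) -> None:
        if self.cl <= 0 or self.v <= 0:
            raise ValueError("clearance and volume must be positive")

    @property
    def k_elim(self) -> float:
        """First-order elimination rate constant CL/V (1/h)."""
        return self.cl / self.v


@dataclass(frozen=True)
class DoseEvent:
    start_time_h: float
    amount_mg: float
    infusion_duration_h: float

    def __post_init__(self) -> None:
        if self.amount_mg < 0:
            raise ValueError("dose amount must be non-negative")
        if self.infusion_duration_h <= 0:
            raise ValueError("infusion duration must be positive")


@dataclass(frozen=True)
class DosingRegimen:
    """An ordered sequence of infusion events plus the observation horizon."""

    dose_events: tuple[DoseEvent, ...]
    observation_horizon_h: float = 96.0

    def __post_init__(self) -> None:
        starts = [ev.start_time_h for ev in self.dose_events]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("dose start times must be strictly increasing")
        if self.observation_horizon_h <= 0:
            raise ValueError("observation horizon must be positive")


@dataclass(frozen=True)
class ConcentrationProfile:
    """Concentration-time grid in ng/mL."""

    times_h: np.ndarray
    conc_ng_ml: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        c = np.asarray(self.conc_ng_ml, dtype=float)
        if t.shape != c.shape:
            raise ValueError("times and concentrations must have equal length")
        if t.size and np.any(np.diff(t) < 0):
            raise ValueError("times must be sorted")
        if np.any(c < -1e-12):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "conc_ng_ml", c)


def typical_clearance(apache2: float, priors: PopulationPriors | None = None) -> float:
    """Typical (fixed-effect) clearance in L/h at a given APACHE II score.

    Raises
    ------
    CovariateError
        If the linear covariate model yields a non-positive clearance
        (APACHE II >= intercept/slope, i.e. >= 81 at the default
        coefficients).
    """
    priors = priors or PopulationPriors()
    if apache2 < 0:
        raise CovariateError(f"APACHE II score must be >= 0, got {apache2}")
    cl = priors.theta_cl_intercept - priors.theta_cl_apache_slope * apache2
    if cl <= 0:
        bound = priors.theta_cl_intercept / priors.theta_cl_apache_slope
        raise CovariateError(
            f"APACHE II = {apache2} gives non-positive typical clearance "
            f"(model valid only for scores < {bound:.2f})"
        )
    return cl


def typical_volume(age: float, priors: PopulationPriors | None = None) -> float:
    """Typical (fixed-effect) volume of distribution in L at a given age."""
    priors = priors or PopulationPriors()
    if age < 0:
        raise CovariateError(f"age must be >= 0, got {age}")
    v = priors.theta_v_intercept * (1.0 - priors.theta_v_age_slope * age)
    if v <= 0:
        bound = 1.0 / priors.theta_v_age_slope
        raise CovariateError(
            f"age = {age} gives non-positive typical volume "
            f"(model valid only for ages < {bound:.1f})"
        )
    return v


def individualize(
    priors: PopulationPriors,
    cov: PatientCovariates,
    eta_cl: float = 0.0,
    eta_v: float = 0.0,
) -> PKParameters:
    """Apply log-normal random effects to the typical values."""
    cl = typical_clearance(cov.apache2, priors) * float(np.exp(eta_cl))
    v = typical_volume(cov.age, priors) * float(np.exp(eta_v))
    return PKParameters(cl=cl, v=v, eta_cl=eta_cl, eta_v=eta_v)


def default_regimen(
    first_dose_mg: float,
    maintenance_fraction: float = 0.5,
    interval_h: float = 12.0,
    infusion_duration_h: float = 1.0,
    horizon_h: float = 96.0,
) -> DosingRegimen:
    """Loading dose at t=0 then half-dose maintenance every 12 h.

    This mirrors labeled tigecycline use (loading dose, then half that
    amount q12h as a 30-60 min infusion) and produces the characteristic
    profile on :data:`SAMPLING_TIMES_H`: declining 12-h troughs settling to
    a steady-state plateau, then a rebound at 74 h (2 h into the post-72-h
    dose) and partial washout at 78 h.
    """
    if first_dose_mg <= 0:
        raise ValueError("first dose must be positive")
    events = [DoseEvent(0.0, first_dose_mg, infusion_duration_h)]
    t = interval_h
    while t < horizon_h:
        events.append(DoseEvent(t, first_dose_mg * maintenance_fraction, infusion_duration_h))
        t += interval_h
    return DosingRegimen(tuple(events), observation_horizon_h=horizon_h)


def concentration_matrix(
    times_h: np.ndarray,
    dose_events: tuple[DoseEvent, ...],
    cl: np.ndarray | float,
    v: np.ndarray | float,
) -> np.ndarray:
    """Superposed closed-form concentrations in ng/mL, broadcast over patients.

    ``cl`` and ``v`` may be scalars or arrays of shape ``(P, 1)`` to
    simulate a whole cohort against a shared time grid at once; the result
    broadcasts to ``(P, T)``.
    """
    times = np.asarray(times_h, dtype=float)
    if times.size and np.any(times < 0):
        raise ValueError("requested times must be non-negative")
    cl_arr = np.asarray(cl, dtype=float)
    v_arr = np.asarray(v, dtype=float)
    if np.any(cl_arr <= 0) or np.any(v_arr <= 0):
        raise ValueError("clearance and volume must be positive")
    k = cl_arr / v_arr
    conc = np.zeros(np.broadcast_shapes(k.shape, times.shape))
    for ev in dose_events:
        if ev.amount_mg == 0:
            continue
        rate = ev.amount_mg / ev.infusion_duration_h
        tau = times - ev.start_time_h
        t_on = np.clip(tau, 0.0, ev.infusion_duration_h)   # time infused so far
        t_off = np.maximum(tau - ev.infusion_duration_h, 0.0)
        conc = conc + (rate / cl_arr) * (1.0 - np.exp(-k * t_on)) * np.exp(-k * t_off)
    return conc * MG_PER_L_TO_NG_PER_ML


def concentration_profile(
    regimen: DosingRegimen,
    params: PKParameters,
    times_h,
) -> ConcentrationProfile:
    """Simulate one patient's concentration-time profile (ng/mL)."""
    times = np.asarray(times_h, dtype=float)
    if times.size == 0:
        return ConcentrationProfile(times, np.zeros(0))
    conc = concentration_matrix(times, regimen.dose_events, params.cl, params.v)
    return ConcentrationProfile(times, np.asarray(conc, dtype=float))


def steady_state_trough(
    maintenance_dose_mg: float,
    interval_h: float,
    infusion_duration_h: float,
    params: PKParameters,
) -> float:
    """Closed-form pre-dose concentration (ng/mL) at steady state.

    For repeated infusions of rate ``R`` over ``T_inf`` every ``tau`` hours::

        C_trough = (R/CL) (1 - e^{-k T_inf}) e^{-k (tau - T_inf)} / (1 - e^{-k tau})
    """
    if maintenance_dose_mg <= 0 or interval_h <= 0 or infusion_duration_h <= 0:
        raise ValueError("dose, interval and infusion duration must be positive")
    if interval_h <= infusion_duration_h:
        raise ValueError("dosing interval must exceed the infusion duration")
    k = params.k_elim
    rate = maintenance_dose_mg / infusion_duration_h
    single = (rate / params.cl) * (1.0 - np.exp(-k * infusion_duration_h))
    trough = single * np.exp(-k * (interval_h - infusion_duration_h)) / (1.0 - np.exp(-k * interval_h))
    return float(trough * MG_PER_L_TO_NG_PER_ML)


def simulate_standard_grid(
    cov: PatientCovariates,
    priors: PopulationPriors | None = None,
    eta_cl: float = 0.0,
    eta_v: float = 0.0,
    regimen: DosingRegimen | None = None,
) -> ConcentrationProfile:
    """Simulate the 10-point post-first-dose grid under the default regimen."""
    priors = priors or PopulationPriors()
    params = individualize(priors, cov, eta_cl, eta_v)
    regimen = regimen or default_regimen(cov.first_dose_mg)
    return concentration_profile(regimen, params, np.array(SAMPLING_TIMES_H))
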
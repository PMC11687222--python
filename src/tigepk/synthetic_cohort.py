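"""Seeded generator of a virtual two-site tigecycline cohort.

The generator emulates the statistical structure the analysis pipeline
assumes for a 263-patient, two-site pulmonary-infection cohort:

* site sizes in the 200:63 proportion;
* liver-status groups drawn with probabilities 202/263, 50/263, 11/263
  (none / injury / hepatotoxicity);
* hospitalization days per group from log-normals calibrated so the group
  medians are 20 / 23 / 30 days and the means 25 / 26 / 32 days
  (sigma^2 = 2 ln(mean/median));
* age ~ truncated normal(62, 18) on [14, 98]; APACHE II ~ truncated
  normal(15, 6) on [3, 40]; loading dose 50 or 100 mg;
* ALT/bilirubin series constructed so that the liver-status rules
  reclassify every patient into their generative group, exactly;
* a laboratory panel drawn around published reference intervals, with
  group-level shifts (in SD units) on AST, GGT, MCHC and MPV;
* the 10-point concentration grid simulated through the population PK
  model with the patient's own random effects plus 20% proportional
  observation noise.

APACHE II and laboratory distributions and the effect sizes are synthetic
choices (literature-plausible defaults held in :class:`CohortConfig`);
only the group proportions, age summaries and hospitalization-day
calibration come from the emulated cohort's published summaries.

Two hospitalization-day modes exist because a real LOS-generating process
is unknowable: ``distributional`` (pure per-group log-normals, for
group-summary work) and ``feature_linked`` (a smooth function of age,
APACHE II, dose and labs plus N(0, 0.5^2) noise, giving the days
regressor a learnable target with a known noise floor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .pk_core import (
    PopulationPriors,
    SAMPLING_TIMES_H,
    concentration_matrix,
    default_regimen,
)

__all__ = [
    "LAB_REFERENCE",
    "FEATURE_COLUMNS",
    "CohortConfig",
    "CohortBundle",
    "generate_cohort",
    "los_model",
    "lab_model",
    "feature_matrix",
    "write_cohort",
]

#: Reference intervals (mean, SD) for the laboratory panel. Synthetic,
#: literature-plausible adult values; units as commonly reported.
LAB_REFERENCE: dict[str, tuple[float, float]] = {
    "EO#": (0.15, 0.10),     # x10^9/L
    "EO%": (2.0, 1.5),       # %
    "HCT": (0.40, 0.05),     # L/L
    "HGB": (135.0, 15.0),    # g/L
    "MCH": (29.0, 2.0),      # pg
    "MCHC": (335.0, 12.0),   # g/L
    "MCV": (90.0, 5.0),      # fL
    "MPV": (10.0, 1.0),      # fL
    "PCT": (0.22, 0.06),     # %
    "PLT": (250.0, 60.0),    # x10^9/L
    "WBC": (9.0, 3.0),       # x10^9/L
    "RH": (4.5, 0.6),        # hemorheology index
    "A/G": (1.5, 0.3),       # ratio
    "AST": (26.0, 8.0),      # U/L
    "GGT": (35.0, 15.0),     # U/L
    "TP": (70.0, 6.0),       # g/L
    "Urea": (6.5, 2.5),      # mmol/L
}

_CONC_COLUMNS = [f"conc_{t:g}h" for t in SAMPLING_TIMES_H]

#: Predictor feature set: demographics/dose/severity, the full lab panel,
#: peak ALT during treatment, and the simulated concentration grid.
FEATURE_COLUMNS: list[str] = ["age", "apache2", "dose_mg", *LAB_REFERENCE, "ALT", *_CONC_COLUMNS]

#: TDM-style sampling design for the MAP-feedback observations: the
#: post-loading peak plus pre-dose troughs near 24, 48 and 72 h.
OBSERVATION_TIMES_H: tuple[float, ...] = (2.0, 24.0, 47.5, 71.5)

_ALT_SERIES_DAYS = (1.0, 3.0, 5.0, 7.0)


@dataclass(frozen=True)
class CohortConfig:
    n_total: int = 263
    site_fractions: tuple[float, float] = (200 / 263, 63 / 263)
    group_probs: tuple[float, float, float] = (202 / 263, 50 / 263, 11 / 263)
    age_mean: float = 62.0
    age_sd: float = 18.0
    age_bounds: tuple[float, float] = (14.0, 98.0)
    apache_mean: float = 15.0
    apache_sd: float = 6.0
    apache_bounds: tuple[float, float] = (3.0, 40.0)
    doses_mg: tuple[float, ...] = (50.0, 100.0)
    dose_probs: tuple[float, ...] = (0.5, 0.5)
    los_median: tuple[float, float, float] = (20.0, 23.0, 30.0)
    los_mean: tuple[float, float, float] = (25.0, 26.0, 32.0)
    los_mode: str = "distributional"           # or "feature_linked"
    feature_link_noise_sd: float = 0.5
    lab_effects: tuple[tuple[str, float], ...] = (("AST", 1.0), ("GGT", 1.0), ("MCHC", -0.6), ("MPV", 0.4))
    conc_noise_cv: float = 0.20
    priors: PopulationPriors = field(default_factory=PopulationPriors)

    def __post_init__(self) -> None:
        if abs(sum(self.group_probs) - 1.0) > 1e-9:
            raise ValueError("group probabilities must sum to 1")
        if abs(sum(self.site_fractions) - 1.0) > 1e-9:
            raise ValueError("site fractions must sum to 1")
        if any(m <= 0 for m in self.los_median):
            raise ValueError("hospitalization-day medians must be positive")
        if self.los_mode not in ("distributional", "feature_linked"):
            raise ValueError(f"unknown los_mode {self.los_mode!r}")
        if self.n_total < 2:
            raise ValueError("n_total too small")

    def site_sizes(self) -> tuple[int, int]:
        n1 = int(round(self.n_total * self.site_fractions[0]))
        return n1, self.n_total - n1


@dataclass(frozen=True)
class CohortBundle:
    patients: pd.DataFrame        # one row per patient: covariates, labs panel, grid, group, days
    labs: pd.DataFrame            # long: patient_id, day, alt, bilirubin
    observations: pd.DataFrame    # long: patient_id, time_h, conc_ng_ml


def _lognormal_sigma(median: float, mean: float) -> float:
    ratio = mean / median
    if ratio < 1.0:
        raise ValueError("log-normal requires mean >= median")
    if ratio == 1.0:
        warnings.warn("mean equals median: degenerate (sigma=0) hospitalization-day model")
        return 0.0
    return float(np.sqrt(2.0 * np.log(ratio)))


def los_model(group, config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Distributional hospitalization days: per-group log-normal draws."""
    group = np.asarray(group, dtype=int)
    mu = np.log(np.asarray(config.los_median, dtype=float))
    sigma = np.array([_lognormal_sigma(m, mn) for m, mn in zip(config.los_median, config.los_mean)])
    z = rng.standard_normal(group.size)
    return np.exp(mu[group] + sigma[group] * z)


def _los_feature_link(age, apache2, dose, ast, wbc, mchc) -> np.ndarray:
    """Smooth additive map from predictor features to expected days."""
    return (
        22.0
        + 5.0 * np.tanh((age - 62.0) / 18.0)
        + 4.0 * np.tanh((apache2 - 15.0) / 6.0)
        + 3.0 * np.tanh((ast - 26.0) / 12.0)
        + 2.0 * np.tanh((wbc - 9.0) / 3.0)
        - 2.0 * np.tanh((mchc - 335.0) / 12.0)
        + 1.5 * (dose - 75.0) / 25.0
    )


def lab_model(group, config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Laboratory panel draws with group-severity shifts on selected analytes."""
    group = np.asarray(group, dtype=int)
    n = group.size
    panel = {}
    effects = dict(config.lab_effects)
    for analyte, (mean, sd) in LAB_REFERENCE.items():
        values = rng.normal(mean, sd, size=n)
        if analyte in effects:
            values = values + effects[analyte] * sd * group
        panel[analyte] = values
    return pd.DataFrame(panel)


def _alt_bili_series(group, rng: np.random.Generator):
    """(n, 4) ALT and bilirubin series that reclassify into their group.

    NONE: all ALT in (12, 38), below ULN. INJURY: two consecutive values in
    (45, 115) c (40, 120]. HEPATOTOXICITY: two consecutive values in
    (130, 300), above 3xULN. Bilirubin stays normal throughout (the
    hepatotoxicity labels here arise via the ALT route).
    """
    group = np.asarray(group, dtype=int)
    n = group.size
    alt = rng.uniform(12.0, 38.0, size=(n, 4))
    inj = group == 1
    hep = group == 2
    alt[inj, 1] = rng.uniform(45.0, 115.0, size=int(inj.sum()))
    alt[inj, 2] = rng.uniform(45.0, 115.0, size=int(inj.sum()))
    alt[hep, 1] = rng.uniform(130.0, 300.0, size=int(hep.sum()))
    alt[hep, 2] = rng.uniform(130.0, 300.0, size=int(hep.sum()))
    alt[hep, 3] = rng.uniform(40.0, 100.0, size=int(hep.sum()))
    bili = rng.uniform(5.0, 15.0, size=(n, 4))
    return alt, bili


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: CohortConfig | None = None, seed: int = 42) -> CohortBundle:
    """Draw a full synthetic cohort; deterministic given (config, seed)."""
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    n = config.n_total
    n1, _ = config.site_sizes()
    site = np.where(np.arange(n) < n1, 1, 2)

    group = rng.choice(3, size=n, p=config.group_probs)
    age = np.round(_truncated_normal(rng, config.age_mean, config.age_sd, *config.age_bounds, n))
    apache2 = np.round(_truncated_normal(rng, config.apache_mean, config.apache_sd, *config.apache_bounds, n))
    dose = rng.choice(config.doses_mg, size=n, p=config.dose_probs)

    priors = config.priors
    eta_cl = rng.normal(0.0, np.sqrt(priors.omega2_cl), n)
    eta_v = rng.normal(0.0, np.sqrt(priors.omega2_v), n)
    cl = (priors.theta_cl_intercept - priors.theta_cl_apache_slope * apache2) * np.exp(eta_cl)
    v = priors.theta_v_intercept * (1.0 - priors.theta_v_age_slope * age) * np.exp(eta_v)

    # dose linearity: simulate a unit (1 mg loading) regimen once, scale by dose
    unit = default_regimen(1.0)
    grid = np.asarray(SAMPLING_TIMES_H)
    conc_clean = concentration_matrix(grid, unit.dose_events, cl[:, None], v[:, None]) * dose[:, None]
    noise = np.clip(1.0 + rng.normal(0.0, config.conc_noise_cv, size=conc_clean.shape), 0.05, None)
    conc = conc_clean * noise

    obs_times = np.asarray(OBSERVATION_TIMES_H)
    obs_clean = concentration_matrix(obs_times, unit.dose_events, cl[:, None], v[:, None]) * dose[:, None]
    obs_noise = np.clip(1.0 + rng.normal(0.0, config.conc_noise_cv, size=obs_clean.shape), 0.05, None)
    obs_conc = obs_clean * obs_noise

    panel = lab_model(group, config, rng)
    alt_series, bili_series = _alt_bili_series(group, rng)

    if config.los_mode == "distributional":
        days = los_model(group, config, rng)
    else:
        expected = _los_feature_link(age, apache2, dose, panel["AST"].to_numpy(),
                                     panel["WBC"].to_numpy(), panel["MCHC"].to_numpy())
        days = np.clip(expected + rng.normal(0.0, config.feature_link_noise_sd, n), 1.0, None)

    patients = pd.DataFrame({
        "patient_id": np.arange(1, n + 1),
        "site": site,
        "group": group,
        "age": age.astype(int),
        "apache2": apache2.astype(int),
        "dose_mg": dose,
        "eta_cl": eta_cl,
        "eta_v": eta_v,
        "days": days,
    })
    for col in panel.columns:
        patients[col] = panel[col].to_numpy()
    patients["ALT"] = alt_series.max(axis=1)   # peak ALT during treatment
    for j, col in enumerate(_CONC_COLUMNS):
        patients[col] = conc[:, j]

    pid = np.repeat(np.arange(1, n + 1), len(_ALT_SERIES_DAYS))
    labs = pd.DataFrame({
        "patient_id": pid,
        "day": np.tile(_ALT_SERIES_DAYS, n),
        "alt": alt_series.ravel(),
        "bilirubin": bili_series.ravel(),
    })
    observations = pd.DataFrame({
        "patient_id": np.repeat(np.arange(1, n + 1), obs_times.size),
        "time_h": np.tile(obs_times, n),
        "conc_ng_ml": obs_conc.ravel(),
    })
    return CohortBundle(patients=patients, labs=labs, observations=observations)


def feature_matrix(patients: pd.DataFrame):
    """(X, days, abnormal) arrays for the predictor from a patients table."""
    X = patients[FEATURE_COLUMNS].to_numpy(dtype=float)
    days = patients["days"].to_numpy(dtype=float)
    abnormal = (patients["group"].to_numpy() > 0).astype(int)
    return X, days, abnormal


def write_cohort(bundle: CohortBundle, outdir) -> dict[str, Path]:
    """Write the CSV bundle consumed by the CLI stages."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": outdir / "patients.csv",
        "liver_labs": outdir / "liver_labs.csv",
        "observations": outdir / "observations.csv",
        "outcomes": outdir / "outcomes.csv",
    }
    bundle.patients.to_csv(paths["patients"], index=False)
    bundle.labs.to_csv(paths["liver_labs"], index=False)
    bundle.observations.to_csv(paths["observations"], index=False)
    bundle.patients[["patient_id", "group", "days"]].to_csv(paths["outcomes"], index=False)
    return paths
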
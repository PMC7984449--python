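"""Synthetic de novo Parkinson cohort generator with known causal effect.

The generator emulates the statistical structure the estimators assume:

* a continuous severity process on a biannual visit grid that worsens by
  ``drift_per_period`` points per half-year when untreated;
* confounded, monotone treatment initiation: at each visit an untreated
  patient starts treatment for the *next* period with probability
  ``logistic(alpha0 + alpha1 * z)``, where ``z`` is the current motor score
  standardized to the cohort's clinical range (three baseline SDs) —
  sicker patients start earlier, and per-visit hazards stay well inside
  (0, 1) so the positivity assumption the estimators rely on holds;
* an additive treatment effect on the severity *state* of
  ``treatment_effect_per_year`` points per treated year (negative =
  beneficial on a UPDRS-like scale), so the effect persists and the marginal
  causal effect of +1 treatment-year on any later annual outcome equals
  ``treatment_effect_per_year`` exactly;
* the primary motor score (``updrs3_off``) is the severity index itself;
  the four secondary scores are noisy affine maps of it, so the treatment
  decision depends only on covariates the estimators observe and measured-
  covariate exchangeability holds by construction;
* visit-level outcome missingness (failed off-state criteria) and optional
  covariate and treatment-flag missingness.

All randomness is driven by ``numpy.random.default_rng`` seeds: the same
config yields a bit-identical panel.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigError
from .panel import (
    BASELINE_COVARIATES,
    OUTCOME_HORIZONS,
    TV_COVARIATES,
    VISIT_GRID,
    CohortPanel,
)

#: Affine maps score = intercept + slope * (S - 21) + noise_scale * sigma_measure * N(0,1).
#: Intercepts/slopes chosen so baseline means and spreads resemble a de novo
#: PD cohort (motor score ~21 +/- 9, ADL ~93, MoCA ~27).  The primary motor
#: score is the severity index itself (slope 1, no measurement noise).
SCORE_MAPS: dict[str, tuple[float, float, float]] = {
    # name: (intercept at S=21, slope, noise_scale)
    "updrs3_off": (21.0, 1.0, 0.0),
    "updrs1": (5.6, 0.20, 1.0),
    "updrs2": (6.2, 0.25, 1.0),
    "mseadl": (92.8, -0.35, 1.5),
    "moca": (27.1, -0.05, 0.5),
}

#: Medication-class mix among treated patients (levodopa / dopamine agonist /
#: other / combination), matching the composition reported for early PD
#: (rounded percentages, renormalized to sum to 1).
REGIMEN_LABELS = ("levodopa", "dopamine_agonist", "other", "combination")
_raw = (0.45, 0.16, 0.13, 0.25)
REGIMEN_PROBS = tuple(p / sum(_raw) for p in _raw)


@dataclass(frozen=True)
class BaselineCovariateParams:
    """Distributions of the time-fixed covariates."""

    age_mean: float = 61.3
    age_sd: float = 9.7
    education_mean: float = 15.6
    education_sd: float = 2.9
    sex_male_prop: float = 0.67
    cardiovascular_prop: float = 0.30
    disease_duration_mean: float = 0.5  # exponential: SD = mean


@dataclass(frozen=True)
class DGPConfig:
    """Full parameterization of the synthetic cohort generator."""

    n_patients: int = 2000
    seed: int = 0
    severity_baseline_mean: float = 21.0
    severity_baseline_sd: float = 9.0
    drift_per_period: float = 1.0
    treatment_effect_per_year: float = -1.5
    initiation_intercept: float = -1.5
    initiation_severity_slope: float = 3.0
    sigma_progress: float = 1.0
    sigma_measure: float = 2.0
    baseline_covariate_params: BaselineCovariateParams = field(
        default_factory=BaselineCovariateParams
    )
    missing_outcome_prob: float = 0.2
    missing_visit_prob: float = 0.0
    missing_treatment_prob: float = 0.0
    #: additive offset on the measured motor score while on treatment
    #: (purely symptomatic component; 0 = all effect through the state).
    symptomatic_offset: float = 0.0

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        for name in ("severity_baseline_sd", "sigma_progress"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.sigma_measure < 0:
            raise ConfigError("sigma_measure must be >= 0")
        for name in ("missing_outcome_prob", "missing_visit_prob", "missing_treatment_prob"):
            p = getattr(self, name)
            if not (0.0 <= p < 1.0):
                raise ConfigError(f"{name} must be in [0, 1), got {p}")

    @property
    def visit_grid(self) -> tuple[float, ...]:
        return VISIT_GRID


@dataclass(frozen=True)
class GroundTruth:
    """True marginal causal effect of +1 treatment-year on the annual outcome."""

    beta_true: float


def true_effect(config: DGPConfig) -> float:
    """Closed-form estimand: the generator's additive per-treated-year effect.

    The treatment effect enters the severity state additively and severity
    maps to the outcome with slope 1, so for any policy duration d,
    E[Y(d+1)] - E[Y(d)] = treatment_effect_per_year at every horizon.  (A
    nonzero symptomatic offset shifts all started policies equally at the
    annual assessments and leaves the slope unchanged.)
    """
    return float(config.treatment_effect_per_year)


def simulate_cohort(config: DGPConfig) -> tuple[CohortPanel, GroundTruth]:
    """Generate a complete cohort panel (no missingness applied).

    Returns the panel and the ground-truth effect.  Apply
    :func:`apply_missingness` afterwards to emulate failed off-state outcome
    assessments.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    grid = np.array(VISIT_GRID)
    T = len(grid)
    bp = config.baseline_covariate_params

    base = {
        "age": rng.normal(bp.age_mean, bp.age_sd, n),
        "sex": (rng.random(n) < bp.sex_male_prop).astype(int),
        "education": np.clip(rng.normal(bp.education_mean, bp.education_sd, n), 0.0, None),
        "cardiovascular": (rng.random(n) < bp.cardiovascular_prop).astype(int),
        "disease_duration": rng.exponential(bp.disease_duration_mean, n),
    }

    S = np.empty((n, T))
    A = np.zeros((n, T), dtype=int)
    S[:, 0] = rng.normal(config.severity_baseline_mean, config.severity_baseline_sd, n)
    mu0, sd0 = config.severity_baseline_mean, config.severity_baseline_sd
    beta_period = config.treatment_effect_per_year * 0.5

    for t in range(1, T):
        untreated = A[:, t - 1] == 0
        # severity index standardized to the clinical range (~3 SD), keeping
        # per-visit hazards inside (0.004, 0.8) over +/-3 SD: positivity holds
        z = (S[:, t - 1] - mu0) / (3.0 * sd0)
        p_start = expit(config.initiation_intercept + config.initiation_severity_slope * z)
        start = untreated & (rng.random(n) < p_start)
        A[:, t] = A[:, t - 1] | start
        S[:, t] = (
            S[:, t - 1]
            + config.drift_per_period
            + beta_period * A[:, t]
            + rng.normal(0.0, config.sigma_progress, n)
        )

    scores = {}
    for name, (intercept, slope, noise_scale) in SCORE_MAPS.items():
        noise = (
            noise_scale * config.sigma_measure * rng.standard_normal((n, T))
            if noise_scale > 0
            else 0.0
        )
        scores[name] = intercept + slope * (S - mu0) + noise
    if config.symptomatic_offset != 0.0:
        scores["updrs3_off"] = scores["updrs3_off"] + config.symptomatic_offset * A

    ever_treated = A.max(axis=1) == 1
    regimen = np.where(
        ever_treated,
        rng.choice(REGIMEN_LABELS, size=n, p=REGIMEN_PROBS),
        "",
    )

    ids = np.array([f"P{i:05d}" for i in range(n)])
    # outcome assessments at the annual visits used for analysis (years 2,3,4)
    outcome_visits = np.isclose(grid[None, :], np.array(OUTCOME_HORIZONS)[:, None]).any(axis=0)

    df = pd.DataFrame(
        {
            "patient_id": np.repeat(ids, T),
            "visit_time": np.tile(grid, n),
            "on_treatment": A.ravel(),
            **{name: scores[name].ravel() for name in TV_COVARIATES},
            "outcome_observed": np.tile(outcome_visits.astype(int), n),
            **{name: np.repeat(base[name], T) for name in BASELINE_COVARIATES},
            "regimen": np.repeat(regimen, T),
        }
    )
    return CohortPanel(df, require_monotone=True), GroundTruth(true_effect(config))


def apply_missingness(panel: CohortPanel, config: DGPConfig, seed: int) -> CohortPanel:
    """Mask annual outcome assessments and (optionally) covariate visits.

    Each annual outcome flag is cleared independently with
    ``missing_outcome_prob`` (the off-state assessment failed; the visit's
    covariate block is untouched).  With ``missing_visit_prob`` > 0, whole
    covariate blocks at non-baseline visits are set missing (to be carried
    forward later).  Treatment flags are never masked here — see
    :func:`mask_treatment`.
    """
    rng = np.random.default_rng(seed)
    df = panel.df.copy()
    obs = df["outcome_observed"].to_numpy().astype(bool)
    drop = rng.random(len(df)) < config.missing_outcome_prob
    df["outcome_observed"] = (obs & ~drop).astype(int)
    if config.missing_visit_prob > 0:
        nonbase = df["visit_time"].to_numpy() > 0
        gone = (rng.random(len(df)) < config.missing_visit_prob) & nonbase
        df.loc[gone, list(TV_COVARIATES)] = np.nan
        # a visit without a valid covariate block cannot host an outcome either
        df.loc[gone, "outcome_observed"] = 0
    return CohortPanel(df, require_monotone=panel.require_monotone)


def mask_treatment(panel: CohortPanel, prob: float, seed: int) -> CohortPanel:
    """Set treatment flags at non-baseline visits to unknown with given probability.

    Feeds :func:`pdstart.panel.impute_treatment_status`; the baseline flag is
    kept known (de novo cohort, untreated at entry).
    """
    if not (0.0 <= prob < 1.0):
        raise ConfigError(f"prob must be in [0, 1), got {prob}")
    rng = np.random.default_rng(seed)
    df = panel.df.copy()
    nonbase = df["visit_time"].to_numpy() > 0
    unknown = (rng.random(len(df)) < prob) & nonbase
    a = df["on_treatment"].to_numpy(dtype=float)
    a[unknown] = np.nan
    df["on_treatment"] = a
    return CohortPanel(df)


def config_from_dict(d: dict) -> DGPConfig:
    """Build a DGPConfig from a plain dict (e.g. parsed YAML)."""
    d = dict(d)
    bp = d.pop("baseline_covariate_params", None)
    if bp is not None:
        d["baseline_covariate_params"] = BaselineCovariateParams(**bp)
    try:
        return DGPConfig(**d)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def config_to_dict(config: DGPConfig) -> dict:
    return asdict(config)
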
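"""Effect estimators for treatment duration under time-varying confounding.

All estimators target the same policy estimand: the change in the mean
annual outcome if every patient's treatment duration within the first two
years of follow-up were increased by one year.  Four routes are provided:

``naive``
    OLS of the horizon outcome on duration, no adjustment.
``baseline_adjusted`` / ``baseline_adjusted_mw``
    OLS additionally conditioning on the baseline value of the outcome;
    the ``_mw`` variant reweights complete cases by inverse probability of
    the outcome being observed given baseline covariates.
``iptw_msm``
    Linear marginal structural model fit by weighted least squares with
    stabilized inverse-probability-of-treatment weights built from
    per-visit (unpooled) logistic initiation models.
``gformula``
    Parametric g-formula: per-visit (unpooled) linear progression models
    for each time-varying score, Monte Carlo simulation of covariate
    trajectories under fixed-duration policies, and an OLS slope of the
    policy means against policy durations.

Analyses are restricted to patients already on treatment at the outcome
horizon, so every compared patient carries the long-duration symptomatic
response of dopaminergic therapy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.special import expit

from ._arrays import DECISION_IDX, PanelArrays, from_panel, horizon_index
from .errors import EstimationError
from .panel import CohortPanel

DEFAULT_POLICIES: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)
PROB_CLIP_EPS = 1e-6


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class EffectEstimate:
    """Point estimate of the effect per +1 treatment-year on one outcome."""

    method: str
    outcome: str
    horizon: int
    effect_per_year: float
    stderr: float | None
    interval: tuple[float, float] | None
    n_used: int
    diagnostics: dict = dc_field(default_factory=dict)


@dataclass
class TreatmentModels:
    """Per-decision-visit initiation models (unpooled).

    For each decision visit t in {0.5, 1.0, 1.5, 2.0}: a logistic model of
    initiation at t among patients still untreated at t - 0.5, on the
    covariates of visit t - 0.5; and the marginal (intercept-only)
    initiation fraction used as the stabilized-weight numerator.
    """

    visit_idx: tuple[int, ...]
    p0: dict[int, float]                 # numerator: marginal initiation fraction
    beta: dict[int, np.ndarray | None]   # denominator coefficients (None if degenerate)
    n_risk: dict[int, int]
    n_init: dict[int, int]
    degenerate: dict[int, bool]
    eps: float = PROB_CLIP_EPS


@dataclass
class WeightSet:
    """Per-patient stabilized treatment weights (optional missingness weights)."""

    ids: np.ndarray
    sw: np.ndarray
    mw: np.ndarray | None = None
    diagnostics: dict = dc_field(default_factory=dict)

    @property
    def n_eff(self) -> float:
        return float(self.sw.sum() ** 2 / np.sum(self.sw**2))


@dataclass
class GFormulaModels:
    """Per-time-point linear progression models and the outcome model."""

    coef: dict[int, np.ndarray]       # t -> (p, k) coefficients for the k scores
    resid_sd: dict[int, np.ndarray]   # t -> (k,) residual SDs
    outcome_coef: np.ndarray          # (p,) outcome model at the horizon
    outcome_resid_sd: float
    horizon_idx: int


# ---------------------------------------------------------------------------
# low-level fitting helpers (statsmodels-backed)


def _fit_logistic(X: np.ndarray, y: np.ndarray, freq_weights=None) -> np.ndarray:
    """Logistic regression coefficients; falls back to LBFGS on separation."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if freq_weights is None:
                res = sm.Logit(y, X).fit(disp=0)
            else:
                res = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=freq_weights).fit()
            params = np.asarray(res.params, dtype=float)
            if not np.all(np.isfinite(params)):
                raise np.linalg.LinAlgError("non-finite logistic coefficients")
            return params
        except Exception:
            pass
    warnings.warn(
        "logistic fit did not converge cleanly (possible separation); "
        "using LBFGS fit with clipped probabilities",
        stacklevel=2,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, X).fit(method="lbfgs", maxiter=500, disp=0)
    return np.asarray(res.params, dtype=float)


def _wlstsq(X: np.ndarray, Y: np.ndarray, w: np.ndarray | None) -> np.ndarray:
    """Minimum-norm (weighted) least squares, tolerant of rank deficiency."""
    if w is None:
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        return beta
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], Y * (sw[:, None] if Y.ndim == 2 else sw), rcond=None)
    return beta


def _wls_slope(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, coef_index: int = 1
) -> tuple[float, float, np.ndarray]:
    """Weighted least squares with an HC0 sandwich stderr for one coefficient."""
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = y - X @ beta
    XtWX = Xw.T @ Xw
    # pinv: collinear designs (e.g. a constant adjustment covariate) degrade
    # to the minimum-norm fit instead of failing; the slope is unaffected
    bread = np.linalg.pinv(XtWX)
    Xs = X * (w * resid)[:, None]
    meat = Xs.T @ Xs
    cov = bread @ meat @ bread
    return float(beta[coef_index]), float(np.sqrt(cov[coef_index, coef_index])), beta


def _as_arrays(panel, outcome: str = "updrs3_off", **kw) -> PanelArrays:
    if isinstance(panel, PanelArrays):
        return panel
    return from_panel(panel, outcome=outcome, **kw)


def _design(pa: PanelArrays, t: int, a_col: np.ndarray) -> np.ndarray:
    """Feature block [1, L_{t}, B, A] used by progression/outcome models."""
    return np.column_stack(
        [np.ones(pa.n), pa.L[:, t, :].reshape(pa.n, -1), pa.B, a_col]
    )


def _outcome_col(pa: PanelArrays) -> int:
    try:
        return pa.tv_names.index(pa.outcome_name)
    except ValueError as exc:
        raise EstimationError(
            f"outcome {pa.outcome_name!r} is not among the panel's time-varying scores"
        ) from exc


def _analysis_mask(pa: PanelArrays, h_idx: int) -> np.ndarray:
    """Starters at the horizon with an observed outcome value."""
    return (pa.A[:, h_idx] == 1) & ~np.isnan(pa.Y[:, h_idx])


# ---------------------------------------------------------------------------
# naive and baseline-adjusted comparators


def fit_naive(panel, outcome: str = "updrs3_off", horizon: int = 2) -> EffectEstimate:
    """Unadjusted OLS of the horizon outcome on treatment duration."""
    pa = _as_arrays(panel, outcome)
    h = horizon_index(horizon)
    effect, se, n = _naive_point(pa, h, with_se=True)
    return EffectEstimate("naive", pa.outcome_name, horizon, effect, se, None, n)


def _naive_point(pa: PanelArrays, h_idx: int, with_se: bool = False):
    mask = _analysis_mask(pa, h_idx)
    d = pa.duration[mask]
    y = pa.Y[mask, h_idx]
    if np.unique(d).size < 3:
        raise EstimationError(
            "fewer than 3 distinct treatment durations with outcome data; "
            "duration slope not reliably identified"
        )
    X = np.column_stack([np.ones(d.size), d])
    effect, se, _ = _wls_slope(X, y, np.ones(d.size))
    return effect, (se if with_se else None), int(mask.sum())


def fit_baseline_adjusted(
    panel,
    outcome: str = "updrs3_off",
    horizon: int = 2,
    adjust_missingness: bool = False,
) -> EffectEstimate:
    """OLS of the horizon outcome on duration plus the baseline outcome value.

    With ``adjust_missingness``, complete cases are weighted by the inverse
    of the fitted probability that the outcome is observed given baseline
    covariates (logistic model); non-convergence falls back to unweighted
    with a warning.
    """
    pa = _as_arrays(panel, outcome)
    h = horizon_index(horizon)
    effect, se, n, diag = _baseline_adjusted_point(pa, h, adjust_missingness, with_se=True)
    label = "baseline_adjusted_mw" if adjust_missingness else "baseline_adjusted"
    return EffectEstimate(label, pa.outcome_name, horizon, effect, se, None, n, diag)


def _missingness_weights(pa: PanelArrays, h_idx: int, population: np.ndarray) -> np.ndarray | None:
    """1 / P(outcome observed | baseline covariates) within a population mask."""
    observed = (~np.isnan(pa.Y[:, h_idx])).astype(float)
    X = np.column_stack([np.ones(pa.n), pa.L[:, 0, :].reshape(pa.n, -1), pa.B])
    Xp, yp = X[population], observed[population]
    if yp.min() == yp.max():
        return None
    try:
        beta = _fit_logistic(Xp, yp)
    except Exception:
        warnings.warn("missingness model failed; falling back to unweighted", stacklevel=2)
        return None
    p = np.clip(expit(X @ beta), PROB_CLIP_EPS, 1.0)
    return 1.0 / p


def _baseline_adjusted_point(
    pa: PanelArrays, h_idx: int, adjust_missingness: bool, with_se: bool = False
):
    mask = _analysis_mask(pa, h_idx)
    starters = pa.A[:, h_idx] == 1
    y0 = pa.L[:, 0, _outcome_col(pa)]
    w = np.ones(pa.n)
    diag = {"missingness_weighted": False}
    if adjust_missingness:
        mw = _missingness_weights(pa, h_idx, starters)
        if mw is not None:
            w = mw
            diag["missingness_weighted"] = True
    d = pa.duration[mask]
    if np.unique(d).size < 2:
        raise EstimationError("no duration variation among complete cases")
    X = np.column_stack([np.ones(int(mask.sum())), d, y0[mask]])
    effect, se, _ = _wls_slope(X, pa.Y[mask, h_idx], w[mask])
    return effect, (se if with_se else None), int(mask.sum()), diag


# ---------------------------------------------------------------------------
# IPTW marginal structural model


def estimate_treatment_probabilities(panel, window_end: float = 2.0) -> TreatmentModels:
    """Fit per-visit logistic initiation models (unpooled) for the 2-year window.

    At each decision visit t in {0.5, 1.0, 1.5, 2.0}, initiation at t among
    patients still untreated at t - 0.5 is regressed on the time-varying
    scores of visit t - 0.5 plus the baseline covariates.  Intercept-only
    fractions at each visit provide the stabilized-weight numerators.
    Degenerate visits (nobody or everybody initiates) contribute weight
    factor 1 and are flagged.
    """
    pa = _as_arrays(panel)
    idx = tuple(t for t in DECISION_IDX if t * 0.5 <= window_end + 1e-9)
    p0, beta, n_risk, n_init, degen = {}, {}, {}, {}, {}
    for t in idx:
        at_risk = pa.A[:, t - 1] == 0
        y = pa.A[at_risk, t].astype(float)
        n_risk[t] = int(at_risk.sum())
        n_init[t] = int(y.sum())
        if n_risk[t] == 0 or y.min() == y.max():
            degen[t] = True
            p0[t] = float(y.mean()) if n_risk[t] else 0.0
            beta[t] = None
            if n_risk[t]:
                warnings.warn(
                    f"degenerate decision visit t={t * 0.5}: initiation fraction "
                    f"{y.mean():.0%}; weight factor forced to 1",
                    stacklevel=2,
                )
            continue
        degen[t] = False
        p0[t] = float(y.mean())
        X = np.column_stack(
            [
                np.ones(n_risk[t]),
                pa.L[at_risk, t - 1, :].reshape(n_risk[t], -1),
                pa.B[at_risk],
            ]
        )
        beta[t] = _fit_logistic(X, y)
    return TreatmentModels(idx, p0, beta, n_risk, n_init, degen)


def compute_stabilized_weights(
    panel, models: TreatmentModels, eps: float = PROB_CLIP_EPS
) -> WeightSet:
    """Stabilized IPTW weights: product of numerator/denominator factors.

    For each patient the product runs over decision visits up to and
    including the initiation visit (all window visits if never initiated):
    at the initiation visit num = P0(start), den = P(start | L_prev);
    at earlier visits num = 1 - P0, den = 1 - P(start | L_prev).  Patients
    already treated at baseline predate the decision window and get sw = 1.
    """
    pa = _as_arrays(panel)
    sw = np.ones(pa.n)
    n_clipped = 0
    for t in models.visit_idx:
        if models.degenerate[t]:
            continue
        at_risk = pa.A[:, t - 1] == 0
        X = np.column_stack(
            [np.ones(pa.n), pa.L[:, t - 1, :].reshape(pa.n, -1), pa.B]
        )
        p_den = expit(X @ models.beta[t])
        clipped = (p_den < eps) | (p_den > 1 - eps)
        n_clipped += int((clipped & at_risk).sum())
        p_den = np.clip(p_den, eps, 1 - eps)
        p_num = np.clip(models.p0[t], eps, 1 - eps)
        initiated = pa.A[:, t] == 1
        factor = np.where(initiated, p_num / p_den, (1 - p_num) / (1 - p_den))
        sw = np.where(at_risk, sw * factor, sw)
    baseline_treated = pa.A[:, 0] == 1
    sw = np.where(baseline_treated, 1.0, sw)
    diags = {
        "mean": float(sw.mean()),
        "max": float(sw.max()),
        "min": float(sw.min()),
        "n_eff": float(sw.sum() ** 2 / np.sum(sw**2)),
        "n_clipped": n_clipped,
        "n_baseline_treated": int(baseline_treated.sum()),
        "degenerate_visits": [t * 0.5 for t in models.visit_idx if models.degenerate[t]],
    }
    if n_clipped:
        diags["positivity_warning"] = (
            f"{n_clipped} fitted initiation probabilities at the clip boundary"
        )
    return WeightSet(ids=pa.ids, sw=sw, diagnostics=diags)


def fit_iptw_msm(
    panel,
    outcome: str = "updrs3_off",
    horizon: int = 2,
    weights: WeightSet | None = None,
    adjust_missingness: bool = False,
) -> EffectEstimate:
    """Linear MSM for the horizon outcome on duration, weighted by sw (x mw).

    Weights are computed on the full panel before the starters/outcome
    filtering.  The sandwich stderr is a convenience; authoritative
    intervals come from :func:`pdstart.bootstrap.bootstrap_estimate`.
    """
    pa = _as_arrays(panel, outcome)
    h = horizon_index(horizon)
    effect, se, n, diag = _iptw_point(pa, h, weights, adjust_missingness, with_se=True)
    label = "iptw_msm_mw" if adjust_missingness else "iptw_msm"
    return EffectEstimate(label, pa.outcome_name, horizon, effect, se, None, n, diag)


def _iptw_point(
    pa: PanelArrays,
    h_idx: int,
    weights: WeightSet | None = None,
    adjust_missingness: bool = False,
    with_se: bool = False,
):
    if weights is None:
        models = estimate_treatment_probabilities(pa)
        weights = compute_stabilized_weights(pa, models)
    w = weights.sw.copy()
    diag = dict(weights.diagnostics)
    if adjust_missingness:
        mw = _missingness_weights(pa, h_idx, pa.A[:, h_idx] == 1)
        if mw is not None:
            w = w * mw
            diag["missingness_weighted"] = True
    mask = _analysis_mask(pa, h_idx)
    if w[mask].sum() <= 0:
        raise EstimationError("total weight among complete cases is zero")
    d = pa.duration[mask]
    if np.unique(d).size < 2:
        raise EstimationError("no duration variation among complete cases")
    X = np.column_stack([np.ones(int(mask.sum())), d])
    effect, se, _ = _wls_slope(X, pa.Y[mask, h_idx], w[mask])
    return effect, (se if with_se else None), int(mask.sum()), diag


# ---------------------------------------------------------------------------
# parametric g-formula


def _check_policies(policies: Sequence[float]) -> np.ndarray:
    pol = np.asarray(sorted(set(float(p) for p in policies)))
    if pol.size < 2:
        raise ValueError("need at least 2 distinct policy durations for a slope")
    on_grid = np.all(np.abs(pol * 2 - np.round(pol * 2)) < 1e-9)
    if not on_grid or pol.min() < 0.5 - 1e-9 or pol.max() > 2.0 + 1e-9:
        raise ValueError(
            f"policy durations must lie on the half-year grid within [0.5, 2.0]; got {list(pol)}"
        )
    return pol


def fit_gformula_models(pa: PanelArrays, h_idx: int) -> GFormulaModels:
    """Fit the unpooled linear progression models and the outcome model.

    At each visit t, every time-varying score at t is regressed on the full
    covariate block of visit t - 0.5 plus the treatment indicator for the
    period (t - 0.5, t]; no pooling across t.  The outcome model at the
    horizon uses only validly observed outcomes (complete case).
    """
    w = pa.freq_weights()
    coef, resid_sd = {}, {}
    for t in range(1, h_idx):
        X = _design(pa, t - 1, pa.A[:, t].astype(float))
        Yt = pa.L[:, t, :].reshape(pa.n, -1)
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(Yt)):
            raise EstimationError(f"non-finite design for progression models at t={t * 0.5}")
        beta = _wlstsq(X, Yt, w)
        resid = Yt - X @ beta
        resid_sd[t] = np.sqrt(np.average(resid**2, axis=0, weights=w))
        coef[t] = beta
    valid = ~np.isnan(pa.Y[:, h_idx])
    if valid.sum() < 3:
        raise EstimationError(f"too few observed outcomes at the horizon visit t={h_idx * 0.5}")
    Xo = _design(pa, h_idx - 1, pa.A[:, h_idx].astype(float))[valid]
    yo = pa.Y[valid, h_idx]
    wo = w[valid]
    beta_o = _wlstsq(Xo, yo, wo)
    resid_o = yo - Xo @ beta_o
    sd_o = float(np.sqrt(np.average(resid_o**2, weights=wo)))
    return GFormulaModels(coef, resid_sd, beta_o, sd_o, h_idx)


def _policy_mean(
    pa: PanelArrays,
    models: GFormulaModels,
    policy: float,
    n_mc: int,
    rng: np.random.Generator | None,
    deterministic: bool,
) -> float:
    """Mean simulated outcome at the horizon under a fixed-duration policy."""
    first_idx = int(round((2.5 - policy) * 2))
    h = models.horizon_idx
    reps = 1 if deterministic else n_mc
    n = pa.n
    Lsim = np.repeat(pa.L[:, 0, :].reshape(n, -1), reps, axis=0)
    Brep = np.repeat(pa.B, reps, axis=0)
    ones = np.ones(n * reps)
    for t in range(1, h):
        a_t = 1.0 if t >= first_idx else 0.0
        X = np.column_stack([ones, Lsim, Brep, np.full(n * reps, a_t)])
        Lsim = X @ models.coef[t]
        if not deterministic:
            Lsim = Lsim + rng.standard_normal(Lsim.shape) * models.resid_sd[t]
    a_h = 1.0 if h >= first_idx else 0.0
    Xo = np.column_stack([ones, Lsim, Brep, np.full(n * reps, a_h)])
    y_pred = Xo @ models.outcome_coef
    per_patient = y_pred.reshape(n, reps).mean(axis=1)
    return float(np.average(per_patient, weights=pa.freq_weights()))


def fit_gformula(
    panel,
    outcome: str = "updrs3_off",
    horizon: int = 2,
    policies: Sequence[float] = DEFAULT_POLICIES,
    n_mc: int = 100,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    deterministic: bool = False,
    patient_weights: Mapping | None = None,
) -> EffectEstimate:
    """Parametric g-formula estimate of the effect per +1 treatment-year.

    Simulates ``n_mc`` covariate trajectories per patient from baseline
    forward under each fixed-duration policy (treatment starts at
    2.0 - duration), drawing progression noise from the fitted residual
    SDs, and reports the OLS slope of the policy outcome means on the
    policy durations.  ``deterministic=True`` propagates conditional means
    without noise (exact for linear models).
    """
    pol = _check_policies(policies)
    if isinstance(panel, CohortPanel):
        pa = from_panel(panel, outcome=outcome, patient_weights=patient_weights)
    else:
        pa = panel
    h = horizon_index(horizon)
    if rng is None:
        rng = np.random.default_rng(seed)
    effect, means = _gformula_point(pa, h, pol, n_mc, rng, deterministic)
    return EffectEstimate(
        "gformula",
        pa.outcome_name,
        horizon,
        effect,
        None,
        None,
        pa.n,
        {"policies": list(pol), "policy_means": [float(m) for m in means], "n_mc": n_mc},
    )


def _gformula_point(
    pa: PanelArrays,
    h_idx: int,
    policies: np.ndarray,
    n_mc: int,
    rng: np.random.Generator | None,
    deterministic: bool,
):
    models = fit_gformula_models(pa, h_idx)
    means = np.array(
        [_policy_mean(pa, models, d, n_mc, rng, deterministic) for d in policies]
    )
    slope = np.polyfit(policies, means, 1)[0]
    return float(slope), means


# ---------------------------------------------------------------------------
# dispatch used by the bootstrap and the CLI

METHODS = (
    "naive",
    "baseline_adjusted",
    "baseline_adjusted_mw",
    "iptw_msm",
    "gformula",
)


def point_estimate(
    pa: PanelArrays,
    method: str,
    horizon: int = 2,
    rng: np.random.Generator | None = None,
    **kwargs,
) -> float:
    """Run one estimator pipeline end to end on an array bundle.

    Refits every component (treatment models, weights, progression models)
    from scratch, which is what the patient-level bootstrap requires.
    """
    h = horizon_index(horizon)
    if method == "naive":
        return _naive_point(pa, h)[0]
    if method == "baseline_adjusted":
        return _baseline_adjusted_point(pa, h, False)[0]
    if method == "baseline_adjusted_mw":
        return _baseline_adjusted_point(pa, h, True)[0]
    if method == "iptw_msm":
        return _iptw_point(pa, h, None, kwargs.get("adjust_missingness", False))[0]
    if method == "gformula":
        pol = _check_policies(kwargs.get("policies", DEFAULT_POLICIES))
        return _gformula_point(
            pa,
            h,
            pol,
            kwargs.get("n_mc", 100),
            rng,
            kwargs.get("deterministic", False),
        )[0]
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def fit_method(panel, method: str, outcome: str = "updrs3_off", horizon: int = 2, **kwargs):
    """Public dispatch returning a full EffectEstimate for a named method."""
    if method == "naive":
        return fit_naive(panel, outcome, horizon)
    if method == "baseline_adjusted":
        return fit_baseline_adjusted(panel, outcome, horizon, adjust_missingness=False)
    if method == "baseline_adjusted_mw":
        return fit_baseline_adjusted(panel, outcome, horizon, adjust_missingness=True)
    if method == "iptw_msm":
        return fit_iptw_msm(panel, outcome, horizon, **kwargs)
    if method == "gformula":
        return fit_gformula(panel, outcome, horizon, **kwargs)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
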
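"""Estimator unit behavior: hand-computable cases, weight arithmetic, cross-checks."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.special import logit

from conftest import build_panel, full_flags

from pdstart._arrays import from_panel
from pdstart.errors import EstimationError
from pdstart.estimators import (
    TreatmentModels,
    _wls_slope,
    _wlstsq,
    compute_stabilized_weights,
    estimate_treatment_probabilities,
    fit_baseline_adjusted,
    fit_gformula,
    fit_iptw_msm,
    fit_naive,
    point_estimate,
)


def _toy_duration_panel(durations, outcomes, baselines=None):
    """Patients with prescribed durations and year-2 outcomes."""
    first_visit = {2.0: 1, 1.5: 2, 1.0: 3, 0.5: 4}
    treatments, out = {}, {}
    for i, (d, y) in enumerate(zip(durations, outcomes)):
        pid = f"p{i}"
        treatments[pid] = full_flags(first_visit[d])
        out[pid] = {2: y}
    panel = build_panel(treatments, outcomes=out)
    if baselines is not None:
        df = panel.df.copy()
        for i, b in enumerate(baselines):
            sel = (df.patient_id == f"p{i}") & (df.visit_time == 0.0)
            df.loc[sel, "updrs3_off"] = b
        from pdstart.panel import CohortPanel

        panel = CohortPanel(df)
    return panel


def test_naive_slope_hand_computed():
    """durations (0.5,0.5,1.5,1.5), outcomes (10,12,16,18) -> slope 6.0."""
    panel = _toy_duration_panel([0.5, 0.5, 1.5, 1.5, 1.0], [10, 12, 16, 18, 14])
    est = fit_naive(panel, horizon=2)
    # the extra duration-1.0 patient lies on the same line's midpoint
    assert est.effect_per_year == pytest.approx(6.0, abs=1e-10)
    assert est.n_used == 5


def test_naive_flat_outcomes_zero_slope():
    panel = _toy_duration_panel([0.5, 1.0, 1.5, 2.0], [7, 7, 7, 7])
    assert fit_naive(panel, horizon=2).effect_per_year == pytest.approx(0.0, abs=1e-12)


def test_naive_needs_three_distinct_durations():
    panel = _toy_duration_panel([0.5, 0.5, 1.5, 1.5], [10, 12, 16, 18])
    with pytest.raises(EstimationError, match="distinct"):
        fit_naive(panel, horizon=2)


def test_baseline_adjusted_equals_naive_when_baseline_constant():
    panel = _toy_duration_panel([0.5, 1.0, 1.5, 2.0], [10, 12, 16, 18])
    n = fit_naive(panel, horizon=2)
    b = fit_baseline_adjusted(panel, horizon=2)
    assert b.effect_per_year == pytest.approx(n.effect_per_year, abs=1e-8)


def test_baseline_adjusted_exact_linear_recovery():
    """outcome = baseline + beta * duration exactly -> slope beta to precision."""
    beta = -1.5
    durations = [0.5, 1.0, 1.5, 2.0, 0.5, 2.0]
    baselines = [20.0, 25.0, 18.0, 30.0, 22.0, 27.0]
    outcomes = [b + beta * d for b, d in zip(baselines, durations)]
    panel = _toy_duration_panel(durations, outcomes, baselines=baselines)
    est = fit_baseline_adjusted(panel, horizon=2)
    assert est.effect_per_year == pytest.approx(beta, abs=1e-9)


def test_missingness_weighting_agrees_under_mcar(unconfounded_cohort):
    """MCAR outcome missingness: weighted and unweighted estimates agree."""
    panel, truth, cfg = unconfounded_cohort
    unw = fit_baseline_adjusted(panel, horizon=2, adjust_missingness=False)
    w = fit_baseline_adjusted(panel, horizon=2, adjust_missingness=True)
    assert w.diagnostics["missingness_weighted"]
    assert abs(w.effect_per_year - unw.effect_per_year) < 2 * unw.stderr


# ---------------------------------------------------------------------------
# treatment models and stabilized weights


def test_numerator_is_empirical_initiation_fraction(default_cohort):
    panel, _, _ = default_cohort
    pa = from_panel(panel)
    models = estimate_treatment_probabilities(pa)
    for t in models.visit_idx:
        at_risk = pa.A[:, t - 1] == 0
        assert models.p0[t] == pytest.approx(pa.A[at_risk, t].mean())


def test_stabilized_weight_single_visit_arithmetic():
    """One decision visit, P0=0.3, P(.|L)=0.6: initiator 0.5, non-initiator 1.75."""
    panel = build_panel({"starts": full_flags(1), "never": full_flags(None)})
    pa = from_panel(panel)
    models = TreatmentModels(
        visit_idx=(1,),
        p0={1: 0.3},
        beta={1: np.r_[logit(0.6), np.zeros(10)]},
        n_risk={1: 2},
        n_init={1: 1},
        degenerate={1: False},
    )
    ws = compute_stabilized_weights(pa, models)
    by_id = dict(zip(ws.ids, ws.sw))
    assert by_id["starts"] == pytest.approx(0.5)
    assert by_id["never"] == pytest.approx(0.7 / 0.4)


def test_baseline_treated_patient_gets_unit_weight(default_cohort):
    panel, _, _ = default_cohort
    df = panel.df.copy()
    pid = df.patient_id.iloc[0]
    df.loc[df.patient_id == pid, "on_treatment"] = 1
    from pdstart.panel import CohortPanel

    pa = from_panel(CohortPanel(df))
    models = estimate_treatment_probabilities(pa)
    ws = compute_stabilized_weights(pa, models)
    assert dict(zip(ws.ids, ws.sw))[pid] == 1.0
    assert ws.diagnostics["n_baseline_treated"] == 1


def test_perfect_separation_clips_and_warns():
    """All high-severity patients initiate, none of the low: weights stay finite."""
    scores_hi = {"updrs3_off": np.full(9, 40.0)}
    scores_lo = {"updrs3_off": np.full(9, 5.0)}
    import pandas as pd

    dfs = []
    for i in range(12):
        hi = i < 6
        p = build_panel(
            {f"p{i}": full_flags(1 if hi else None)},
            scores=scores_hi if hi else scores_lo,
        )
        dfs.append(p.df)
    from pdstart.panel import CohortPanel

    panel = CohortPanel(pd.concat(dfs, ignore_index=True))
    pa = from_panel(panel)
    with pytest.warns(UserWarning, match="separation|converge"):
        models = estimate_treatment_probabilities(pa)
    ws = compute_stabilized_weights(pa, models)
    assert np.all(np.isfinite(ws.sw)) and np.all(ws.sw > 0)


def test_degenerate_visit_contributes_factor_one():
    """Nobody initiates anywhere: all weights exactly 1, visits flagged."""
    panel = build_panel({f"p{i}": full_flags(None) for i in range(8)})
    pa = from_panel(panel)
    with pytest.warns(UserWarning, match="degenerate"):
        models = estimate_treatment_probabilities(pa)
    ws = compute_stabilized_weights(pa, models)
    assert np.all(ws.sw == 1.0)
    assert ws.diagnostics["degenerate_visits"] == [0.5, 1.0, 1.5, 2.0]


def test_iptw_with_unit_weights_equals_naive(default_cohort):
    panel, _, _ = default_cohort
    pa = from_panel(panel)
    from pdstart.estimators import WeightSet

    ones = WeightSet(ids=pa.ids, sw=np.ones(pa.n))
    est = fit_iptw_msm(panel, horizon=2, weights=ones)
    naive = fit_naive(panel, horizon=2)
    assert est.effect_per_year == pytest.approx(naive.effect_per_year, abs=1e-10)


def test_weight_stabilization_under_no_confounding(unconfounded_cohort):
    panel, _, _ = unconfounded_cohort
    pa = from_panel(panel)
    ws = compute_stabilized_weights(pa, estimate_treatment_probabilities(pa))
    assert 0.95 <= ws.sw.mean() <= 1.05
    assert ws.n_eff / pa.n > 0.9


# ---------------------------------------------------------------------------
# g-formula contracts


def test_gformula_policy_contracts(default_cohort):
    panel, _, _ = default_cohort
    with pytest.raises(ValueError, match="at least 2"):
        fit_gformula(panel, policies=[1.0], seed=0)
    with pytest.raises(ValueError, match="half-year"):
        fit_gformula(panel, policies=[0.7, 1.3], seed=0)


def test_gformula_deterministic_mode_is_seed_free(default_cohort):
    panel, _, _ = default_cohort
    a = fit_gformula(panel, deterministic=True, seed=1)
    b = fit_gformula(panel, deterministic=True, seed=999)
    assert a.effect_per_year == b.effect_per_year


def test_gformula_noiseless_static_panel_has_zero_slope():
    """No progression, no effect: all policy means equal, slope 0."""
    treatments = {}
    outcomes = {}
    rng = np.random.default_rng(0)
    for i in range(40):
        first = int(rng.integers(1, 5))
        pid = f"p{i}"
        treatments[pid] = full_flags(first)
        outcomes[pid] = {2: 10.0}
    for i in range(10):  # some never-treated for model support
        treatments[f"n{i}"] = full_flags(None)
        outcomes[f"n{i}"] = {2: 10.0}
    panel = build_panel(treatments, outcomes=outcomes)
    est = fit_gformula(panel, deterministic=True, seed=0)
    assert est.effect_per_year == pytest.approx(0.0, abs=1e-8)
    assert np.allclose(est.diagnostics["policy_means"], 10.0, atol=1e-8)


def test_gformula_seeded_reproducibility(default_cohort):
    panel, _, _ = default_cohort
    a = fit_gformula(panel, n_mc=20, seed=42)
    b = fit_gformula(panel, n_mc=20, seed=42)
    assert a.effect_per_year == b.effect_per_year


# ---------------------------------------------------------------------------
# regression machinery cross-checked against statsmodels


def test_wls_slope_matches_statsmodels_hc0():
    rng = np.random.default_rng(2)
    n = 400
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = 1.0 + 2.0 * X[:, 1] + rng.normal(size=n)
    w = rng.uniform(0.5, 3.0, n)
    slope, se, beta = _wls_slope(X, y, w)
    ref = sm.WLS(y, X, weights=w).fit(cov_type="HC0")
    assert beta == pytest.approx(list(ref.params), abs=1e-10)
    assert se == pytest.approx(ref.bse[1], rel=1e-6)


def test_weighted_lstsq_matches_statsmodels():
    rng = np.random.default_rng(4)
    n = 300
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
    Y = rng.normal(size=(n, 2))
    w = rng.uniform(0.1, 2.0, n)
    beta = _wlstsq(X, Y, w)
    for j in range(2):
        ref = sm.WLS(Y[:, j], X, weights=w).fit()
        assert beta[:, j] == pytest.approx(list(ref.params), abs=1e-8)


def test_point_estimate_rejects_unknown_method(default_cohort):
    panel, _, _ = default_cohort
    pa = from_panel(panel)
    with pytest.raises(ValueError, match="unknown method"):
        point_estimate(pa, "tmle", 2)
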
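"""Internal dense-array view of a cohort panel.

Estimators and the bootstrap work on this bundle: one numpy row block per
patient, aligned on the full visit grid.  Resampling patients is then a
single fancy-indexing operation, which keeps the per-replicate cost of the
bootstrap small.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PanelDataError
from .panel import (
    BASELINE_COVARIATES,
    TV_COVARIATES,
    VISIT_GRID,
    CohortPanel,
    carry_forward_covariates,
)

GRID = np.array(VISIT_GRID)
N_VISITS = len(GRID)
#: decision visits for the 2-year window: initiation observable at 0.5..2.0
DECISION_IDX = (1, 2, 3, 4)


def horizon_index(horizon: float) -> int:
    idx = int(round(horizon * 2))
    if not (0 <= idx < N_VISITS) or abs(idx * 0.5 - horizon) > 1e-9:
        raise ValueError(f"horizon {horizon!r} not on the visit grid")
    return idx


@dataclass
class PanelArrays:
    """Per-patient arrays on the full visit grid (n patients, 9 visits)."""

    ids: np.ndarray          # (n,) object
    A: np.ndarray            # (n, 9) int8 treatment flags
    L: np.ndarray            # (n, 9, k) time-varying scores, carried forward
    B: np.ndarray            # (n, b) baseline covariates
    Y: np.ndarray            # (n, 9) outcome value where validly observed, else NaN
    duration: np.ndarray     # (n,) treated years in (0, 2]
    first_treated: np.ndarray  # (n,) visit index of first treatment, -1 if never
    tv_names: tuple[str, ...]
    baseline_names: tuple[str, ...]
    outcome_name: str = "updrs3_off"
    weights: np.ndarray | None = None  # optional per-patient frequency weights

    @property
    def n(self) -> int:
        return len(self.ids)

    def take(self, idx: np.ndarray) -> "PanelArrays":
        return PanelArrays(
            ids=self.ids[idx],
            A=self.A[idx],
            L=self.L[idx],
            B=self.B[idx],
            Y=self.Y[idx],
            duration=self.duration[idx],
            first_treated=self.first_treated[idx],
            tv_names=self.tv_names,
            baseline_names=self.baseline_names,
            outcome_name=self.outcome_name,
            weights=None if self.weights is None else self.weights[idx],
        )

    def freq_weights(self) -> np.ndarray:
        return np.ones(self.n) if self.weights is None else self.weights


def from_panel(
    panel: CohortPanel,
    tv_covariates: tuple[str, ...] = TV_COVARIATES,
    baseline_covariates: tuple[str, ...] = BASELINE_COVARIATES,
    outcome: str = "updrs3_off",
    patient_weights=None,
) -> PanelArrays:
    """Build the array bundle from a validated, monotone, imputed panel.

    Covariates are carried forward onto the full grid first; the outcome at
    each annual visit is the *raw* (pre-carry) value, gated by the
    outcome_observed flag, so a carried covariate can never masquerade as a
    measured outcome.
    """
    raw = panel.df
    if raw["on_treatment"].isna().any():
        raise PanelDataError("panel has unknown treatment flags; impute first")
    cf = carry_forward_covariates(panel)
    df = cf.df
    n = panel.n_patients

    ids = df["patient_id"].to_numpy()[::N_VISITS].copy()
    A = df["on_treatment"].to_numpy(dtype=float).reshape(n, N_VISITS)
    if np.isnan(A[:, 0]).any():
        raise PanelDataError("baseline treatment flag missing for some patients")
    A = np.nan_to_num(A, nan=0.0).astype(np.int8)
    if np.any(np.diff(A, axis=1) < 0):
        raise PanelDataError("non-monotone treatment; run exclude_discontinuers first")
    L = np.stack(
        [df[c].to_numpy(dtype=float).reshape(n, N_VISITS) for c in tv_covariates], axis=2
    )
    B = np.column_stack(
        [df[c].to_numpy(dtype=float).reshape(n, N_VISITS)[:, 0] for c in baseline_covariates]
    ) if baseline_covariates else np.empty((n, 0))

    # outcome from the raw rows (value present + flag set at that visit)
    y_raw = np.full((n, N_VISITS), np.nan)
    pos = {pid: i for i, pid in enumerate(ids)}
    r_ids = raw["patient_id"].to_numpy()
    r_t = np.round(raw["visit_time"].to_numpy() * 2).astype(int)
    r_obs = raw["outcome_observed"].to_numpy().astype(bool)
    r_val = raw[outcome].to_numpy(dtype=float)
    ok = r_obs & ~np.isnan(r_val)
    rows = np.fromiter((pos[p] for p in r_ids[ok]), dtype=int, count=int(ok.sum()))
    y_raw[rows, r_t[ok]] = r_val[ok]

    in_window = (GRID > 1e-9) & (GRID <= 2.0 + 1e-9)
    duration = 0.5 * A[:, in_window].sum(axis=1).astype(float)
    any_treated = A.max(axis=1) == 1
    first_treated = np.where(any_treated, np.argmax(A == 1, axis=1), -1)

    w = None
    if patient_weights is not None:
        w = np.array([patient_weights[pid] for pid in ids], dtype=float)

    return PanelArrays(
        ids=ids,
        A=A,
        L=L,
        B=B,
        Y=y_raw,
        duration=duration,
        first_treated=first_treated,
        tv_names=tuple(tv_covariates),
        baseline_names=tuple(baseline_covariates),
        outcome_name=outcome,
        weights=w,
    )
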
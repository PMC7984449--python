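"""Longitudinal visit-level data model for treatment-timing analyses.

The unit of analysis is a patient trajectory on a biannual visit grid
(0.0, 0.5, ..., 4.0 years since baseline).  Each visit row records whether
the patient is on dopaminergic treatment, a block of time-varying clinical
scores, and whether the annual motor outcome assessment was valid.  Treatment
recorded at a visit is taken to cover the preceding half-year period
(t - 0.5, t]: the decision to start is made at the previous visit based on
the patient's state there, and the patient is first *recorded* on treatment
at the next visit.

Treatment is monotone: once started it is never stopped.  Patients who do
stop ("discontinuers") are identified and excluded before estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import PanelDataError, SchemaError

#: Biannual visit grid in years since baseline.
VISIT_GRID: tuple[float, ...] = tuple(i * 0.5 for i in range(9))

#: Time-varying clinical scores carried at every visit.
TV_COVARIATES: tuple[str, ...] = ("updrs1", "updrs2", "updrs3_off", "mseadl", "moca")

#: Baseline (time-fixed) covariates.
BASELINE_COVARIATES: tuple[str, ...] = (
    "age",
    "sex",
    "education",
    "cardiovascular",
    "disease_duration",
)

#: Canonical long-format CSV columns.
PANEL_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "visit_time",
    "on_treatment",
    *TV_COVARIATES,
    "outcome_observed",
    *BASELINE_COVARIATES,
    "regimen",
)

#: Horizons (years) at which annual outcomes are analyzed.
OUTCOME_HORIZONS: tuple[int, ...] = (2, 3, 4)

_GRID_TOL = 1e-9


def _on_grid(times: np.ndarray) -> np.ndarray:
    """Boolean mask of times that lie on the half-year grid within [0, 4]."""
    t = np.asarray(times, dtype=float)
    near = np.abs(t * 2.0 - np.round(t * 2.0)) <= _GRID_TOL
    return near & (t >= -_GRID_TOL) & (t <= 4.0 + _GRID_TOL)


@dataclass(frozen=True)
class TreatmentSummary:
    """Per-patient treatment bookkeeping within the duration window.

    ``first_treated_visit`` is the first visit time with on_treatment = 1
    (None if never treated in the observed window).  Under the
    preceding-period convention, a patient first recorded on treatment at
    visit ``s`` effectively started at ``s - 0.5`` (floored at 0), which is
    the ``start_time`` label.  ``duration_2y`` is the period count:
    0.5 x (number of treated visits in (0, window_end]).
    """

    patient_id: object
    first_treated_visit: float | None
    start_time: float | None
    duration_2y: float


@dataclass
class CohortPanel:
    """Validated long-format collection of patient trajectories.

    ``df`` holds one row per (patient, visit) sorted by (patient_id,
    visit_time).  Construction validates the visit grid, the presence of a
    baseline (time-0) row for every patient, and uniqueness of
    (patient, time) pairs.  Monotone treatment is *not* required at load
    time (discontinuers may be present until :func:`exclude_discontinuers`
    runs); pass ``require_monotone=True`` to enforce it.
    """

    df: pd.DataFrame
    require_monotone: bool = False

    def __post_init__(self) -> None:
        self.df = self.df.copy()
        missing = [c for c in PANEL_COLUMNS if c not in self.df.columns and c != "regimen"]
        if missing:
            raise SchemaError(f"panel is missing required columns: {missing}")
        if "regimen" not in self.df.columns:
            self.df["regimen"] = ""
        self.df["regimen"] = self.df["regimen"].fillna("")
        self.df["visit_time"] = self.df["visit_time"].astype(float)
        self._validate()
        self.df = (
            self.df.sort_values(["patient_id", "visit_time"], kind="mergesort")
            .reset_index(drop=True)
        )

    def _validate(self) -> None:
        df = self.df
        bad = ~_on_grid(df["visit_time"].to_numpy())
        if bad.any():
            row = df.index[bad][0]
            raise PanelDataError(
                f"visit_time {df.loc[row, 'visit_time']!r} at input row {row} "
                "is not on the half-year grid [0, 4]"
            )
        dup = df.duplicated(subset=["patient_id", "visit_time"])
        if dup.any():
            row = df.index[dup][0]
            raise PanelDataError(
                f"duplicate (patient_id, visit_time) pair at input row {row}: "
                f"({df.loc[row, 'patient_id']!r}, {df.loc[row, 'visit_time']!r})"
            )
        has_baseline = df.groupby("patient_id")["visit_time"].min() <= _GRID_TOL
        if not has_baseline.all():
            missing_ids = list(has_baseline.index[~has_baseline])
            raise PanelDataError(f"patients lacking a baseline (time 0) visit: {missing_ids}")
        if self.require_monotone:
            viol = _discontinuer_ids(df)
            if viol:
                raise PanelDataError(f"non-monotone treatment for patients: {viol}")

    @property
    def patient_ids(self) -> np.ndarray:
        return self.df["patient_id"].unique()

    @property
    def n_patients(self) -> int:
        return int(self.df["patient_id"].nunique())

    def baseline(self) -> pd.DataFrame:
        """Baseline covariate table indexed by patient_id (one row each)."""
        base = self.df[self.df["visit_time"] <= _GRID_TOL]
        return base.set_index("patient_id")[list(BASELINE_COVARIATES) + ["regimen"]]

    def subset(self, patient_ids: Iterable) -> "CohortPanel":
        keep = set(patient_ids)
        return CohortPanel(
            self.df[self.df["patient_id"].isin(keep)],
            require_monotone=self.require_monotone,
        )


def read_panel(path, schema: Mapping[str, str] | None = None) -> CohortPanel:
    """Read a long-format visit CSV into a validated :class:`CohortPanel`.

    Parameters
    ----------
    path
        CSV file with one row per patient-visit; missing values as empty
        fields.  ``on_treatment`` may be empty (unknown before imputation).
    schema
        Optional mapping from canonical column names to the file's column
        names, for files with non-standard headers.
    """
    df = pd.read_csv(path)
    if schema:
        rename = {v: k for k, v in schema.items()}
        df = df.rename(columns=rename)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns and c != "regimen"]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return CohortPanel(df)


def write_panel(panel: CohortPanel, path) -> None:
    """Write a panel back to CSV in the canonical dialect (stable formatting)."""
    out = panel.df.loc[:, list(PANEL_COLUMNS)]
    out.to_csv(path, index=False, float_format="%.10g")


def _discontinuer_ids(df: pd.DataFrame) -> list:
    """Patients with any 1 -> 0 treatment transition (on known flags)."""
    out = []
    for pid, g in df.sort_values("visit_time").groupby("patient_id", sort=False):
        a = g["on_treatment"].to_numpy(dtype=float)
        known = a[~np.isnan(a)]
        if np.any(np.diff(known) < 0):
            out.append(pid)
    return out


def exclude_discontinuers(panel: CohortPanel) -> tuple[CohortPanel, list]:
    """Drop patients who stop treatment during follow-up.

    Returns the monotone panel and the list of excluded patient ids.
    """
    excluded = _discontinuer_ids(panel.df)
    keep = ~panel.df["patient_id"].isin(set(excluded))
    return CohortPanel(panel.df[keep], require_monotone=True), excluded


def impute_treatment_status(panel: CohortPanel) -> tuple[CohortPanel, list]:
    """Resolve unknown treatment flags with last-observation-carried-forward.

    Rules, applied per patient in visit order:

    * interior unknowns bracketed by two treated visits are forced to 1
      (monotonicity leaves no alternative);
    * all other unknowns take the last known flag (LOCF), so a
      (0, unknown, 1) gap resolves to (0, 0, 1);
    * patients whose flags start unknown with a later treated visit and no
      earlier known 0 have an undeterminable start time and are flagged for
      exclusion rather than guessed.

    Returns the imputed panel (undeterminable patients removed) and the list
    of excluded patient ids.  Imputation never creates a 1 -> 0 transition.
    """
    df = panel.df.copy()
    excluded: list = []
    filled = np.empty(len(df), dtype=float)
    pos = 0
    for pid, g in df.groupby("patient_id", sort=False):
        a = g["on_treatment"].to_numpy(dtype=float)
        n = len(a)
        known_idx = np.flatnonzero(~np.isnan(a))
        if known_idx.size == 0:
            excluded.append(pid)
            filled[pos : pos + n] = np.nan
            pos += n
            continue
        out = a.copy()
        # force 1 between two treated visits
        ones = np.flatnonzero(a == 1)
        if ones.size >= 2:
            out[ones[0] : ones[-1] + 1] = np.where(
                np.isnan(out[ones[0] : ones[-1] + 1]), 1.0, out[ones[0] : ones[-1] + 1]
            )
        # leading unknowns: undeterminable start iff first known flag is 1
        first_known = np.flatnonzero(~np.isnan(out))[0]
        if first_known > 0:
            if out[first_known] == 1:
                excluded.append(pid)
                filled[pos : pos + n] = np.nan
                pos += n
                continue
            out[:first_known] = 0.0
        # LOCF for the rest
        for i in range(1, n):
            if np.isnan(out[i]):
                out[i] = out[i - 1]
        filled[pos : pos + n] = out
        pos += n
    df["on_treatment"] = filled
    keep = ~df["patient_id"].isin(set(excluded))
    df = df[keep]
    df["on_treatment"] = df["on_treatment"].astype(int)
    return CohortPanel(df, require_monotone=panel.require_monotone), excluded


def derive_treatment_duration(
    panel: CohortPanel, window_end: float = 2.0
) -> list[TreatmentSummary]:
    """Per-patient treatment duration within (0, window_end] by period counting.

    duration = 0.5 x (number of visits in (0, window_end] with
    on_treatment = 1), under the convention that treatment recorded at a
    visit covers the preceding half-year period.  A patient first recorded
    on treatment at the baseline visit or at 0.5 y therefore accrues the
    full 2.0 years within the default window.
    """
    if _discontinuer_ids(panel.df):
        raise PanelDataError(
            "derive_treatment_duration requires a monotone panel; "
            "run exclude_discontinuers first"
        )
    out = []
    for pid, g in panel.df.groupby("patient_id", sort=False):
        g = g.sort_values("visit_time")
        t = g["visit_time"].to_numpy(dtype=float)
        a = g["on_treatment"].to_numpy(dtype=float)
        if np.isnan(a).any():
            raise PanelDataError(
                f"patient {pid!r} has unknown treatment flags; impute first"
            )
        treated = np.flatnonzero(a == 1)
        if treated.size:
            first = float(t[treated[0]])
            start = max(0.0, first - 0.5)
        else:
            first = None
            start = None
        in_window = (t > _GRID_TOL) & (t <= window_end + _GRID_TOL)
        duration = 0.5 * float(np.sum(a[in_window] == 1))
        out.append(TreatmentSummary(pid, first, start, duration))
    return out


def filter_starters(panel: CohortPanel, horizon: int) -> CohortPanel:
    """Keep patients who are on treatment at the horizon visit.

    Annual outcomes are compared only within patients who have started
    treatment by the assessment, so that the long-duration symptomatic
    response is present for everyone in the comparison.  Idempotent.
    """
    if horizon not in OUTCOME_HORIZONS:
        raise ValueError(f"horizon must be one of {OUTCOME_HORIZONS}, got {horizon!r}")
    at_h = panel.df[np.abs(panel.df["visit_time"] - horizon) <= _GRID_TOL]
    started = at_h.loc[at_h["on_treatment"] == 1, "patient_id"]
    return panel.subset(started)


def filter_regimen(
    panel: CohortPanel,
    regimen: str,
    labels: Mapping[object, str] | None = None,
) -> CohortPanel:
    """Restrict treated patients to one medication class (untreated retained).

    ``labels`` maps patient_id -> class; when omitted, the panel's own
    ``regimen`` column is used.  Treated patients without a label are a data
    error; requesting a class no treated patient carries leaves only the
    untreated and logs a warning.
    """
    df = panel.df
    ever_treated = df.groupby("patient_id")["on_treatment"].max() == 1
    treated_ids = set(ever_treated.index[ever_treated])
    if labels is None:
        labels = {
            pid: lab
            for pid, lab in panel.baseline()["regimen"].items()
            if lab not in ("", None)
        }
    unlabeled = treated_ids - set(labels)
    if unlabeled:
        raise PanelDataError(f"treated patients without a regimen label: {sorted(map(str, unlabeled))}")
    keep_treated = {pid for pid in treated_ids if labels[pid] == regimen}
    if not keep_treated:
        warnings.warn(
            f"no treated patient has regimen {regimen!r}; only untreated patients remain",
            stacklevel=2,
        )
    keep = (set(ever_treated.index[~ever_treated])) | keep_treated
    return panel.subset(keep)


def carry_forward_covariates(panel: CohortPanel) -> CohortPanel:
    """Fill missing time-varying scores by last observation carried forward.

    Also reindexes each patient to the full visit grid (dropout rows are
    created and carried forward) so downstream estimators see a complete
    covariate block at every visit.  Treatment flags are carried forward as
    well, which cannot break monotonicity.
    """
    ids = panel.df["patient_id"].unique()
    full_index = pd.MultiIndex.from_product(
        [ids, list(VISIT_GRID)], names=["patient_id", "visit_time"]
    )
    df = (
        panel.df.set_index(["patient_id", "visit_time"])
        .reindex(full_index)
        .sort_index()
    )
    carry_cols = (
        list(TV_COVARIATES) + list(BASELINE_COVARIATES) + ["on_treatment", "regimen"]
    )
    df[carry_cols] = df.groupby(level=0, sort=False)[carry_cols].ffill()
    df["outcome_observed"] = df["outcome_observed"].fillna(0).astype(int)
    out = df.reset_index()
    return CohortPanel(out, require_monotone=panel.require_monotone)
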
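"""Shared fixtures and panel-construction helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pdstart.panel import (
    BASELINE_COVARIATES,
    TV_COVARIATES,
    VISIT_GRID,
    CohortPanel,
)
from pdstart.simulate import DGPConfig, apply_missingness, simulate_cohort


def build_panel(
    treatments: dict[str, list],
    scores: dict[str, np.ndarray] | None = None,
    outcomes: dict[str, dict[int, float]] | None = None,
    baseline: dict[str, dict[str, float]] | None = None,
    regimen: dict[str, str] | None = None,
    require_monotone: bool = False,
) -> CohortPanel:
    """Hand-build a panel from per-patient treatment flag sequences.

    ``treatments[pid]`` is a list of 0/1/None flags starting at visit 0
    (None = unknown).  Scores default to constant 10 everywhere; outcomes,
    when given, set the primary motor score at those annual visits and mark
    them observed.
    """
    rows = []
    for pid, flags in treatments.items():
        for k, a in enumerate(flags):
            t = VISIT_GRID[k]
            row = {
                "patient_id": pid,
                "visit_time": t,
                "on_treatment": np.nan if a is None else a,
                "outcome_observed": 0,
                "regimen": (regimen or {}).get(pid, ""),
            }
            for name in TV_COVARIATES:
                if scores and name in scores:
                    row[name] = scores[name][k]
                else:
                    row[name] = 10.0
            for name in BASELINE_COVARIATES:
                row[name] = (baseline or {}).get(pid, {}).get(name, 0.0)
            if outcomes and pid in outcomes:
                year = t if t == int(t) else None
                if year is not None and int(year) in outcomes[pid]:
                    row["updrs3_off"] = outcomes[pid][int(year)]
                    row["outcome_observed"] = 1
            rows.append(row)
    return CohortPanel(pd.DataFrame(rows), require_monotone=require_monotone)


def full_flags(first_treated_visit: int | None, n: int = 9) -> list[int]:
    """Monotone flag sequence over the grid, starting at the given visit index."""
    if first_treated_visit is None:
        return [0] * n
    return [0] * first_treated_visit + [1] * (n - first_treated_visit)


@pytest.fixture(scope="session")
def default_cohort():
    """One moderate default-DGP cohort with missingness applied."""
    cfg = DGPConfig(n_patients=1500, seed=11)
    panel, truth = simulate_cohort(cfg)
    panel = apply_missingness(panel, cfg, seed=12)
    return panel, truth, cfg


@pytest.fixture(scope="session")
def unconfounded_cohort():
    """No-confounding cohort (initiation independent of severity)."""
    cfg = DGPConfig(n_patients=2000, seed=21, initiation_severity_slope=0.0)
    panel, truth = simulate_cohort(cfg)
    panel = apply_missingness(panel, cfg, seed=22)
    return panel, truth, cfg
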
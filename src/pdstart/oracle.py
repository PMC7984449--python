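"""Exhaustive-enumeration g-formula oracle on discrete-state toy processes.

Used to verify the parametric g-formula: on a small discrete process with
exactly known path probabilities, policy means can be computed by summing
over every state path — no models, no sampling.  When the parametric
g-formula is fit on a dataset enumerating every observational path with its
exact frequency, and the true conditional means are linear in the included
regressors, the two routes must agree to numerical precision.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EstimationError
from .panel import BASELINE_COVARIATES, TV_COVARIATES, CohortPanel

MAX_PATHS = 1_000_000


@dataclass(frozen=True)
class DiscreteDGP:
    """Finite-state severity process on the biannual grid.

    ``n_periods`` half-year periods (visits 0..n_periods).  The transition
    kernel gives P(next state | state, on_treatment); ``initiation`` gives
    the probability that an untreated patient at a visit starts treatment
    for the next period.  The outcome at the final visit is
    ``y0 + y_state * S_final + y_per_period * (#treated periods)``.
    """

    states: tuple[float, ...]
    p0: tuple[float, ...]
    transition: Mapping[tuple[float, int], tuple[float, ...]]
    initiation: Mapping[float, float]
    n_periods: int = 4
    y0: float = 0.0
    y_state: float = 1.0
    y_per_period: float = 0.0

    def __post_init__(self):
        if len(self.states) ** (self.n_periods + 1) > MAX_PATHS:
            raise ValueError("state-path space too large to enumerate")
        assert abs(sum(self.p0) - 1.0) < 1e-12

    def outcome(self, s_final: float, n_treated_periods: int) -> float:
        return self.y0 + self.y_state * s_final + self.y_per_period * n_treated_periods


def _policy_treatment_path(dgp: DiscreteDGP, duration_years: float) -> np.ndarray:
    """A[k] for visits k = 0..n_periods; start so that the last
    ``2 * duration`` periods of the window are treated."""
    n_treated = int(round(duration_years * 2))
    if abs(n_treated - duration_years * 2) > 1e-9 or not (0 < n_treated <= dgp.n_periods):
        raise ValueError(f"duration {duration_years} not on the half-year grid within the window")
    a = np.zeros(dgp.n_periods + 1, dtype=int)
    a[dgp.n_periods - n_treated + 1 :] = 1
    return a


def policy_mean(dgp: DiscreteDGP, duration_years: float) -> float:
    """Exact mean outcome under a fixed-duration policy, by path enumeration."""
    a = _policy_treatment_path(dgp, duration_years)
    total = 0.0
    n_states = len(dgp.states)
    for path in itertools.product(range(n_states), repeat=dgp.n_periods + 1):
        p = dgp.p0[path[0]]
        for k in range(1, dgp.n_periods + 1):
            p *= dgp.transition[(dgp.states[path[k - 1]], int(a[k]))][path[k]]
        if p == 0.0:
            continue
        total += p * dgp.outcome(dgp.states[path[-1]], int(a.sum()))
    return total


def nonparametric_gformula_oracle(
    dgp: DiscreteDGP, policies: Sequence[float]
) -> tuple[float, np.ndarray]:
    """Exact effect slope per +1 treatment-year over the policy grid."""
    pol = np.asarray(sorted(set(float(p) for p in policies)))
    if pol.size < 2:
        raise ValueError("need at least 2 policies for a slope")
    means = np.array([policy_mean(dgp, d) for d in pol])
    slope = float(np.polyfit(pol, means, 1)[0])
    return slope, means


def enumerate_observational(dgp: DiscreteDGP) -> tuple[CohortPanel, dict]:
    """Every observational (state path, initiation time) with exact probability.

    Returns a panel with one synthetic patient per path (the severity state
    stored as the primary motor score; all other scores and baseline
    covariates constant 0) and a patient_id -> probability weight map.
    Initiation decisions happen at visits 0..n_periods-1 with probability
    ``initiation[state]``; treatment is monotone.
    """
    K = dgp.n_periods
    n_states = len(dgp.states)
    grid = [k * 0.5 for k in range(K + 1)]
    rows, weights = [], {}
    pid = 0
    for path in itertools.product(range(n_states), repeat=K + 1):
        # first treated visit f in 1..K, or None (never within window)
        for f in list(range(1, K + 1)) + [None]:
            a = np.zeros(K + 1, dtype=int)
            if f is not None:
                a[f:] = 1
            p = dgp.p0[path[0]]
            for k in range(1, K + 1):
                p *= dgp.transition[(dgp.states[path[k - 1]], int(a[k]))][path[k]]
            # initiation factors: decisions at visits 0..K-1 while untreated
            last_decision = (f - 1) if f is not None else (K - 1)
            for j in range(0, last_decision + 1):
                q = dgp.initiation[dgp.states[path[j]]]
                p *= q if (f is not None and j == f - 1) else (1.0 - q)
            if p == 0.0:
                continue
            pid_str = f"path{pid:05d}"
            pid += 1
            weights[pid_str] = p
            s_final = dgp.states[path[-1]]
            y = dgp.outcome(s_final, int(a.sum()))
            for k in range(K + 1):
                row = {
                    "patient_id": pid_str,
                    "visit_time": grid[k],
                    "on_treatment": int(a[k]),
                    "outcome_observed": int(k == K),
                    "regimen": "toy" if a.max() else "",
                }
                for name in TV_COVARIATES:
                    row[name] = float(dgp.states[path[k]]) if name == "updrs3_off" else 0.0
                if k == K:
                    # the recorded outcome equals the final-state outcome
                    row["updrs3_off"] = y
                for name in BASELINE_COVARIATES:
                    row[name] = 0.0
                rows.append(row)
    if pid == 0:
        raise EstimationError("no observational path has positive probability")
    total = sum(weights.values())
    assert abs(total - 1.0) < 1e-9, f"path probabilities sum to {total}"
    return CohortPanel(pd.DataFrame(rows), require_monotone=True), weights
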
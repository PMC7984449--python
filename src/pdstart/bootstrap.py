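"""Patient-level bootstrap intervals for every estimator.

Whole patient trajectories are resampled with replacement (the conventional
nonparametric bootstrap; an m-out-of-n subsampling mode without replacement
is available since "subsampling the patients" can be read either way), and
the complete estimator pipeline — treatment models, weights, progression
models — is refit on every resample.  The reported interval is the point
estimate +/- 2 bootstrap standard deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from ._arrays import PanelArrays, from_panel
from .errors import EstimationError, InferenceError
from .estimators import METHODS, point_estimate

#: a replicate failing for these reasons is counted, not propagated
_REPLICATE_ERRORS = (EstimationError, np.linalg.LinAlgError, ValueError)


@dataclass
class BootstrapResult:
    """Bootstrap distribution summary for one (method, outcome, horizon)."""

    method: str
    outcome: str
    horizon: int
    point: float
    sd: float
    interval: tuple[float, float]
    replicate_estimates: np.ndarray
    n_failed: int
    n_used: int = 0
    diagnostics: dict = dc_field(default_factory=dict)


def bootstrap_estimate(
    panel,
    method: str,
    outcome: str = "updrs3_off",
    horizon: int = 2,
    repeats: int = 1000,
    seed: int | None = None,
    subsample_fraction: float | None = None,
    max_failed_fraction: float = 0.2,
    **estimator_kwargs,
) -> BootstrapResult:
    """Resample patients, refit the whole pipeline, return +/- 2 SD interval.

    Parameters
    ----------
    panel
        CohortPanel (or prepared PanelArrays) after exclusions/imputation.
    method
        One of ``pdstart.estimators.METHODS``.
    repeats
        Number of bootstrap replicates.
    seed
        Master seed; replicate streams are spawned deterministically from it
        (required — both resampling and the g-formula are stochastic).
    subsample_fraction
        If given, draw ``round(frac * n)`` patients *without* replacement per
        replicate instead of n with replacement.
    max_failed_fraction
        Raise InferenceError when more replicates than this fail.
    """
    if not callable(method) and method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if seed is None:
        raise InferenceError("bootstrap_estimate requires an explicit seed")
    pa = panel if isinstance(panel, PanelArrays) else from_panel(panel, outcome=outcome)
    n = pa.n

    def _run(bundle: PanelArrays, rng: np.random.Generator) -> float:
        if callable(method):
            return float(method(bundle, rng))
        return point_estimate(bundle, method, horizon, rng=rng, **estimator_kwargs)

    ss = np.random.SeedSequence(seed)
    point_rng = np.random.default_rng(ss.spawn(1)[0])
    point = _run(pa, point_rng)

    child_seeds = ss.spawn(repeats)
    if subsample_fraction is not None:
        m = int(round(subsample_fraction * n))
        if not (0 < m <= n):
            raise InferenceError(f"subsample_fraction {subsample_fraction} gives m={m}")
    estimates = []
    n_failed = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for child in child_seeds:
            rng = np.random.default_rng(child)
            if subsample_fraction is None:
                idx = rng.integers(0, n, size=n)
            else:
                idx = rng.permutation(n)[:m]
            try:
                estimates.append(_run(pa.take(idx), rng))
            except _REPLICATE_ERRORS:
                n_failed += 1
    if n_failed > max_failed_fraction * repeats:
        raise InferenceError(
            f"{n_failed}/{repeats} bootstrap replicates failed; interval unreliable"
        )
    est = np.asarray(estimates, dtype=float)
    sd = float(est.std(ddof=1)) if est.size > 1 else 0.0
    return BootstrapResult(
        method=method if isinstance(method, str) else getattr(method, "__name__", "custom"),
        outcome=pa.outcome_name,
        horizon=horizon,
        point=float(point),
        sd=sd,
        interval=(float(point - 2 * sd), float(point + 2 * sd)),
        replicate_estimates=est,
        n_failed=n_failed,
        n_used=n,
        diagnostics={
            "repeats": repeats,
            "subsample_fraction": subsample_fraction,
            "seed": seed,
        },
    )
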
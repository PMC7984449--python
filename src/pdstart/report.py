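"""Tabular and graphical reporting of effect estimates."""

from __future__ import annotations

import json
from typing import Sequence

import pandas as pd

from .bootstrap import BootstrapResult
from .estimators import EffectEstimate

TSV_COLUMNS = (
    "method",
    "outcome",
    "horizon",
    "effect_per_year",
    "ci_low",
    "ci_high",
    "n_used",
    "diagnostics",
)


def estimates_table(results: Sequence) -> pd.DataFrame:
    """Normalize EffectEstimate / BootstrapResult objects into one table."""
    rows = []
    for r in results:
        if isinstance(r, BootstrapResult):
            rows.append(
                {
                    "method": r.method,
                    "outcome": r.outcome,
                    "horizon": r.horizon,
                    "effect_per_year": r.point,
                    "ci_low": r.interval[0],
                    "ci_high": r.interval[1],
                    "n_used": r.n_used,
                    "diagnostics": json.dumps(
                        {**r.diagnostics, "bootstrap_sd": r.sd, "n_failed": r.n_failed},
                        sort_keys=True,
                    ),
                }
            )
        elif isinstance(r, EffectEstimate):
            lo, hi = (r.interval if r.interval else (None, None))
            rows.append(
                {
                    "method": r.method,
                    "outcome": r.outcome,
                    "horizon": r.horizon,
                    "effect_per_year": r.effect_per_year,
                    "ci_low": lo,
                    "ci_high": hi,
                    "n_used": r.n_used,
                    "diagnostics": json.dumps(
                        {**r.diagnostics, "stderr": r.stderr}, sort_keys=True, default=str
                    ),
                }
            )
        else:
            raise TypeError(f"cannot tabulate {type(r).__name__}")
    return pd.DataFrame(rows, columns=list(TSV_COLUMNS))


def write_estimates_tsv(results: Sequence, path) -> None:
    estimates_table(results).to_csv(path, sep="\t", index=False, float_format="%.6g")


def plot_method_comparison(results: Sequence, path) -> None:
    """Effect +/- interval per method, one panel per horizon (headless-safe)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = estimates_table(results)
    horizons = sorted(tab["horizon"].unique())
    fig, axes = plt.subplots(
        1, len(horizons), figsize=(4 * len(horizons), 4), sharey=True, squeeze=False
    )
    for ax, h in zip(axes[0], horizons):
        sub = tab[tab["horizon"] == h].reset_index(drop=True)
        y = range(len(sub))
        has_ci = sub["ci_low"].notna()
        err = [
            (sub["effect_per_year"] - sub["ci_low"]).where(has_ci, 0.0),
            (sub["ci_high"] - sub["effect_per_year"]).where(has_ci, 0.0),
        ]
        ax.errorbar(sub["effect_per_year"], y, xerr=err, fmt="o", capsize=3)
        ax.axvline(0.0, color="grey", lw=0.8, ls="--")
        ax.set_yticks(list(y))
        ax.set_yticklabels(sub["method"])
        ax.set_xlabel("effect per +1 treatment-year")
        ax.set_title(f"outcome at year {h}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
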
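"""Diagnostic plots: species response curves and paired-difference CIs."""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_species_curves(curves: pd.DataFrame, ax=None, top_n: int = 10):
    """Moving-average cover curves along the moisture axis.

    ``curves`` is the long table written by the stratify stage
    (species, grid_z, smoothed_cover); the ``top_n`` species by peak
    smoothed cover are drawn.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4.5))
    peaks = curves.groupby("species")["smoothed_cover"].max()
    for sp in peaks.sort_values(ascending=False).head(top_n).index:
        sub = curves[curves["species"] == sp].sort_values("grid_z")
        ax.plot(sub["grid_z"], sub["smoothed_cover"], label=sp, lw=1.5)
    ax.set_xlabel("soil water content (s.d. from meadow mean)")
    ax.set_ylabel("moving-average cover (%)")
    ax.legend(fontsize=7, ncols=2)
    return ax


def plot_paired_differences(
    estimates: pd.DataFrame,
    use_metric: pd.Series,
    response: str,
    stratum: str,
    log_x: bool = True,
    ax=None,
):
    """Bootstrapped differences vs a stock-use metric, with 95% CIs.

    ``use_metric`` maps pair_id to the x-axis stock-use value (e.g. max
    stock nights/ha); the x axis is natural-log scaled by default, the
    convention for stock-use gradients.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    sel = estimates[
        (estimates["response"] == response) & (estimates["stratum"] == stratum)
    ].copy()
    x = use_metric.loc[sel["pair_id"]].to_numpy(dtype=float)
    if log_x:
        x = np.log(np.maximum(x, 1e-9))
    ax.errorbar(
        x, sel["estimate"],
        yerr=[sel["estimate"] - sel["ci_low"], sel["ci_high"] - sel["estimate"]],
        fmt="o", capsize=3, ms=4,
    )
    ax.axhline(0.0, color="0.5", lw=0.8)
    ax.set_xlabel(("ln " if log_x else "") + str(use_metric.name))
    ax.set_ylabel(f"{response} ({stratum})")
    return ax
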
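"""Soil-moisture standardization, species response curves, and strata.

Within-meadow hydrology is expressed as a z-score: each plot's mean
volumetric water content (VWC) standardized to its own meadow's mean and
standard deviation.  Species response curves are two-sided moving
averages of cover along that axis.  Every plot is assigned to one of
three vegetation community types — Dry, Intermediate, Wet — by fixed
breaks on the z axis; the breaks are configuration (they mirror a visual
delineation of dominance turnover, not an estimated changepoint).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Dataset, MeadowPair, PlotSample

logger = logging.getLogger(__name__)

__all__ = [
    "STRATA",
    "DEFAULT_BREAKS",
    "MoistureAxis",
    "CommunityStrata",
    "standardize_vwc",
    "moving_average_cover",
    "assign_strata",
    "min_plots_filter",
]

STRATA = ("Dry", "Intermediate", "Wet")
#: Generator-aligned default breaks on the standardized moisture axis.
DEFAULT_BREAKS = (-0.5, 0.5)
#: Grid for response curves: 121 points spanning the -3..3 s.d. axis.
DEFAULT_GRID = np.linspace(-3.0, 3.0, 121)


@dataclass
class MoistureAxis:
    """Per-plot standardized moisture plus per-meadow summary stats."""

    z: pd.Series  # indexed by (meadow_id, plot_index)
    meadow_stats: pd.DataFrame  # index meadow_id, columns vwc_mean, vwc_sd

    def z_for(self, meadow_id: str, plot_index: int) -> float:
        return float(self.z.loc[(meadow_id, plot_index)])


@dataclass
class CommunityStrata:
    """Per-plot Dry/Intermediate/Wet assignment under fixed breaks."""

    breaks: tuple[float, float]
    stratum: pd.Series  # indexed by (meadow_id, plot_index)

    def stratum_for(self, meadow_id: str, plot_index: int) -> str:
        return str(self.stratum.loc[(meadow_id, plot_index)])

    def counts(self) -> pd.DataFrame:
        df = self.stratum.rename("stratum").reset_index()
        return (
            df.groupby(["meadow_id", "stratum"], observed=True)
            .size()
            .rename("n_plots")
            .reset_index()
        )


def standardize_vwc(plots: list[PlotSample]) -> MoistureAxis:
    """Standardize plot VWC to each meadow's own mean and s.d.

    Meadows with zero VWC variance get z = 0 for all plots (with a
    warning), so downstream stratification still sees every plot.
    """
    df = pd.DataFrame(
        {
            "meadow_id": [p.meadow_id for p in plots],
            "plot_index": [p.plot_index for p in plots],
            "vwc": [p.vwc_mean for p in plots],
        }
    )
    stats = df.groupby("meadow_id")["vwc"].agg(["mean", "std"])
    stats.columns = ["vwc_mean", "vwc_sd"]
    degenerate = stats.index[
        (stats["vwc_sd"].isna()) | (stats["vwc_sd"] == 0.0)
    ].tolist()
    if degenerate:
        warnings.warn(
            f"meadows with zero VWC variance, z set to 0: {degenerate}"
        )
    merged = df.merge(stats, left_on="meadow_id", right_index=True)
    sd = merged["vwc_sd"].replace(0.0, np.nan)
    z = ((merged["vwc"] - merged["vwc_mean"]) / sd).fillna(0.0)
    z.index = pd.MultiIndex.from_arrays(
        [merged["meadow_id"], merged["plot_index"]],
        names=["meadow_id", "plot_index"],
    )
    return MoistureAxis(z=z, meadow_stats=stats)


def moving_average_cover(
    cover: np.ndarray,
    z: np.ndarray,
    grid: np.ndarray | None = None,
    window_width: float = 0.25,
    half_width_mode: bool = False,
) -> np.ndarray:
    """Two-sided running mean of cover along the moisture axis.

    At each grid point the value is the plain mean of ``cover`` over plots
    whose z lies within the window; empty windows yield NaN.  The stated
    window width of 0.25 s.d. is read as the TOTAL width (plots within
    +/- 0.125 s.d.); set ``half_width_mode`` for the alternative reading
    (+/- 0.25 s.d.).
    """
    if not window_width > 0:
        raise ValueError("window_width must be positive")
    cover = np.asarray(cover, dtype=float)
    z = np.asarray(z, dtype=float)
    if cover.shape != z.shape:
        raise ValueError("cover and z must align")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    half = window_width if half_width_mode else window_width / 2.0
    out = np.full(grid.shape, np.nan)
    for i, g in enumerate(grid):
        mask = np.abs(z - g) <= half
        if mask.any():
            out[i] = cover[mask].mean()
    return out


def assign_strata(
    axis: MoistureAxis, breaks: tuple[float, float] = DEFAULT_BREAKS
) -> CommunityStrata:
    """Three-way Dry/Intermediate/Wet assignment from fixed z breaks.

    Dry: z < breaks[0]; Wet: z >= breaks[1] (boundaries fall into the
    wetter stratum); Intermediate otherwise.
    """
    b_dry, b_wet = breaks
    if not b_dry < b_wet:
        raise ValueError("breaks must satisfy b_dry_int < b_int_wet")
    z = axis.z
    labels = np.where(z < b_dry, "Dry", np.where(z >= b_wet, "Wet", "Intermediate"))
    stratum = pd.Series(labels, index=z.index, name="stratum")
    counts = stratum.groupby(level="meadow_id").value_counts()
    logger.info("stratum counts per meadow:\n%s", counts)
    return CommunityStrata(breaks=(b_dry, b_wet), stratum=stratum)


def min_plots_filter(
    pairs: list[MeadowPair],
    strata: CommunityStrata,
    dataset: Dataset,
    required: int = 3,
    species_only: bool = False,
) -> set[tuple[str, str]]:
    """Retain (pair, stratum) cells where both meadows have enough plots.

    A cell survives only if the stock AND control meadow each contribute
    at least ``required`` plots of that stratum.  For composition
    responses (``species_only``) only species plots count; bare ground
    draws on all plots.  The pseudo-stratum ``"All"`` ignores strata and
    applies the same rule to whole meadows.
    """
    plot_ok = {
        (p.meadow_id, p.plot_index): (p.has_species_data or not species_only)
        for p in dataset.plots
    }
    counts: dict[tuple[str, str], int] = {}
    for (mid, pidx), stratum in strata.stratum.items():
        if plot_ok.get((mid, pidx), False):
            counts[(mid, stratum)] = counts.get((mid, stratum), 0) + 1
            counts[(mid, "All")] = counts.get((mid, "All"), 0) + 1

    retained: set[tuple[str, str]] = set()
    for pair in pairs:
        for stratum in STRATA + ("All",):
            n_s = counts.get((pair.stock_meadow_id, stratum), 0)
            n_c = counts.get((pair.control_meadow_id, stratum), 0)
            if n_s >= required and n_c >= required:
                retained.add((pair.pair_id, stratum))
            else:
                logger.info(
                    "dropped (%s, %s): %d stock / %d control plots",
                    pair.pair_id, stratum, n_s, n_c,
                )
    return retained
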
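"""Model/Results facade for the full paired stock-effects analysis.

:class:`PackStockModel` is built from a validated dataset plus the list of
matched meadow pairs; :meth:`PackStockModel.fit` runs moisture
stratification, the three community responses, the paired bootstrap, and
CART variance attribution, returning a :class:`PackStockResults` that
carries the per-pair estimates with their confidence intervals, the 12
attribution models, diagnostics, and a text ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bootstrap import (
    PairedDifferenceEstimate,
    boot_dissimilarity,
    boot_dispersion_diff,
    boot_mean_diff,
)
from .cart import (
    ContributionTable,
    contributions_frame,
    pair_explanatory_table,
    run_all_models,
)
from .io import Dataset, MeadowPair, read_tables
from .matching import filter_eligible_stock, match_meadows, matches_to_pairs
from .responses import (
    bare_veg_correlation,
    plot_dispersions_for_meadow,
    subplot_matrix,
)
from .stratify import (
    DEFAULT_BREAKS,
    STRATA,
    CommunityStrata,
    MoistureAxis,
    assign_strata,
    min_plots_filter,
    standardize_vwc,
)

logger = logging.getLogger(__name__)

__all__ = ["PackStockModel", "PackStockResults"]

_ALL = ("All",) + STRATA


class PackStockModel:
    """Paired stock-vs-control analysis of meadow plant communities.

    Parameters
    ----------
    dataset
        Validated bundle of meadows, stock use, plots and subplot covers.
    pairs
        Matched stock/control pairs.  If omitted, pairs are produced by
        eligibility filtering and Mahalanobis matching on the dataset's
        own meadow pool.
    breaks
        Fixed (dry|intermediate, intermediate|wet) breaks on the
        meadow-standardized soil-moisture axis.
    b_reps, seed
        Bootstrap replicates per cell and master seed for the per-cell
        substreams.
    min_plots
        Minimum plots per meadow per stratum for a (pair, stratum) cell
        to enter the analysis.
    """

    def __init__(
        self,
        dataset: Dataset,
        pairs: list[MeadowPair] | None = None,
        breaks: tuple[float, float] = DEFAULT_BREAKS,
        b_reps: int = 1000,
        seed: int = 0,
        min_plots: int = 3,
        cart_kwargs: dict | None = None,
    ) -> None:
        self.dataset = dataset
        self.pairs = pairs
        self.breaks = breaks
        self.b_reps = b_reps
        self.seed = seed
        self.min_plots = min_plots
        self.cart_kwargs = cart_kwargs or {}

    @classmethod
    def from_csv(
        cls,
        meadows_path: str | Path,
        stock_use_path: str | Path,
        plots_path: str | Path,
        subplots_path: str | Path,
        pairs: list[MeadowPair] | None = None,
        **kwargs,
    ) -> "PackStockModel":
        dataset = read_tables(
            meadows_path, stock_use_path, plots_path, subplots_path
        )
        return cls(dataset, pairs=pairs, **kwargs)

    # -- pipeline stages ---------------------------------------------------

    def _ensure_pairs(self) -> list[MeadowPair]:
        if self.pairs is not None:
            return self.pairs
        ds = self.dataset
        eligible = filter_eligible_stock(ds.meadows, ds.stock_use)
        matches = match_meadows(eligible, ds.meadows, ds.stock_use, ds.registry)
        self.pairs = matches_to_pairs(matches)
        return self.pairs

    def _strata_of(self, strata: CommunityStrata, mid: str) -> dict[int, str]:
        sel = strata.stratum.xs(mid, level="meadow_id")
        return {int(k): str(v) for k, v in sel.items()}

    def fit(self) -> "PackStockResults":
        ds = self.dataset
        pairs = self._ensure_pairs()
        axis = standardize_vwc(ds.plots)
        strata = assign_strata(axis, self.breaks)

        retained_all = min_plots_filter(
            pairs, strata, ds, required=self.min_plots, species_only=False
        )
        retained_species = min_plots_filter(
            pairs, strata, ds, required=self.min_plots, species_only=True
        )

        species = ds.species_names
        # per-meadow caches: plot strata, plot-mean cover vectors, dispersions
        meadow_ids = sorted(
            {p.stock_meadow_id for p in pairs} | {p.control_meadow_id for p in pairs}
        )
        plot_stratum: dict[str, dict[int, str]] = {}
        bare: dict[str, dict[int, float]] = {}
        plot_means: dict[str, dict[int, np.ndarray]] = {}
        dispersions: dict[str, dict[int, float]] = {}
        for mid in meadow_ids:
            plot_stratum[mid] = self._strata_of(strata, mid)
            mplots = ds.plots_for(mid)
            bare[mid] = {p.plot_index: p.bare_ground_pct for p in mplots}
            sp_plots = [p.plot_index for p in mplots if p.has_species_data]
            pm: dict[int, np.ndarray] = {}
            for pidx in sp_plots:
                subs = ds.subplots_for(mid, pidx)
                if subs:
                    pm[pidx] = subplot_matrix(subs, species).mean(axis=0)
            plot_means[mid] = pm
            dispersions[mid] = plot_dispersions_for_meadow(ds, mid, sp_plots)

        def in_stratum(mid: str, pidx: int, stratum: str) -> bool:
            return stratum == "All" or plot_stratum[mid].get(pidx) == stratum

        estimates: list[PairedDifferenceEstimate] = []
        for pair in pairs:
            smid, cmid = pair.stock_meadow_id, pair.control_meadow_id
            for stratum in _ALL:
                if (pair.pair_id, stratum) in retained_all:
                    sv = np.array(
                        [v for p, v in bare[smid].items()
                         if in_stratum(smid, p, stratum)]
                    )
                    cv = np.array(
                        [v for p, v in bare[cmid].items()
                         if in_stratum(cmid, p, stratum)]
                    )
                    estimates.append(
                        boot_mean_diff(
                            sv, cv, pair.pair_id, stratum,
                            b_reps=self.b_reps, seed=self.seed,
                        )
                    )
                if (pair.pair_id, stratum) in retained_species:
                    sm = np.array(
                        [v for p, v in plot_means[smid].items()
                         if in_stratum(smid, p, stratum)]
                    )
                    cm = np.array(
                        [v for p, v in plot_means[cmid].items()
                         if in_stratum(cmid, p, stratum)]
                    )
                    if sm.size and cm.size:
                        estimates.append(
                            boot_dissimilarity(
                                sm, cm, pair.pair_id, stratum,
                                b_reps=self.b_reps, seed=self.seed,
                            )
                        )
                    sd = np.array(
                        [v for p, v in dispersions[smid].items()
                         if in_stratum(smid, p, stratum)]
                    )
                    cd = np.array(
                        [v for p, v in dispersions[cmid].items()
                         if in_stratum(cmid, p, stratum)]
                    )
                    if sd.size >= self.min_plots and cd.size >= self.min_plots:
                        estimates.append(
                            boot_dispersion_diff(
                                sd, cd, pair.pair_id, stratum,
                                b_reps=self.b_reps, seed=self.seed,
                            )
                        )

        explanatory = pair_explanatory_table(
            pairs, ds.meadows, ds.stock_use, ds.registry
        )
        models = run_all_models(estimates, explanatory, **self.cart_kwargs)
        diagnostics = bare_veg_correlation(ds.plots)
        return PackStockResults(
            model=self,
            pairs=pairs,
            axis=axis,
            strata=strata,
            estimates=estimates,
            explanatory=explanatory,
            attribution=models,
            diagnostics=diagnostics,
        )


@dataclass
class PackStockResults:
    """Fitted results: estimates, attribution models, and diagnostics."""

    model: PackStockModel
    pairs: list[MeadowPair]
    axis: MoistureAxis
    strata: CommunityStrata
    estimates: list[PairedDifferenceEstimate]
    explanatory: pd.DataFrame
    attribution: dict[tuple[str, str], ContributionTable | str]
    diagnostics: dict[str, float] = field(default_factory=dict)

    def estimates_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "pair_id": e.pair_id, "stratum": e.stratum,
                    "response": e.response, "estimate": e.estimate,
                    "ci_low": e.ci_low, "ci_high": e.ci_high,
                    "n_stock": e.n_stock, "n_control": e.n_control,
                    "significant": int(e.significant), "seed": e.seed,
                }
                for e in self.estimates
            ]
        )

    def contributions_frame(self) -> pd.DataFrame:
        return contributions_frame(self.attribution)

    def category_table(self) -> pd.DataFrame:
        """Category contributions per model, in the 3 x 4 grid layout."""
        rows = []
        for (response, stratum), res in self.attribution.items():
            if isinstance(res, str):
                continue
            row = {"response": response, "stratum": stratum,
                   "r2": res.r2, "n_pairs": res.n}
            row.update(res.by_category)
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Pack-stock meadow analysis", "=" * 60]
        lines.append(f"pairs: {len(self.pairs)}   "
                     f"bootstrap B: {self.model.b_reps}   "
                     f"seed: {self.model.seed}")
        lines.append(
            f"moisture breaks (z): {self.strata.breaks[0]:+.2f} / "
            f"{self.strata.breaks[1]:+.2f}"
        )
        lines.append(
            "bare vs vegetation cover r = "
            f"{self.diagnostics.get('bare_vs_veg', float('nan')):+.2f}; "
            "bare vs veg+litter r = "
            f"{self.diagnostics.get('bare_vs_veg_plus_litter', float('nan')):+.2f}"
        )
        lines.append("")
        lines.append("CART attribution (% of total SS by covariate class)")
        lines.append(
            f"{'response':<18}{'stratum':<14}{'n':>3}{'R2':>7}"
            f"{'StockUse':>10}{'Within':>8}{'Between':>9}"
        )
        for (response, stratum), res in self.attribution.items():
            if isinstance(res, str):
                lines.append(f"{response:<18}{stratum:<14}  - {res}")
                continue
            lines.append(
                f"{response:<18}{stratum:<14}{res.n:>3}{res.r2:>7.2f}"
                f"{res.by_category['StockUse']:>10.1f}"
                f"{res.by_category['WithinPair']:>8.1f}"
                f"{res.by_category['BetweenPairs']:>9.1f}"
            )
        n_sig = sum(
            1 for e in self.estimates
            if e.response != "dissimilarity" and e.significant
        )
        lines.append("")
        lines.append(
            f"paired-difference cells: {len(self.estimates)} "
            f"({n_sig} difference CIs exclude 0)"
        )
        return "\n".join(lines)
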
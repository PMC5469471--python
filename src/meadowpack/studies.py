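"""Self-contained validation studies on the synthetic landscape.

These functions run the full machinery under controlled conditions and
return summary numbers: bootstrap CI coverage under exchangeability,
recovery of injected disturbance effects (bare-ground increase in dry
strata of heavily used meadows; dispersion inflation in wet strata), and
the attribution behaviour of the CART stage under a null landscape.
They are used both by the test suite and by the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .bootstrap import boot_mean_diff
from .io import MeadowRecord, compute_stock_metrics
from .matching import filter_eligible_stock, match_meadows, matches_to_pairs
from .model import PackStockModel, PackStockResults
from .registry import default_registry
from .simulate import (
    EffectConfig,
    SpeciesNiche,
    generate_dataset,
    generate_landscape,
    generate_meadow_plots,
)

__all__ = [
    "twin_pair_coverage",
    "fit_synthetic_landscape",
    "effect_recovery_study",
    "null_attribution_study",
]


def _sub_seed(seed: int, k: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(k,))
    return int(ss.generate_state(1)[0] & 0x7FFF_FFFF)


def twin_pair_coverage(
    n_pairs: int = 500, seed: int = 0, b_reps: int = 1000
) -> float:
    """95% CI coverage of zero for exchangeable twin meadows.

    Each simulated pair is two independent samplings of the *same* meadow
    (identical covariates, no stock effects), so the true difference is
    zero and a well-calibrated percentile bootstrap CI should cover zero
    in ~95% of pairs.
    """
    reg = default_registry()
    template = MeadowRecord(
        meadow_id="TWIN", park="YOSE", area_ha=2.0,
        centroid_x=0.0, centroid_y=0.0,
        covariates={c: 0.0 for c in reg.names}, role="nonstock",
    )
    niches = [SpeciesNiche("carex", 0.0, 1.5, 25.0, 1.0)]
    covered = 0
    for k in range(n_pairs):
        # gradient-free twins: plot values are iid draws, the regime the
        # bootstrap's plot-resampling assumes
        plots_s, _ = generate_meadow_plots(
            template, niches, moisture_gradient=0.0,
            seed=_sub_seed(seed, 2 * k),
        )
        plots_c, _ = generate_meadow_plots(
            template, niches, moisture_gradient=0.0,
            seed=_sub_seed(seed, 2 * k + 1),
        )
        est = boot_mean_diff(
            np.array([p.bare_ground_pct for p in plots_s]),
            np.array([p.bare_ground_pct for p in plots_c]),
            f"T{k}", "All", b_reps=b_reps, seed=_sub_seed(seed, 10_000 + k),
        )
        covered += est.ci_low <= 0.0 <= est.ci_high
    return covered / n_pairs


def fit_synthetic_landscape(
    seed: int,
    n_meadows: int = 1000,
    n_stock: int = 22,
    effect_config: EffectConfig | None = None,
    b_reps: int = 1000,
) -> tuple[PackStockResults, dict]:
    """Generate, match, sample and fit one landscape; returns results
    plus the per-stock-meadow use metrics."""
    meadows, stock_use = generate_landscape(
        n_meadows=n_meadows, n_stock=n_stock, seed=seed
    )
    eligible = filter_eligible_stock(meadows, stock_use)
    pairs = matches_to_pairs(match_meadows(eligible, meadows, stock_use))
    sampled = sorted(
        {p.stock_meadow_id for p in pairs} | {p.control_meadow_id for p in pairs}
    )
    dataset = generate_dataset(
        sampled, meadows, stock_use, effect_config=effect_config, seed=seed
    )
    model = PackStockModel(dataset, pairs=pairs, b_reps=b_reps, seed=seed)
    results = model.fit()
    metrics = {
        p.stock_meadow_id: compute_stock_metrics(
            stock_use[p.stock_meadow_id], meadows[p.stock_meadow_id].area_ha
        )
        for p in pairs
    }
    return results, metrics


def top2_use_threshold(metrics: dict) -> float:
    """Stock-density threshold isolating the two most heavily used
    meadows (midpoint between the 2nd and 3rd largest max nights/ha)."""
    dens = sorted((m.max_nights_per_ha for m in metrics.values()), reverse=True)
    if len(dens) < 3:
        return 0.0
    return (dens[1] + dens[2]) / 2.0


def effect_recovery_study(
    seed: int = 0,
    bare_dry_effect: float = 50.0,
    wet_dispersion_factor: float = 3.0,
    n_meadows: int = 1000,
    n_stock: int = 22,
    b_reps: int = 1000,
) -> dict:
    """Inject disturbance at the two most heavily used meadows and ask
    the pipeline to find it.

    Mirrors the field pattern under study: a bare-ground increase in dry
    strata confined to the highest stock densities, and wet-stratum
    dispersion inflation growing with inter-annual use variability.
    """
    # pass 1 (no effects) only to learn the use distribution for this seed
    meadows, stock_use = generate_landscape(
        n_meadows=n_meadows, n_stock=n_stock, seed=seed
    )
    eligible = filter_eligible_stock(meadows, stock_use)
    pairs = matches_to_pairs(match_meadows(eligible, meadows, stock_use))
    metrics = {
        p.stock_meadow_id: compute_stock_metrics(
            stock_use[p.stock_meadow_id], meadows[p.stock_meadow_id].area_ha
        )
        for p in pairs
    }
    threshold = top2_use_threshold(metrics)
    eff = EffectConfig(
        bare_dry_effect=bare_dry_effect,
        use_threshold=threshold,
        wet_dispersion_factor=wet_dispersion_factor,
    )
    results, _ = fit_synthetic_landscape(
        seed, n_meadows=n_meadows, n_stock=n_stock,
        effect_config=eff, b_reps=b_reps,
    )
    # the zero-effect generator reproduces the identical field draws, so
    # differencing against the null fit isolates the injected shift
    results_null, _ = fit_synthetic_landscape(
        seed, n_meadows=n_meadows, n_stock=n_stock,
        effect_config=EffectConfig(), b_reps=b_reps,
    )
    affected = {
        p.pair_id
        for p in results.pairs
        if metrics[p.stock_meadow_id].max_nights_per_ha > threshold
    }
    ef = results.estimates_frame()
    dry_bare = ef[
        (ef.response == "bare_ground_diff") & (ef.stratum == "Dry")
        & (ef.pair_id.isin(affected))
    ]
    ef0 = results_null.estimates_frame()
    dry_bare_null = ef0[
        (ef0.response == "bare_ground_diff") & (ef0.stratum == "Dry")
        & (ef0.pair_id.isin(affected))
    ]
    injected_recovery = (
        dry_bare.set_index("pair_id")["estimate"]
        - dry_bare_null.set_index("pair_id")["estimate"]
    )
    # wet-stratum dispersion: the effect scales with sd of stock nights,
    # so the pairs with the highest inter-annual variability carry it
    top_sd = sorted(
        metrics, key=lambda m: -metrics[m].sd_nights
    )[:2]
    top_sd_pairs = {
        p.pair_id for p in results.pairs if p.stock_meadow_id in top_sd
    }
    wet_disp = ef[
        (ef.response == "dispersion_diff") & (ef.stratum == "Wet")
        & (ef.pair_id.isin(top_sd_pairs))
    ]
    dry_model = results.attribution[("bare_ground_diff", "Dry")]
    wet_model = results.attribution[("dispersion_diff", "Wet")]
    r2s = [
        t.r2 for t in results.attribution.values()
        if not isinstance(t, str) and t.r2 > 0
    ]
    out = {
        "threshold_max_nights_per_ha": threshold,
        "n_affected_pairs": len(affected),
        "dry_bare_estimates": dry_bare["estimate"].tolist(),
        "dry_bare_ci_low": dry_bare["ci_low"].tolist(),
        "dry_bare_all_significant": bool((dry_bare["ci_low"] > 0).all())
        and len(dry_bare) > 0,
        "injected_bare_effect": bare_dry_effect,
        "isolated_effect_estimates": injected_recovery.tolist(),
        "wet_dispersion_estimates": wet_disp["estimate"].tolist(),
        "wet_dispersion_positive_significant": bool(
            len(wet_disp) > 0 and (wet_disp["ci_low"] > 0).any()
        ),
        "r2_range": (min(r2s), max(r2s)) if r2s else (0.0, 0.0),
        "results": results,
    }
    for name, model in (("dry_bare", dry_model), ("wet_dispersion", wet_model)):
        if isinstance(model, str):
            out[f"{name}_top_covariate"] = ""
            out[f"{name}_top_pct"] = 0.0
            out[f"{name}_stockuse_pct"] = 0.0
        else:
            cov, pct = model.top_covariate()
            out[f"{name}_top_covariate"] = cov
            out[f"{name}_top_pct"] = pct
            out[f"{name}_stockuse_pct"] = model.by_category["StockUse"]
    return out


def null_attribution_study(
    seeds: tuple[int, ...], n_meadows: int = 1000, n_stock: int = 22,
    b_reps: int = 1000,
) -> dict:
    """Stock-use attribution across replicate null landscapes.

    With no injected effects the stock metrics are pure noise, so the
    CART stage should attribute (almost) nothing to the Stock Use class;
    greedy trees at ~22 rows retain an occasional spurious >10%-of-SS
    split, so the headline number is the mean contribution over all
    fitted models.
    """
    contribs: list[float] = []
    for seed in seeds:
        results, _ = fit_synthetic_landscape(
            seed, n_meadows=n_meadows, n_stock=n_stock,
            effect_config=EffectConfig(), b_reps=b_reps,
        )
        for table in results.attribution.values():
            if not isinstance(table, str):
                contribs.append(table.by_category["StockUse"])
    arr = np.array(contribs)
    return {
        "n_models": len(arr),
        "mean_stockuse_pct": float(arr.mean()) if len(arr) else 0.0,
        "n_zero": int((arr == 0.0).sum()),
        "max_stockuse_pct": float(arr.max()) if len(arr) else 0.0,
    }
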
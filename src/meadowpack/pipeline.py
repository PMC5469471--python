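"""File-based pipeline stages: simulate, match, stratify, responses,
bootstrap, cart.

Each stage reads the CSV artifacts of earlier stages from the working
directory, writes its own CSVs plus a manifest entry (inputs hashed, seed,
row counts), and is idempotent given identical inputs and configuration.
The stages mirror the field workflow: the landscape (or user data) exists
first, matching selects the sampled meadows, and the statistical stages
run on the sampled tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate as sim
from .cart import pair_explanatory_table, run_all_models, contributions_frame
from .io import Dataset, MeadowPair, read_tables, write_tables
from .matching import (
    filter_eligible_stock,
    match_meadows,
    matches_to_pairs,
    pairs_to_frame,
)
from .model import PackStockModel
from .registry import default_registry
from .responses import bare_veg_correlation
from .stratify import (
    DEFAULT_BREAKS,
    DEFAULT_GRID,
    assign_strata,
    moving_average_cover,
    standardize_vwc,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "match", "stratify", "responses", "bootstrap", "cart")

__all__ = ["PipelineConfig", "run", "STAGES"]


@dataclass
class PipelineConfig:
    """Declarative configuration for an end-to-end run."""

    outdir: Path = Path("meadowpack_out")
    seed: int = 0
    # generator
    n_meadows: int = 1000
    n_stock: int = 22
    bare_dry_effect: float = 0.0
    use_threshold: float = 0.0
    wet_dispersion_factor: float = 0.0
    n_transects: int = 6
    plots_per_transect: int = 8
    # matching
    top_k_per_park: int = 20
    top_n_candidates: int = 3
    # stratification
    breaks: tuple[float, float] = DEFAULT_BREAKS
    window_width: float = 0.25
    # bootstrap
    b_reps: int = 1000
    # cart
    min_split: int = 5
    min_leaf: int = 2
    prune_frac: float = 0.10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key {k!r}")
            if k == "outdir":
                v = Path(v)
            if k == "breaks":
                v = tuple(float(b) for b in v)
            setattr(cfg, k, v)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _append_manifest(outdir: Path, entry: dict) -> None:
    manifest = outdir / "manifest.json"
    entries = []
    if manifest.exists():
        entries = json.loads(manifest.read_text())
    entries = [e for e in entries if e.get("stage") != entry["stage"]]
    entries.append(entry)
    manifest.write_text(json.dumps(entries, indent=2, sort_keys=True) + "\n")


def _require(outdir: Path, names: list[str], stage: str) -> list[Path]:
    paths = [outdir / n for n in names]
    missing = [str(p) for p in paths if not p.exists()]
    if missing:
        raise FileNotFoundError(
            f"stage {stage!r} requires missing artifacts: {missing}"
        )
    return paths


def _load_dataset(outdir: Path, stage: str) -> Dataset:
    paths = _require(
        outdir,
        ["meadows.csv", "stock_use.csv", "plots.csv", "species_cover.csv"],
        stage,
    )
    return read_tables(*paths)


def _load_pairs(outdir: Path, stage: str) -> list[MeadowPair]:
    (path,) = _require(outdir, ["pairs.csv"], stage)
    df = pd.read_csv(path, dtype={"stock_meadow_id": str, "control_meadow_id": str})
    return [
        MeadowPair(
            pair_id=row["pair_id"],
            stock_meadow_id=row["stock_meadow_id"],
            control_meadow_id=row["control_meadow_id"],
            match_rank=int(row["rank"]),
            mahalanobis_distance=float(row["distance"]),
            override=bool(row["override_flag"]),
        )
        for _, row in df.iterrows()
    ]


def stage_simulate(cfg: PipelineConfig) -> dict:
    """Generate the landscape, pick the sampled meadows, write the tables.

    Matching is run internally (exactly as the match stage will re-run
    it) purely to decide which meadows receive field sampling, mirroring
    a campaign where control selection precedes the field visit.
    """
    meadows, stock_use = sim.generate_landscape(
        n_meadows=cfg.n_meadows, n_stock=cfg.n_stock, seed=cfg.seed
    )
    eligible = filter_eligible_stock(
        meadows, stock_use, top_k_per_park=cfg.top_k_per_park
    )
    matches = match_meadows(
        eligible, meadows, stock_use, top_n=cfg.top_n_candidates
    )
    pairs = matches_to_pairs(matches)
    sampled = sorted(
        {p.stock_meadow_id for p in pairs} | {p.control_meadow_id for p in pairs}
    )
    effect = sim.EffectConfig(
        bare_dry_effect=cfg.bare_dry_effect,
        use_threshold=cfg.use_threshold,
        wet_dispersion_factor=cfg.wet_dispersion_factor,
        dry_break=cfg.breaks[0],
        wet_break=cfg.breaks[1],
    )
    sampled_ds = sim.generate_dataset(
        sampled, meadows, stock_use,
        effect_config=effect, seed=cfg.seed,
        n_transects=cfg.n_transects,
        plots_per_transect=cfg.plots_per_transect,
    )
    # the landscape tables carry ALL meadows so matching can be re-run
    full = Dataset(
        meadows=meadows, stock_use=stock_use,
        plots=sampled_ds.plots, subplots=sampled_ds.subplots,
        registry=sampled_ds.registry,
    )
    paths = write_tables(full, cfg.outdir)
    return {
        "n_meadows": len(meadows),
        "n_sampled": len(sampled),
        "outputs": {k: str(v) for k, v in paths.items()},
    }


def stage_match(cfg: PipelineConfig) -> dict:
    ds = _load_dataset(cfg.outdir, "match")
    eligible = filter_eligible_stock(
        ds.meadows, ds.stock_use, top_k_per_park=cfg.top_k_per_park
    )
    # manual control-selection overrides, if the field crew recorded any
    overrides: dict[str, str] = {}
    ov_path = cfg.outdir / "overrides.csv"
    if ov_path.exists():
        odf = pd.read_csv(
            ov_path, dtype={"stock_meadow_id": str, "control_meadow_id": str}
        )
        overrides = dict(
            zip(odf["stock_meadow_id"], odf["control_meadow_id"])
        )
        logger.info("applying %d matching overrides", len(overrides))
    matches = match_meadows(
        eligible, ds.meadows, ds.stock_use, ds.registry,
        top_n=cfg.top_n_candidates, overrides=overrides,
    )
    df = pairs_to_frame(matches)
    out = cfg.outdir / "pairs.csv"
    df.to_csv(out, index=False)
    return {"n_pairs": len(df), "outputs": {"pairs": str(out)}}


def stage_stratify(cfg: PipelineConfig) -> dict:
    ds = _load_dataset(cfg.outdir, "stratify")
    axis = standardize_vwc(ds.plots)
    strata = assign_strata(axis, cfg.breaks)
    sdf = pd.DataFrame(
        {
            "meadow_id": [i[0] for i in axis.z.index],
            "plot": [i[1] for i in axis.z.index],
            "z": axis.z.to_numpy(),
            "stratum": strata.stratum.to_numpy(),
        }
    )
    strata_path = cfg.outdir / "strata.csv"
    sdf.to_csv(strata_path, index=False)

    # species response curves along the moisture axis (plot-mean cover)
    zmap = {(m, p): z for (m, p), z in axis.z.items()}
    rows = []
    by_plot: dict[tuple[str, int], dict[str, list[float]]] = {}
    for sc in ds.subplots:
        acc = by_plot.setdefault((sc.meadow_id, sc.plot_index), {})
        for sp, v in sc.cover.items():
            acc.setdefault(sp, []).append(v)
    species = ds.species_names
    if by_plot:
        keys = sorted(by_plot)
        zs = np.array([zmap[k] for k in keys])
        for sp in species:
            cover = np.array(
                [sum(by_plot[k].get(sp, [])) / 8.0 for k in keys]
            )
            curve = moving_average_cover(
                cover, zs, DEFAULT_GRID, window_width=cfg.window_width
            )
            for g, v in zip(DEFAULT_GRID, curve):
                if not np.isnan(v):
                    rows.append(
                        {"species": sp, "grid_z": g, "smoothed_cover": v}
                    )
    curves_path = cfg.outdir / "curves.csv"
    pd.DataFrame(rows, columns=["species", "grid_z", "smoothed_cover"]).to_csv(
        curves_path, index=False
    )
    return {
        "n_plots": len(sdf),
        "outputs": {"strata": str(strata_path), "curves": str(curves_path)},
    }


def stage_responses(cfg: PipelineConfig) -> dict:
    ds = _load_dataset(cfg.outdir, "responses")
    pairs = _load_pairs(cfg.outdir, "responses")
    _require(cfg.outdir, ["strata.csv"], "responses")
    sdf = pd.read_csv(cfg.outdir / "strata.csv", dtype={"meadow_id": str})
    stratum_of = {
        (row["meadow_id"], int(row["plot"])): row["stratum"]
        for _, row in sdf.iterrows()
    }
    from .responses import plot_dispersions_for_meadow

    pair_of = {}
    for p in pairs:
        pair_of[p.stock_meadow_id] = p.pair_id
        pair_of[p.control_meadow_id] = p.pair_id
    rows = []
    for p in ds.plots:
        if p.meadow_id not in pair_of:
            continue
        rows.append(
            {
                "pair_id": pair_of[p.meadow_id], "meadow_id": p.meadow_id,
                "stratum": stratum_of.get((p.meadow_id, p.plot_index), ""),
                "response_name": "bare_ground", "unit_id": p.plot_index,
                "value": p.bare_ground_pct,
            }
        )
    for mid in sorted(set(pair_of)):
        sp_plots = [
            p.plot_index for p in ds.plots_for(mid) if p.has_species_data
        ]
        for pidx, disp in plot_dispersions_for_meadow(ds, mid, sp_plots).items():
            rows.append(
                {
                    "pair_id": pair_of[mid], "meadow_id": mid,
                    "stratum": stratum_of.get((mid, pidx), ""),
                    "response_name": "dispersion", "unit_id": pidx,
                    "value": disp,
                }
            )
    out = cfg.outdir / "responses.csv"
    pd.DataFrame(
        rows,
        columns=["pair_id", "meadow_id", "stratum", "response_name",
                 "unit_id", "value"],
    ).to_csv(out, index=False)
    corr = bare_veg_correlation(ds.plots)
    return {"n_rows": len(rows), "diagnostics": corr, "outputs": {"responses": str(out)}}


def stage_bootstrap(cfg: PipelineConfig) -> dict:
    ds = _load_dataset(cfg.outdir, "bootstrap")
    pairs = _load_pairs(cfg.outdir, "bootstrap")
    model = PackStockModel(
        ds, pairs=pairs, breaks=cfg.breaks, b_reps=cfg.b_reps, seed=cfg.seed
    )
    results = model.fit()
    df = results.estimates_frame()
    out = cfg.outdir / "boot_estimates.csv"
    df.to_csv(out, index=False)
    return {"n_cells": len(df), "outputs": {"boot_estimates": str(out)}}


def stage_cart(cfg: PipelineConfig) -> dict:
    ds = _load_dataset(cfg.outdir, "cart")
    pairs = _load_pairs(cfg.outdir, "cart")
    (est_path,) = _require(cfg.outdir, ["boot_estimates.csv"], "cart")
    est_df = pd.read_csv(est_path)
    from .bootstrap import PairedDifferenceEstimate

    estimates = [
        PairedDifferenceEstimate(
            pair_id=row["pair_id"], stratum=row["stratum"],
            response=row["response"], estimate=float(row["estimate"]),
            ci_low=float(row["ci_low"]), ci_high=float(row["ci_high"]),
            n_stock=int(row["n_stock"]), n_control=int(row["n_control"]),
            b_reps=cfg.b_reps, seed=int(row["seed"]),
        )
        for _, row in est_df.iterrows()
    ]
    explanatory = pair_explanatory_table(
        pairs, ds.meadows, ds.stock_use, ds.registry
    )
    models = run_all_models(
        estimates, explanatory,
        min_split=cfg.min_split, min_leaf=cfg.min_leaf,
        prune_frac=cfg.prune_frac,
    )
    df = contributions_frame(models)
    out = cfg.outdir / "cart_contributions.csv"
    df.to_csv(out, index=False)
    summaries = {
        f"{response}|{stratum}": (
            res if isinstance(res, str) else
            {"r2": res.r2, "n_pairs": res.n, "by_category": res.by_category,
             "by_covariate": {k: v for k, v in res.by_covariate.items() if v}}
        )
        for (response, stratum), res in models.items()
    }
    (cfg.outdir / "cart_models.json").write_text(
        json.dumps(summaries, indent=2, sort_keys=True) + "\n"
    )
    return {
        "n_models": len(models),
        "outputs": {"cart_contributions": str(out)},
    }


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "match": stage_match,
    "stratify": stage_stratify,
    "responses": stage_responses,
    "bootstrap": stage_bootstrap,
    "cart": stage_cart,
}


def run(cfg: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Run the requested stages in order; returns the artifact manifest."""
    stages = list(STAGES) if not stages or stages == ["all"] else stages
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}}
    for stage in STAGES:
        if stage not in stages:
            continue
        logger.info("stage %s (seed=%d)", stage, cfg.seed)
        try:
            info = _STAGE_FUNCS[stage](cfg)
        except Exception:
            (cfg.outdir / f"{stage}.failed").touch()
            raise
        entry = {"stage": stage, "seed": cfg.seed, **info}
        if "outputs" in info:
            entry["output_sha256"] = {
                k: _sha256(Path(v)) for k, v in info["outputs"].items()
            }
        _append_manifest(cfg.outdir, entry)
        manifest["stages"][stage] = entry
        failed = cfg.outdir / f"{stage}.failed"
        if failed.exists():
            failed.unlink()
    return manifest
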
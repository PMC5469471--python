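"""Synthetic meadow landscapes with Gaussian-niche plant communities.

The generator emulates the statistical structure the analysis pipeline
assumes: a large candidate pool of meadows with correlated remotely sensed
covariates, annual pack-stock-night series for a subset of meadows, field
sampling on belt transects (plots every 20 m on transects 40 m apart, with
species composition recorded on eight 25x25 cm subplots at every third
plot), a within-meadow soil-moisture gradient, and species whose cover
follows unimodal Gaussian niche curves along that gradient.

Two disturbance effects can be injected into stock meadows only, so that
downstream estimators can be checked for parameter recovery:

* an additive bare-ground increase in dry-stratum plots of heavily used
  meadows (above a stock-density threshold), and
* a multiplicative inflation of subplot-level compositional noise in
  wet-stratum plots, scaled by the inter-annual standard deviation of
  stock nights.

With both effects zeroed the generator is an exact null model: stock and
control meadows are exchangeable draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    Dataset,
    MeadowRecord,
    PlotSample,
    StockUseSeries,
    SubplotCover,
    compute_stock_metrics,
)
from .registry import CovariateRegistry, default_registry

__all__ = [
    "SpeciesNiche",
    "EffectConfig",
    "default_niches",
    "default_covariance",
    "generate_landscape",
    "generate_meadow_plots",
    "generate_dataset",
]

# Printed bounds used as generator defaults: max annual stock nights across
# the sampled landscape span 10-577; meadow areas span 0.42-22.14 ha.
DEFAULT_MAX_NIGHTS_RANGE = (10.0, 577.0)
DEFAULT_AREA_RANGE = (0.4, 25.0)
# Reference scale for the wet-dispersion effect: the largest inter-annual
# stock-night standard deviation on the sampled landscape (~135 nights).
SD_NIGHTS_SCALE = 135.0


@dataclass(frozen=True)
class SpeciesNiche:
    """Gaussian niche curve for one species along the moisture axis.

    Moisture is expressed in meadow-standardized units (s.d. from the
    meadow mean, roughly -3..3).  Expected cover at moisture ``z`` is
    ``peak_cover * exp(-(z - moisture_optimum)^2 / (2 * niche_width^2))``,
    thinned by a per-plot presence probability.
    """

    species_name: str
    moisture_optimum: float
    niche_width: float
    peak_cover: float
    presence_prob: float = 1.0

    def __post_init__(self) -> None:
        if not self.niche_width > 0:
            raise ValueError("niche_width must be positive")
        if not 0 < self.peak_cover <= 100:
            raise ValueError("peak_cover must be in (0, 100]")
        if not 0 <= self.presence_prob <= 1:
            raise ValueError("presence_prob must be in [0, 1]")

    def mean_cover(self, z: float | np.ndarray) -> float | np.ndarray:
        return self.peak_cover * np.exp(
            -((np.asarray(z) - self.moisture_optimum) ** 2)
            / (2.0 * self.niche_width**2)
        )


@dataclass(frozen=True)
class EffectConfig:
    """Injectable stock effects; all-zero settings reproduce the null model.

    ``bare_dry_effect`` is the bare-ground percentage added to dry-stratum
    plots (latent moisture below ``dry_break``) of stock meadows whose
    maximum stock density exceeds ``use_threshold`` (max nights/ha).
    ``wet_dispersion_factor`` inflates the log-scale subplot noise s.d. in
    wet-stratum plots by ``1 + factor * sd_nights / 135``.
    """

    bare_dry_effect: float = 0.0
    use_threshold: float = 0.0
    wet_dispersion_factor: float = 0.0
    dry_break: float = -0.5
    wet_break: float = 0.5


def default_niches(n_dominant: int = 10, n_minor: int = 20) -> list[SpeciesNiche]:
    """Deterministic default species pool: 10 dominants + 20 minor species.

    Dominant optima are spread across the moisture axis so that dominance
    turns over from xeric to hydric species; minor species are broader and
    sparser, and bring per-plot richness to roughly 10-12 species.
    """
    niches: list[SpeciesNiche] = []
    for i in range(n_dominant):
        opt = -2.4 + 4.8 * i / max(n_dominant - 1, 1)
        niches.append(
            SpeciesNiche(
                species_name=f"dom_{i + 1:02d}",
                moisture_optimum=opt,
                niche_width=0.9,
                peak_cover=18.0 + 12.0 * ((i * 7) % 3) / 2.0,
                presence_prob=0.95,
            )
        )
    for i in range(n_minor):
        opt = -2.7 + 5.4 * i / max(n_minor - 1, 1)
        niches.append(
            SpeciesNiche(
                species_name=f"min_{i + 1:02d}",
                moisture_optimum=opt,
                niche_width=1.4,
                peak_cover=4.0 + ((i * 5) % 4),
                presence_prob=0.75,
            )
        )
    return niches


def default_covariance(registry: CovariateRegistry | None = None) -> np.ndarray:
    """Block-structured covariate correlation: related indices correlate.

    Covariates within the same registry category share a moderate positive
    correlation (0.5), mimicking the redundancy among precipitation,
    snowmelt and greenness indices that motivates generalized (correlation
    -aware) Mahalanobis matching.
    """
    registry = registry or default_registry()
    cats = [e.category for e in registry.entries]
    p = len(cats)
    cov = np.eye(p)
    for i in range(p):
        for j in range(p):
            if i != j and cats[i] == cats[j]:
                cov[i, j] = 0.5
    return cov


def _check_psd(cov: np.ndarray) -> None:
    w = np.linalg.eigvalsh((cov + cov.T) / 2.0)
    if w.min() < -1e-8:
        raise ValueError("covariance_spec is not positive semidefinite")


def generate_landscape(
    n_meadows: int = 1000,
    n_stock: int = 22,
    park_split: float = 0.5,
    covariance_spec: np.ndarray | None = None,
    max_nights_range: tuple[float, float] = DEFAULT_MAX_NIGHTS_RANGE,
    area_range: tuple[float, float] = DEFAULT_AREA_RANGE,
    registry: CovariateRegistry | None = None,
    seed: int = 0,
) -> tuple[dict[str, MeadowRecord], dict[str, StockUseSeries]]:
    """Draw a candidate meadow pool plus stock-use series.

    Covariates are multivariate Gaussian (with ``covariance_spec``
    correlation) then converted to within-park ranks for registry entries
    flagged as ranked.  ``n_stock`` meadows (split across parks) receive
    annual stock-night series whose single-year maxima are log-uniform
    over ``max_nights_range``.  Areas are log-uniform over ``area_range``.
    """
    if n_meadows < 4:
        raise ValueError("n_meadows must be at least 4")
    registry = registry or default_registry()
    cov = default_covariance(registry) if covariance_spec is None else covariance_spec
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (len(registry), len(registry)):
        raise ValueError(
            f"covariance_spec must be {len(registry)}x{len(registry)}"
        )
    _check_psd(cov)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_yose = int(round(n_meadows * park_split))
    parks = np.array(["YOSE"] * n_yose + ["SEKI"] * (n_meadows - n_yose))

    raw = rng.multivariate_normal(
        np.zeros(len(registry)), cov, size=n_meadows, method="svd"
    )
    lo, hi = area_range
    areas = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_meadows))
    xs = rng.uniform(250_000, 350_000, size=n_meadows)
    ys = rng.uniform(4_050_000, 4_200_000, size=n_meadows)

    # stock meadows: split across parks, chosen at random from each pool
    stock_ids = np.zeros(n_meadows, dtype=bool)
    for park in ("YOSE", "SEKI"):
        idx = np.flatnonzero(parks == park)
        k = min(
            n_stock // 2 + (n_stock % 2 if park == "YOSE" else 0), len(idx)
        )
        chosen = rng.choice(idx, size=k, replace=False)
        stock_ids[chosen] = True

    cov_values = raw.copy()
    for j, entry in enumerate(registry.entries):
        if entry.ranked:
            for park in ("YOSE", "SEKI"):
                mask = parks == park
                ranks = pd.Series(raw[mask, j]).rank(method="first").to_numpy()
                cov_values[mask, j] = ranks
    area_col = registry.names.index("meadow_area")
    cov_values[:, area_col] = areas

    meadows: dict[str, MeadowRecord] = {}
    stock_use: dict[str, StockUseSeries] = {}
    for i in range(n_meadows):
        mid = f"M{i + 1:04d}"
        covariates = dict(zip(registry.names, cov_values[i]))
        if parks[i] == "SEKI":
            covariates.pop("travel_time_trailhead", None)
        meadows[mid] = MeadowRecord(
            meadow_id=mid,
            park=str(parks[i]),
            area_ha=float(areas[i]),
            centroid_x=float(xs[i]),
            centroid_y=float(ys[i]),
            covariates=covariates,
            role="stock" if stock_ids[i] else "nonstock",
        )
        if stock_ids[i]:
            peak = np.exp(
                rng.uniform(np.log(max_nights_range[0]), np.log(max_nights_range[1]))
            )
            frac = rng.uniform(0.1, 1.0, size=6)
            frac[rng.uniform(size=6) < 0.2] = 0.0  # unvisited years
            frac[int(rng.integers(6))] = 1.0  # the max year hits the peak
            nights = np.rint(frac * peak)
            stock_use[mid] = StockUseSeries(
                meadow_id=mid,
                nights_by_year={
                    2004 + k: float(nights[k]) for k in range(6)
                },
            )
    return meadows, stock_use


def generate_meadow_plots(
    meadow: MeadowRecord,
    niches: list[SpeciesNiche],
    effect_config: EffectConfig | None = None,
    stock_series: StockUseSeries | None = None,
    n_transects: int = 6,
    plots_per_transect: int = 8,
    vwc_center: float = 18.0,
    vwc_scale: float = 8.0,
    moisture_gradient: float = 1.8,
    moisture_noise: float = 0.6,
    subplot_noise_sd: float = 0.6,
    vwc_covariate_gain: float = 3.0,
    veg_covariate_gain: float = 10.0,
    comp_covariate_gain: float = 0.8,
    heterogeneity_gain: float = 0.4,
    seed: int = 0,
) -> tuple[list[PlotSample], list[SubplotCover]]:
    """Sample one meadow: plots on the transect grid plus subplot covers.

    A latent moisture score ``z`` runs linearly along each transect (the
    cross-meadow drainage gradient) with Gaussian noise, and is mapped to
    VWC via ``vwc_center + vwc_scale * z`` (clamped at zero).  Species
    cover per subplot is the Gaussian-niche mean at ``z`` with lognormal
    multiplicative noise; vegetation, litter, and bare ground covers are
    derived from the same latent moisture.  Every third plot carries
    species data.  Effects are injected only when ``meadow.role`` is
    ``stock`` and ``stock_series`` is given.

    Landscape covariates genuinely drive meadow vegetation — the premise
    that makes covariate matching informative: elevation shifts the
    meadow's moisture regime and baseline vegetation cover
    (``vwc_covariate_gain``, ``veg_covariate_gain``), the lake-distance
    covariate shifts the whole community along the moisture-niche axis
    (``comp_covariate_gain``), and the cumulative-elevation-change
    covariate scales local compositional heterogeneity
    (``heterogeneity_gain``).  All three drivers sit in the 14-covariate
    CART subset, so the attribution stage can in principle recover them.
    Stock and control meadows with identical covariates are exchangeable
    draws whenever the injected effects are zero.
    """
    if not niches:
        raise ValueError("niches must be non-empty")
    eff = effect_config or EffectConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    # landscape drivers (raw MVN covariates are ~N(0,1) and correlated
    # with the rest of their registry category)
    elev = float(meadow.covariates.get("elevation", 0.0))
    comp_shift = comp_covariate_gain * float(
        meadow.covariates.get("dist_nearest_lake", 0.0)
    )
    meadow_noise_sd = subplot_noise_sd * float(
        np.exp(
            heterogeneity_gain
            * float(meadow.covariates.get("nearest_meadow_cum_elev_change", 0.0))
        )
    )
    vwc_center = vwc_center + vwc_covariate_gain * elev
    veg_base = 55.0 + veg_covariate_gain * elev

    # effect scaling from the meadow's own use record
    bare_add = 0.0
    wet_noise_factor = 1.0
    if meadow.role == "stock" and stock_series is not None:
        metrics = compute_stock_metrics(stock_series, meadow.area_ha)
        if metrics.max_nights_per_ha > eff.use_threshold:
            bare_add = eff.bare_dry_effect
        wet_noise_factor = 1.0 + eff.wet_dispersion_factor * (
            metrics.sd_nights / SD_NIGHTS_SCALE
        )

    plots: list[PlotSample] = []
    subplots: list[SubplotCover] = []
    plot_ordinal = 0
    for t in range(n_transects):
        for k in range(plots_per_transect):
            # linear moisture gradient along the transect, plus local noise
            frac = k / max(plots_per_transect - 1, 1)
            z = moisture_gradient * (2.0 * frac - 1.0) + rng.normal(
                0.0, moisture_noise
            )
            vwc = max(vwc_center + vwc_scale * z, 0.0)

            veg = float(np.clip(veg_base + 9.0 * z + rng.normal(0.0, 8.0), 0.0, 97.0))
            litter = float(np.clip(rng.normal(20.0, 5.0), 0.0, 100.0 - veg))
            bare = float(
                np.clip(100.0 - veg - litter + rng.normal(0.0, 3.0), 0.0, 100.0)
            )
            if bare_add and z < eff.dry_break:
                shift = min(bare_add, 100.0 - bare)
                bare += shift
                veg = max(veg - shift, 0.0)

            has_species = plot_ordinal % 3 == 0
            plots.append(
                PlotSample(
                    meadow_id=meadow.meadow_id,
                    transect_index=t + 1,
                    plot_index=plot_ordinal + 1,
                    vwc_mean=vwc,
                    bare_ground_pct=bare,
                    litter_pct=litter,
                    total_veg_pct=veg,
                    has_species_data=has_species,
                )
            )
            if has_species:
                noise_sd = meadow_noise_sd
                if z >= eff.wet_break:
                    noise_sd = meadow_noise_sd * wet_noise_factor
                present = rng.uniform(size=len(niches)) < np.array(
                    [n.presence_prob for n in niches]
                )
                log_noise = rng.normal(0.0, 1.0, size=(8, len(niches)))
                z_comp = z - comp_shift  # landscape shift of the community
                for s in range(8):
                    cover: dict[str, float] = {}
                    for j, niche in enumerate(niches):
                        if not present[j]:
                            continue
                        mean = niche.mean_cover(z_comp)
                        val = mean * np.exp(
                            noise_sd * log_noise[s, j] - 0.5 * noise_sd**2
                        )
                        val = float(min(val, 100.0))
                        if val >= 0.05:  # ocular estimates have a floor
                            cover[niche.species_name] = val
                    subplots.append(
                        SubplotCover(
                            meadow_id=meadow.meadow_id,
                            plot_index=plot_ordinal + 1,
                            subplot_index=s + 1,
                            cover=cover,
                        )
                    )
            plot_ordinal += 1
    return plots, subplots


def generate_dataset(
    meadow_ids: list[str],
    meadows: dict[str, MeadowRecord],
    stock_use: dict[str, StockUseSeries],
    niches: list[SpeciesNiche] | None = None,
    effect_config: EffectConfig | None = None,
    registry: CovariateRegistry | None = None,
    seed: int = 0,
    **plot_kwargs,
) -> Dataset:
    """Field-sample the listed meadows into a full analysis dataset.

    Each meadow gets an independent random substream derived from the
    master seed, so adding a meadow never perturbs another's draws.
    """
    niches = niches if niches is not None else default_niches()
    registry = registry or default_registry()
    all_plots: list[PlotSample] = []
    all_subplots: list[SubplotCover] = []
    for i, mid in enumerate(sorted(meadow_ids)):
        child = np.random.SeedSequence(entropy=seed, spawn_key=(i,))
        plots, subs = generate_meadow_plots(
            meadows[mid],
            niches,
            effect_config=effect_config,
            stock_series=stock_use.get(mid),
            seed=child.generate_state(1)[0],
            **plot_kwargs,
        )
        all_plots.extend(plots)
        all_subplots.extend(subs)
    return Dataset(
        meadows={mid: meadows[mid] for mid in meadow_ids},
        stock_use={m: s for m, s in stock_use.items() if m in set(meadow_ids)},
        plots=all_plots,
        subplots=all_subplots,
        registry=registry,
    )
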
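"""Domain types, validation, and CSV readers/writers shared by all stages.

The pipeline consumes four tidy CSV tables:

``meadows.csv``
    one row per meadow: identity, park, area (ha), projected centroid,
    stock/nonstock role, and one column per registry covariate.
``stock_use.csv``
    long table of annual stock nights (animal-nights) per meadow for the
    fixed 2004-2009 reporting window.
``plots.csv``
    one row per 4 m^2 plot: transect/plot indices, mean volumetric water
    content (% VWC, five readings averaged), ocular cover estimates for
    bare ground, litter and total vegetation, and a flag marking the
    every-third plots where species composition was recorded.
``species_cover.csv``
    long table of per-subplot species cover (eight 25x25 cm subplots per
    species plot); rows exist only for nonzero cover.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import CovariateRegistry, default_registry

logger = logging.getLogger(__name__)

STOCK_YEARS: tuple[int, ...] = tuple(range(2004, 2010))

__all__ = [
    "STOCK_YEARS",
    "MeadowRecord",
    "StockUseSeries",
    "StockUseMetrics",
    "PlotSample",
    "SubplotCover",
    "MeadowPair",
    "Dataset",
    "compute_stock_metrics",
    "read_tables",
    "write_tables",
]


class ValidationError(ValueError):
    """A table failed schema or referential-integrity checks."""


@dataclass
class MeadowRecord:
    """One meadow: identity, park, geometry, covariates and stock role."""

    meadow_id: str
    park: str  # YOSE | SEKI
    area_ha: float
    centroid_x: float
    centroid_y: float
    covariates: dict[str, float]
    role: str  # stock | nonstock

    def __post_init__(self) -> None:
        if self.park not in ("YOSE", "SEKI"):
            raise ValidationError(f"unknown park {self.park!r} for {self.meadow_id}")
        if not self.area_ha > 0:
            raise ValidationError(f"area_ha must be > 0 for {self.meadow_id}")
        if self.role not in ("stock", "nonstock"):
            raise ValidationError(f"role must be stock|nonstock for {self.meadow_id}")


@dataclass
class StockUseSeries:
    """Annual stock nights over the fixed 2004-2009 window.

    Years with no reported visit are stored as 0 so that the six-year
    mean and standard deviation are always well defined.
    """

    meadow_id: str
    nights_by_year: dict[int, float]

    def __post_init__(self) -> None:
        filled = {y: float(self.nights_by_year.get(y, 0.0)) for y in STOCK_YEARS}
        extra = set(self.nights_by_year) - set(STOCK_YEARS)
        if extra:
            raise ValidationError(
                f"stock-use years outside {STOCK_YEARS[0]}-{STOCK_YEARS[-1]} "
                f"for {self.meadow_id}: {sorted(extra)}"
            )
        if any(v < 0 for v in filled.values()):
            raise ValidationError(f"negative stock nights for {self.meadow_id}")
        self.nights_by_year = filled

    @property
    def nights(self) -> np.ndarray:
        return np.array([self.nights_by_year[y] for y in STOCK_YEARS], dtype=float)


@dataclass(frozen=True)
class StockUseMetrics:
    """The six pack-stock use intensity metrics derived from a series."""

    mean_nights: float
    max_nights: float
    sd_nights: float
    cv_nights: float
    mean_nights_per_ha: float
    max_nights_per_ha: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_nights": self.mean_nights,
            "max_nights": self.max_nights,
            "sd_nights": self.sd_nights,
            "cv_nights": self.cv_nights,
            "mean_nights_per_ha": self.mean_nights_per_ha,
            "max_nights_per_ha": self.max_nights_per_ha,
        }


STOCK_METRIC_NAMES = [
    "mean_nights",
    "max_nights",
    "sd_nights",
    "cv_nights",
    "mean_nights_per_ha",
    "max_nights_per_ha",
]


@dataclass
class PlotSample:
    """One 4 m^2 plot: soil moisture and ocular cover estimates."""

    meadow_id: str
    transect_index: int
    plot_index: int
    vwc_mean: float
    bare_ground_pct: float
    litter_pct: float
    total_veg_pct: float
    has_species_data: bool

    def __post_init__(self) -> None:
        for name in ("bare_ground_pct", "litter_pct", "total_veg_pct"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValidationError(
                    f"{name}={v} outside [0,100] for plot "
                    f"({self.meadow_id}, {self.plot_index})"
                )
        if self.vwc_mean < 0:
            raise ValidationError(
                f"negative VWC for plot ({self.meadow_id}, {self.plot_index})"
            )


@dataclass
class SubplotCover:
    """Species cover (%) in one 25x25 cm subplot of a species plot."""

    meadow_id: str
    plot_index: int
    subplot_index: int
    cover: dict[str, float]

    def __post_init__(self) -> None:
        if not 1 <= self.subplot_index <= 8:
            raise ValidationError(
                f"subplot_index {self.subplot_index} outside 1..8 "
                f"({self.meadow_id}, plot {self.plot_index})"
            )
        for sp, v in self.cover.items():
            if v < 0 or v > 100:
                raise ValidationError(
                    f"cover {v} outside [0,100] for species {sp!r} "
                    f"({self.meadow_id}, plot {self.plot_index})"
                )


@dataclass
class MeadowPair:
    """A stock meadow and its matched non-stock control."""

    pair_id: str
    stock_meadow_id: str
    control_meadow_id: str
    match_rank: int
    mahalanobis_distance: float
    override: bool = False

    def __post_init__(self) -> None:
        if self.stock_meadow_id == self.control_meadow_id:
            raise ValidationError(f"pair {self.pair_id} matches a meadow to itself")
        if self.mahalanobis_distance < 0:
            raise ValidationError(f"negative distance in pair {self.pair_id}")


@dataclass
class Dataset:
    """Validated bundle of the four tables plus the covariate registry."""

    meadows: dict[str, MeadowRecord]
    stock_use: dict[str, StockUseSeries]
    plots: list[PlotSample]
    subplots: list[SubplotCover]
    registry: CovariateRegistry = field(default_factory=default_registry)

    @property
    def species_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for sc in self.subplots:
            for sp in sc.cover:
                seen.setdefault(sp, None)
        return sorted(seen)

    def plots_for(self, meadow_id: str) -> list[PlotSample]:
        return [p for p in self.plots if p.meadow_id == meadow_id]

    def subplots_for(self, meadow_id: str, plot_index: int) -> list[SubplotCover]:
        return [
            s
            for s in self.subplots
            if s.meadow_id == meadow_id and s.plot_index == plot_index
        ]


def compute_stock_metrics(series: StockUseSeries, area_ha: float) -> StockUseMetrics:
    """Derive the six use-intensity metrics from an annual series.

    The standard deviation is the sample (n-1) standard deviation over the
    six annual values; the coefficient of variation is sd/mean and is NaN
    when the mean is zero (a never-used meadow).  Density metrics divide
    by meadow area in hectares.
    """
    if not area_ha > 0:
        raise ValueError(f"area_ha must be positive, got {area_ha}")
    nights = series.nights
    mean = float(nights.mean())
    mx = float(nights.max())
    sd = float(nights.std(ddof=1))
    cv = sd / mean if mean > 0 else math.nan
    return StockUseMetrics(
        mean_nights=mean,
        max_nights=mx,
        sd_nights=sd,
        cv_nights=cv,
        mean_nights_per_ha=mean / area_ha,
        max_nights_per_ha=mx / area_ha,
    )


# ---------------------------------------------------------------------------
# CSV plumbing
# ---------------------------------------------------------------------------

_MEADOW_FIXED_COLS = ["meadow_id", "park", "area_ha", "x", "y", "role"]


def _require_columns(df: pd.DataFrame, cols: list[str], path: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def read_tables(
    meadows_path: str | Path,
    stock_use_path: str | Path,
    plots_path: str | Path,
    subplots_path: str | Path,
    registry: CovariateRegistry | None = None,
) -> Dataset:
    """Read and cross-validate the four pipeline tables.

    Raises :class:`ValidationError` on unknown covariate columns, cover
    values outside [0,100], or dangling cross-references (a plot whose
    meadow does not exist, a subplot whose plot does not exist).
    """
    registry = registry or default_registry()
    for p in (meadows_path, stock_use_path, plots_path, subplots_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input table not found: {p}")

    mdf = pd.read_csv(meadows_path, dtype={"meadow_id": str})
    _require_columns(mdf, _MEADOW_FIXED_COLS, str(meadows_path))
    cov_cols = [c for c in mdf.columns if c not in _MEADOW_FIXED_COLS]
    unknown = [c for c in cov_cols if c not in registry]
    if unknown:
        raise ValidationError(f"{meadows_path}: unknown covariates {unknown}")

    meadows: dict[str, MeadowRecord] = {}
    for _, row in mdf.iterrows():
        rec = MeadowRecord(
            meadow_id=row["meadow_id"],
            park=row["park"],
            area_ha=float(row["area_ha"]),
            centroid_x=float(row["x"]),
            centroid_y=float(row["y"]),
            covariates={c: float(row[c]) for c in cov_cols if pd.notna(row[c])},
            role=row["role"],
        )
        if rec.meadow_id in meadows:
            raise ValidationError(f"duplicate meadow_id {rec.meadow_id!r}")
        meadows[rec.meadow_id] = rec

    sdf = pd.read_csv(stock_use_path, dtype={"meadow_id": str})
    _require_columns(sdf, ["meadow_id", "year", "stock_nights"], str(stock_use_path))
    stock_use: dict[str, StockUseSeries] = {}
    for mid, grp in sdf.groupby("meadow_id"):
        if mid not in meadows:
            raise ValidationError(f"{stock_use_path}: unknown meadow_id {mid!r}")
        stock_use[str(mid)] = StockUseSeries(
            meadow_id=str(mid),
            nights_by_year=dict(
                zip(grp["year"].astype(int), grp["stock_nights"].astype(float))
            ),
        )

    pdf = pd.read_csv(plots_path, dtype={"meadow_id": str})
    _require_columns(
        pdf,
        ["meadow_id", "transect", "plot", "vwc_mean", "bare_pct", "litter_pct",
         "veg_pct", "has_species"],
        str(plots_path),
    )
    plots: list[PlotSample] = []
    plot_keys: set[tuple[str, int]] = set()
    for i, row in pdf.iterrows():
        if row["meadow_id"] not in meadows:
            raise ValidationError(
                f"{plots_path} row {i}: plot references absent meadow "
                f"{row['meadow_id']!r}"
            )
        try:
            p = PlotSample(
                meadow_id=row["meadow_id"],
                transect_index=int(row["transect"]),
                plot_index=int(row["plot"]),
                vwc_mean=float(row["vwc_mean"]),
                bare_ground_pct=float(row["bare_pct"]),
                litter_pct=float(row["litter_pct"]),
                total_veg_pct=float(row["veg_pct"]),
                has_species_data=bool(row["has_species"]),
            )
        except ValidationError as exc:
            raise ValidationError(f"{plots_path} row {i}: {exc}") from exc
        plots.append(p)
        plot_keys.add((p.meadow_id, p.plot_index))

    cdf = pd.read_csv(subplots_path, dtype={"meadow_id": str, "species": str})
    _require_columns(
        cdf, ["meadow_id", "plot", "subplot", "species", "cover_pct"],
        str(subplots_path),
    )
    subplots: list[SubplotCover] = []
    if len(cdf) == 0:
        warnings.warn("species_cover table is empty: no species plots available")
    else:
        for (mid, plot, sub), grp in cdf.groupby(["meadow_id", "plot", "subplot"]):
            if (str(mid), int(plot)) not in plot_keys:
                raise ValidationError(
                    f"{subplots_path}: subplot references absent plot "
                    f"({mid!r}, {int(plot)})"
                )
            subplots.append(
                SubplotCover(
                    meadow_id=str(mid),
                    plot_index=int(plot),
                    subplot_index=int(sub),
                    cover=dict(
                        zip(grp["species"], grp["cover_pct"].astype(float))
                    ),
                )
            )

    logger.info(
        "read %d meadows, %d stock-use series, %d plots, %d subplot records",
        len(meadows), len(stock_use), len(plots), len(subplots),
    )
    return Dataset(
        meadows=meadows, stock_use=stock_use, plots=plots, subplots=subplots,
        registry=registry,
    )


def read_locations(path: str | Path) -> pd.DataFrame:
    """Read a study-locations table (X, Y, Site, SampleYear, matchGroup,
    Stock) as an optional meadow coordinate / pairing source.

    ``Site`` is matched against meadow_id; ``Stock`` is 1 for pack-stock
    meadows, 0 for controls; ``matchGroup`` groups the two meadows of a
    pair.  Returns the parsed frame; callers decide how to apply it.
    """
    df = pd.read_csv(path)
    required = ["X", "Y", "Site", "SampleYear", "matchGroup", "Stock"]
    _require_columns(df, required, str(path))
    return df


def apply_locations(dataset: Dataset, locations: pd.DataFrame) -> int:
    """Override meadow centroids from a locations table; returns the
    number of meadows updated (unknown sites are ignored)."""
    n = 0
    for _, row in locations.iterrows():
        m = dataset.meadows.get(str(row["Site"]))
        if m is not None:
            m.centroid_x = float(row["X"])
            m.centroid_y = float(row["Y"])
            n += 1
    return n


def write_tables(dataset: Dataset, outdir: str | Path) -> dict[str, Path]:
    """Write the four tables to ``outdir``; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cov_names = dataset.registry.names

    mrows = []
    for m in dataset.meadows.values():
        row: dict[str, object] = {
            "meadow_id": m.meadow_id, "park": m.park, "area_ha": m.area_ha,
            "x": m.centroid_x, "y": m.centroid_y, "role": m.role,
        }
        for c in cov_names:
            row[c] = m.covariates.get(c, np.nan)
        mrows.append(row)
    meadows_path = outdir / "meadows.csv"
    pd.DataFrame(mrows).to_csv(meadows_path, index=False)

    srows = [
        {"meadow_id": s.meadow_id, "year": y, "stock_nights": s.nights_by_year[y]}
        for s in dataset.stock_use.values()
        for y in STOCK_YEARS
    ]
    stock_path = outdir / "stock_use.csv"
    pd.DataFrame(srows, columns=["meadow_id", "year", "stock_nights"]).to_csv(
        stock_path, index=False
    )

    prows = [
        {
            "meadow_id": p.meadow_id, "transect": p.transect_index,
            "plot": p.plot_index, "vwc_mean": p.vwc_mean,
            "bare_pct": p.bare_ground_pct, "litter_pct": p.litter_pct,
            "veg_pct": p.total_veg_pct, "has_species": int(p.has_species_data),
        }
        for p in dataset.plots
    ]
    plots_path = outdir / "plots.csv"
    pd.DataFrame(
        prows,
        columns=["meadow_id", "transect", "plot", "vwc_mean", "bare_pct",
                 "litter_pct", "veg_pct", "has_species"],
    ).to_csv(plots_path, index=False)

    crows = [
        {
            "meadow_id": s.meadow_id, "plot": s.plot_index,
            "subplot": s.subplot_index, "species": sp, "cover_pct": v,
        }
        for s in dataset.subplots
        for sp, v in sorted(s.cover.items())
        if v > 0
    ]
    subplots_path = outdir / "species_cover.csv"
    pd.DataFrame(
        crows, columns=["meadow_id", "plot", "subplot", "species", "cover_pct"]
    ).to_csv(subplots_path, index=False)

    return {
        "meadows": meadows_path,
        "stock_use": stock_path,
        "plots": plots_path,
        "subplots": subplots_path,
    }
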
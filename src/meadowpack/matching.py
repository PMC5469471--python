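"""Stock-meadow eligibility filtering and Mahalanobis control matching.

Candidate stock meadows are those with at least 10 reported stock nights
in at least one year of the 2004-2009 window and area below 25 ha; the
top-k per park by maximum annual stock nights are retained (k = 20 by
default).  Each retained stock meadow is then paired with a non-stock
control from the same park by generalized Mahalanobis distance over the
covariate registry, computed with the pooled within-park covariance so
that correlated indices are not double counted.  Controls are assigned
greedily without replacement in descending stock-use order, and the top
three candidates are recorded so a manual override can replace the
default rank-1 selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MeadowPair, MeadowRecord, StockUseSeries
from .registry import CovariateRegistry, default_registry

logger = logging.getLogger(__name__)

__all__ = [
    "MatchCandidateList",
    "filter_eligible_stock",
    "mahalanobis_distance",
    "match_meadows",
    "pairs_to_frame",
]


@dataclass
class MatchCandidateList:
    """Ranked control candidates for one stock meadow."""

    stock_meadow_id: str
    candidates: list[tuple[str, float]]  # (control_id, distance), ascending
    selected: str
    override: bool = False

    @property
    def selected_rank(self) -> int:
        for r, (cid, _) in enumerate(self.candidates, start=1):
            if cid == self.selected:
                return r
        return 0  # override outside the candidate list

    @property
    def selected_distance(self) -> float:
        for cid, d in self.candidates:
            if cid == self.selected:
                return d
        return float("nan")


def filter_eligible_stock(
    meadows: dict[str, MeadowRecord],
    stock_use: dict[str, StockUseSeries],
    min_nights: float = 10.0,
    max_area_ha: float = 25.0,
    top_k_per_park: int = 20,
) -> list[str]:
    """Select candidate stock meadows under the use and size rules.

    A meadow qualifies with >= ``min_nights`` stock nights in at least one
    reporting year and area strictly below ``max_area_ha``; per park, only
    the ``top_k_per_park`` meadows with the largest single-year maximum
    are kept.
    """
    eligible: list[tuple[str, str, float]] = []
    for mid, series in stock_use.items():
        m = meadows.get(mid)
        if m is None:
            continue
        mx = float(series.nights.max())
        if mx >= min_nights and m.area_ha < max_area_ha:
            eligible.append((mid, m.park, mx))
    if not eligible:
        logger.warning("no eligible stock meadows after filtering")
        return []
    out: list[str] = []
    for park in ("YOSE", "SEKI"):
        in_park = [e for e in eligible if e[1] == park]
        in_park.sort(key=lambda e: (-e[2], e[0]))
        out.extend(mid for mid, _, _ in in_park[:top_k_per_park])
    return out


def mahalanobis_distance(
    x: np.ndarray, y: np.ndarray, s_inv: np.ndarray
) -> float:
    """Generalized Mahalanobis distance sqrt((x-y)' S^-1 (x-y))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    s_inv = np.asarray(s_inv, dtype=float)
    if x.shape != y.shape or s_inv.shape != (x.size, x.size):
        raise ValueError(
            f"dimension mismatch: x {x.shape}, y {y.shape}, S_inv {s_inv.shape}"
        )
    d = x - y
    q = float(d @ s_inv @ d)
    return float(np.sqrt(max(q, 0.0)))


def _covariate_matrix(
    records: list[MeadowRecord], names: list[str]
) -> np.ndarray:
    return np.array(
        [[m.covariates.get(c, np.nan) for c in names] for m in records]
    )


def match_meadows(
    stock_ids: list[str],
    meadows: dict[str, MeadowRecord],
    stock_use: dict[str, StockUseSeries],
    registry: CovariateRegistry | None = None,
    top_n: int = 3,
    overrides: dict[str, str] | None = None,
) -> list[MatchCandidateList]:
    """Pair each stock meadow with a same-park non-stock control.

    The covariance is estimated per park from the pooled covariate matrix
    of the stock meadows and the full non-stock candidate pool; a singular
    covariance falls back to the Moore-Penrose pseudo-inverse with a
    warning.  Stock meadows are processed in descending order of maximum
    stock nights, and each control can be used at most once.
    """
    registry = registry or default_registry()
    overrides = overrides or {}

    order = sorted(
        stock_ids,
        key=lambda mid: (-float(stock_use[mid].nights.max()), mid),
    )
    results: list[MatchCandidateList] = []
    taken: set[str] = set()

    for park in ("YOSE", "SEKI"):
        park_stock = [mid for mid in order if meadows[mid].park == park]
        if not park_stock:
            continue
        pool = [
            m
            for m in meadows.values()
            if m.park == park and m.role == "nonstock"
        ]
        if len(pool) < top_n:
            raise ValueError(
                f"{park}: only {len(pool)} non-stock candidates, need >= {top_n}"
            )
        names = registry.names_for_park(park)
        stock_recs = [meadows[mid] for mid in park_stock]
        pooled = _covariate_matrix(stock_recs + pool, names)
        if np.isnan(pooled).any():
            raise ValueError(f"{park}: missing covariate values in pooled matrix")
        cov = np.cov(pooled, rowvar=False)
        try:
            s_inv = np.linalg.inv(cov)
            # guard against numerically singular matrices that invert badly
            if not np.isfinite(s_inv).all():
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            logger.warning("%s: singular covariance, using pseudo-inverse", park)
            s_inv = np.linalg.pinv(cov)

        pool_mat = _covariate_matrix(pool, names)
        for mid in park_stock:
            x = np.array([meadows[mid].covariates[c] for c in names])
            dists = [
                (p.meadow_id, mahalanobis_distance(x, pool_mat[i], s_inv))
                for i, p in enumerate(pool)
                if p.meadow_id not in taken
            ]
            dists.sort(key=lambda t: (t[1], t[0]))
            candidates = dists[:top_n]
            if not candidates:
                raise ValueError(f"no remaining control candidates for {mid}")
            selected = overrides.get(mid, candidates[0][0])
            results.append(
                MatchCandidateList(
                    stock_meadow_id=mid,
                    candidates=candidates,
                    selected=selected,
                    override=mid in overrides,
                )
            )
            taken.add(selected)
    return results


def pairs_to_frame(matches: list[MatchCandidateList]) -> pd.DataFrame:
    """Tabulate selections as the pairs.csv layout."""
    rows = []
    for i, m in enumerate(matches, start=1):
        rows.append(
            {
                "pair_id": f"P{i:02d}",
                "stock_meadow_id": m.stock_meadow_id,
                "control_meadow_id": m.selected,
                "distance": m.selected_distance,
                "rank": m.selected_rank,
                "override_flag": int(m.override),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pair_id", "stock_meadow_id", "control_meadow_id",
            "distance", "rank", "override_flag",
        ],
    )


def matches_to_pairs(matches: list[MatchCandidateList]) -> list[MeadowPair]:
    return [
        MeadowPair(
            pair_id=f"P{i:02d}",
            stock_meadow_id=m.stock_meadow_id,
            control_meadow_id=m.selected,
            match_rank=m.selected_rank,
            mahalanobis_distance=m.selected_distance,
            override=m.override,
        )
        for i, m in enumerate(matches, start=1)
    ]
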
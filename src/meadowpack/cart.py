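"""Regression-tree attribution of paired differences to covariate classes.

For each response and vegetation community type, the unit of analysis is
a matched meadow pair; the response is the bootstrapped stock-minus-
control estimate and the explanatory variables fall into three classes:

* **Stock Use** — the six use-intensity metrics of the pair's stock
  meadow (mean/max annual nights, mean/max nights per hectare, and the
  s.d. and c.v. of annual nights over 2004-2009);
* **Within-pair** — stock-minus-control differences of the 14 CART
  covariates (a large effect here flags a weak pairing);
* **Between-pairs** — the pair means of the same 14 covariates (the
  pair's overall environmental context).

Trees are grown by greedy binary partitioning on the sum-of-squares
criterion with midpoint thresholds.  Two rules keep the small-n trees
honest: a split must reduce more than 10% of the TOTAL sum of squares,
and a node where two different covariates tie for the best split (within
a numerical tolerance) is not split at all.  With 12-22 rows this yields
trees of 0-3 splits whose per-covariate contributions — percent of total
sum of squares — sum exactly to 100 x R^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bootstrap import PairedDifferenceEstimate
from .io import (
    STOCK_METRIC_NAMES,
    MeadowPair,
    MeadowRecord,
    StockUseSeries,
    compute_stock_metrics,
)
from .registry import CovariateRegistry, default_registry
from .responses import RESPONSES
from .stratify import STRATA

logger = logging.getLogger(__name__)

__all__ = [
    "Split",
    "TreeModel",
    "ContributionTable",
    "pair_explanatory_table",
    "build_difference_table",
    "fit_cart",
    "contributions",
    "run_all_models",
    "CATEGORIES",
]

CATEGORIES = ("StockUse", "WithinPair", "BetweenPairs")
MODEL_STRATA = ("All",) + STRATA


@dataclass(frozen=True)
class Split:
    node_id: int
    covariate: str
    threshold: float
    ss_reduction: float


@dataclass
class TreeModel:
    """A fitted, pruned regression tree."""

    splits: list[Split]
    leaf_means: dict[int, float]
    total_ss: float
    n: int

    @property
    def r2(self) -> float:
        if self.total_ss <= 0:
            return 0.0
        return sum(s.ss_reduction for s in self.splits) / self.total_ss


@dataclass
class ContributionTable:
    """Percent of total sum of squares per covariate and per category."""

    by_covariate: dict[str, float]
    by_category: dict[str, float]
    r2: float
    n: int

    def top_covariate(self) -> tuple[str, float]:
        if not self.by_covariate:
            return ("", 0.0)
        name = max(self.by_covariate, key=lambda k: self.by_covariate[k])
        return (name, self.by_covariate[name])


def category_of(column: str, strict: bool = True) -> str | None:
    if column in STOCK_METRIC_NAMES:
        return "StockUse"
    if column.startswith("d_"):
        return "WithinPair"
    if column.startswith("m_"):
        return "BetweenPairs"
    if strict:
        raise ValueError(f"cannot categorize explanatory column {column!r}")
    return None


def pair_explanatory_table(
    pairs: list[MeadowPair],
    meadows: dict[str, MeadowRecord],
    stock_use: dict[str, StockUseSeries],
    registry: CovariateRegistry | None = None,
) -> pd.DataFrame:
    """Per-pair explanatory block: stock metrics, d_* diffs, m_* means."""
    registry = registry or default_registry()
    cart_names = registry.cart_names
    rows = []
    for pair in pairs:
        sm = meadows[pair.stock_meadow_id]
        cm = meadows[pair.control_meadow_id]
        metrics = compute_stock_metrics(stock_use[pair.stock_meadow_id], sm.area_ha)
        row: dict[str, float] = dict(metrics.as_dict())
        for c in cart_names:
            sv = sm.covariates.get(c, np.nan)
            cv = cm.covariates.get(c, np.nan)
            row[f"d_{c}"] = sv - cv
            row[f"m_{c}"] = (sv + cv) / 2.0
        rows.append(pd.Series(row, name=pair.pair_id))
    cols = (
        STOCK_METRIC_NAMES
        + [f"d_{c}" for c in cart_names]
        + [f"m_{c}" for c in cart_names]
    )
    return pd.DataFrame(rows)[cols]


def build_difference_table(
    response: pd.Series,
    explanatory: pd.DataFrame,
    corr_threshold: float = 0.80,
    const_tol: float = 1e-12,
) -> pd.DataFrame:
    """Assemble the modelling table for one (stratum, response) cell.

    Rows are retained pairs (index of ``response``).  Near-constant
    explanatory columns are dropped, then physical-covariate columns
    (the d_*/m_* blocks) pairwise correlated beyond |r| > ``corr_threshold``
    with an earlier (registry-ordered) surviving column are dropped
    greedily.  The six stock-use metrics are exempt from the correlation
    filter: they are reported as a fixed block even though mean/max and
    their per-hectare versions are strongly related.
    """
    df = explanatory.loc[response.index].copy()
    if len(df) < 4:
        raise ValueError(
            f"only {len(df)} pairs available; tree fitting needs >= 4"
        )
    keep: list[str] = []
    for col in df.columns:
        vals = df[col].to_numpy(dtype=float)
        if np.isnan(vals).any():
            logger.info("dropping %s: missing values", col)
            continue
        if np.std(vals) < const_tol:
            logger.info("dropping %s: near-constant", col)
            continue
        redundant = False
        if col not in STOCK_METRIC_NAMES:
            for prev in keep:
                if prev in STOCK_METRIC_NAMES:
                    continue
                r = np.corrcoef(vals, df[prev].to_numpy(dtype=float))[0, 1]
                if abs(r) > corr_threshold:
                    logger.info("dropping %s: |r|=%.2f with %s", col, abs(r), prev)
                    redundant = True
                    break
        if not redundant:
            keep.append(col)
    out = df[keep].copy()
    out.insert(0, "response", response)
    return out


def _node_ss(y: np.ndarray) -> float:
    return float(((y - y.mean()) ** 2).sum()) if y.size else 0.0


def _best_split_per_covariate(
    x: np.ndarray, y: np.ndarray, min_leaf: int
) -> tuple[float, float] | None:
    """Best (threshold, ss_reduction) for one covariate, or None."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    uniq = np.unique(xs)
    if uniq.size < 2:
        return None
    parent = _node_ss(ys)
    best: tuple[float, float] | None = None
    for t in (uniq[:-1] + uniq[1:]) / 2.0:
        left = ys[xs <= t]
        right = ys[xs > t]
        if left.size < min_leaf or right.size < min_leaf:
            continue
        red = parent - _node_ss(left) - _node_ss(right)
        if best is None or red > best[1]:
            best = (float(t), float(red))
    return best


def fit_cart(
    table: pd.DataFrame,
    min_split: int = 5,
    min_leaf: int = 2,
    prune_frac: float = 0.10,
    tie_tol: float = 1e-9,
) -> TreeModel:
    """Greedy SS-minimizing binary tree with growth-time pruning.

    Candidate thresholds are midpoints between consecutive sorted unique
    covariate values.  A node is split only when the best split clears
    ``prune_frac`` of the total (root) sum of squares AND no second
    covariate ties the best reduction within ``tie_tol`` while inducing a
    conflicting partition (tied covariates that group the rows
    identically are not ambiguous; the earlier column wins).  Entirely
    deterministic.
    """
    y = table["response"].to_numpy(dtype=float)
    covs = [c for c in table.columns if c != "response"]
    x_all = {c: table[c].to_numpy(dtype=float) for c in covs}
    total_ss = _node_ss(y)
    tree = TreeModel(splits=[], leaf_means={}, total_ss=total_ss, n=len(y))
    if total_ss <= 0 or len(y) < min_split:
        tree.leaf_means[0] = float(y.mean()) if y.size else 0.0
        return tree

    next_id = [0]

    def grow(idx: np.ndarray, node_id: int) -> None:
        yn = y[idx]
        if yn.size < min_split or _node_ss(yn) <= 0:
            tree.leaf_means[node_id] = float(yn.mean())
            return
        per_cov: list[tuple[str, float, float]] = []  # (cov, thr, red)
        for c in covs:
            res = _best_split_per_covariate(x_all[c][idx], yn, min_leaf)
            if res is not None:
                per_cov.append((c, res[0], res[1]))
        if not per_cov:
            tree.leaf_means[node_id] = float(yn.mean())
            return
        per_cov.sort(key=lambda t: (-t[2], covs.index(t[0])))
        best_cov, best_thr, best_red = per_cov[0]
        if best_red <= prune_frac * total_ss:
            tree.leaf_means[node_id] = float(yn.mean())
            return
        for other_cov, other_thr, other_red in per_cov[1:]:
            if best_red - other_red > tie_tol:
                break
            # a second covariate ties the best reduction; the split is
            # ambiguous (and suppressed) only if it disagrees about the
            # partition — strongly related covariates that induce the
            # identical left/right grouping resolve to the earlier column
            best_mask = x_all[best_cov][idx] <= best_thr
            other_mask = x_all[other_cov][idx] <= other_thr
            if not (
                np.array_equal(best_mask, other_mask)
                or np.array_equal(best_mask, ~other_mask)
            ):
                logger.info(
                    "node %d: tie between %s and %s with conflicting "
                    "partitions, split suppressed",
                    node_id, best_cov, other_cov,
                )
                tree.leaf_means[node_id] = float(yn.mean())
                return
        tree.splits.append(
            Split(
                node_id=node_id, covariate=best_cov,
                threshold=best_thr, ss_reduction=best_red,
            )
        )
        left = idx[x_all[best_cov][idx] <= best_thr]
        right = idx[x_all[best_cov][idx] > best_thr]
        next_id[0] += 1
        grow(left, next_id[0])
        next_id[0] += 1
        grow(right, next_id[0])

    grow(np.arange(len(y)), 0)
    return tree


def contributions(
    tree: TreeModel, columns: list[str] | None = None
) -> ContributionTable:
    """Percent of total SS per covariate, summed into the three classes."""
    by_cov: dict[str, float] = {}
    if tree.total_ss > 0:
        for s in tree.splits:
            by_cov[s.covariate] = (
                by_cov.get(s.covariate, 0.0)
                + 100.0 * s.ss_reduction / tree.total_ss
            )
    by_cat = {c: 0.0 for c in CATEGORIES}
    for cov, pct in by_cov.items():
        cat = category_of(cov, strict=False)
        if cat is not None:
            by_cat[cat] += pct
    if columns:
        for c in columns:
            by_cov.setdefault(c, 0.0)
    return ContributionTable(
        by_covariate=by_cov, by_category=by_cat, r2=tree.r2, n=tree.n
    )


def run_all_models(
    estimates: list[PairedDifferenceEstimate],
    explanatory: pd.DataFrame,
    min_pairs: int = 4,
    **cart_kwargs,
) -> dict[tuple[str, str], ContributionTable | str]:
    """Fit the 12 (response x stratum) attribution models.

    Returns a mapping keyed by (response, stratum); a cell with too few
    retained pairs maps to a string reason instead of a table.
    """
    est_df = pd.DataFrame(
        [
            {
                "pair_id": e.pair_id, "stratum": e.stratum,
                "response": e.response, "estimate": e.estimate,
            }
            for e in estimates
        ]
    )
    out: dict[tuple[str, str], ContributionTable | str] = {}
    for response in RESPONSES:
        for stratum in MODEL_STRATA:
            sel = est_df[
                (est_df["response"] == response) & (est_df["stratum"] == stratum)
            ]
            if len(sel) < min_pairs:
                out[(response, stratum)] = (
                    f"skipped: {len(sel)} pairs < {min_pairs}"
                )
                logger.info("model (%s, %s) skipped: n=%d", response, stratum,
                            len(sel))
                continue
            y = pd.Series(
                sel["estimate"].to_numpy(), index=sel["pair_id"], name="response"
            )
            table = build_difference_table(y, explanatory)
            tree = fit_cart(table, **cart_kwargs)
            out[(response, stratum)] = contributions(tree)
    return out


def contributions_frame(
    models: dict[tuple[str, str], ContributionTable | str],
) -> pd.DataFrame:
    """Long-format table of the fitted models' covariate contributions."""
    rows = []
    for (response, stratum), res in models.items():
        if isinstance(res, str):
            rows.append(
                {
                    "response": response, "stratum": stratum, "r2": np.nan,
                    "n_pairs": np.nan, "covariate": "", "category": "",
                    "contribution_pct": np.nan, "note": res,
                }
            )
            continue
        if not res.by_covariate:
            rows.append(
                {
                    "response": response, "stratum": stratum, "r2": res.r2,
                    "n_pairs": res.n, "covariate": "", "category": "",
                    "contribution_pct": 0.0, "note": "no splits",
                }
            )
        for cov, pct in sorted(
            res.by_covariate.items(), key=lambda kv: -kv[1]
        ):
            if pct == 0.0:
                continue
            rows.append(
                {
                    "response": response, "stratum": stratum, "r2": res.r2,
                    "n_pairs": res.n, "covariate": cov,
                    "category": category_of(cov), "contribution_pct": pct,
                    "note": "",
                }
            )
    return pd.DataFrame(
        rows,
        columns=["response", "stratum", "r2", "n_pairs", "covariate",
                 "category", "contribution_pct", "note"],
    )
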
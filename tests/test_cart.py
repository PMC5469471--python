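"""Deterministic CART: exhaustive-split oracles, pruning, contributions."""

import numpy as np
import pandas as pd
import pytest

from meadowpack.cart import (
    build_difference_table,
    category_of,
    contributions,
    fit_cart,
)
from meadowpack.io import STOCK_METRIC_NAMES


def _table(y, **covs):
    df = pd.DataFrame({"response": y})
    for k, v in covs.items():
        df[k] = v
    return df


def _exhaustive_root_split(table, min_leaf=2):
    """Oracle: enumerate every covariate x midpoint threshold."""
    y = table["response"].to_numpy(float)
    parent = ((y - y.mean()) ** 2).sum()
    best = None
    for c in [c for c in table.columns if c != "response"]:
        x = table[c].to_numpy(float)
        for t in np.unique(x)[:-1]:
            # midpoint between consecutive unique values
            uniq = np.unique(x)
            mids = (uniq[:-1] + uniq[1:]) / 2
            for m in mids:
                l, r = y[x <= m], y[x > m]
                if len(l) < min_leaf or len(r) < min_leaf:
                    continue
                red = parent - ((l - l.mean()) ** 2).sum() - (
                    (r - r.mean()) ** 2
                ).sum()
                if best is None or red > best[2] + 1e-12:
                    best = (c, m, red)
        break_outer = False
    return best


class TestFitCart:
    def test_constant_response_empty_tree(self):
        t = _table(np.full(10, 3.0), x=np.arange(10.0))
        tree = fit_cart(t)
        assert tree.splits == [] and tree.r2 == 0.0

    def test_perfect_separator(self):
        x = np.arange(10.0)
        y = np.where(x <= 4, 0.0, 10.0)
        tree = fit_cart(_table(y, x=x))
        assert len(tree.splits) == 1
        assert tree.splits[0].covariate == "x"
        assert tree.splits[0].threshold == pytest.approx(4.5)
        assert tree.r2 == pytest.approx(1.0)
        c = contributions(tree)
        assert c.by_covariate["x"] == pytest.approx(100.0)

    def test_root_split_matches_exhaustive_oracle(self, rng):
        for trial in range(5):
            n = 12
            t = _table(
                rng.normal(size=n),
                a=rng.normal(size=n),
                b=rng.normal(size=n),
                c=rng.normal(size=n),
            )
            tree = fit_cart(t, prune_frac=0.0, tie_tol=0.0)
            oracle = _exhaustive_root_split(t)
            if not tree.splits:
                continue
            root = tree.splits[0]
            assert root.covariate == oracle[0]
            assert root.threshold == pytest.approx(oracle[1])
            assert root.ss_reduction == pytest.approx(oracle[2])

    def test_conflicting_tie_suppresses_split(self):
        # two covariates achieve the same reduction with *different*
        # partitions: genuinely ambiguous, so the node is not split
        y = np.array([0.0, 0.0, 10.0, 10.0, 5.0, 5.0])
        x1 = np.array([0.0, 0.0, 1.0, 1.0, 1.0, 1.0])  # isolates the 0s
        x2 = np.array([1.0, 1.0, 0.0, 0.0, 1.0, 1.0])  # isolates the 10s
        tree = fit_cart(_table(y, x1=x1, x2=x2), min_split=5)
        assert tree.splits == []
        assert tree.r2 == 0.0

    def test_identical_partition_tie_resolved_to_earlier_column(self):
        # strongly related covariates that group rows identically are not
        # ambiguous: the earlier column takes the split
        x1 = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        x2 = np.array([5.0, 5.0, 5.0, 9.0, 9.0, 9.0])
        y = np.array([0.0, 0.0, 0.0, 10.0, 10.0, 10.0])
        tree = fit_cart(_table(y, x1=x1, x2=x2), min_split=5)
        assert len(tree.splits) == 1
        assert tree.splits[0].covariate == "x1"
        assert tree.r2 == pytest.approx(1.0)

    def test_prune_frac_respects_total_ss(self):
        # a weak secondary structure below 10% of total SS is not split
        y = np.array([0.0, 0.0, 0.0, 0.5, 10.0, 10.0, 10.0, 10.4])
        x = np.arange(8.0)
        tree = fit_cart(_table(y, x=x), min_split=4, prune_frac=0.10)
        assert len(tree.splits) == 1  # only the big break survives

    def test_pruning_monotonicity(self, rng):
        n = 20
        t = _table(
            rng.normal(size=n) + np.repeat([0, 4], 10),
            a=rng.normal(size=n),
            b=np.repeat([0.0, 1.0], 10) + rng.normal(0, 0.1, size=n),
        )
        n_splits = []
        for pf in (0.0, 0.05, 0.10, 0.25, 0.6):
            n_splits.append(len(fit_cart(t, prune_frac=pf).splits))
        assert n_splits == sorted(n_splits, reverse=True)

    def test_contribution_conservation(self, rng):
        for _ in range(5):
            n = 18
            t = _table(
                rng.normal(size=n) * 3,
                a=rng.normal(size=n), b=rng.normal(size=n),
            )
            tree = fit_cart(t, prune_frac=0.05)
            c = contributions(tree)
            assert sum(c.by_covariate.values()) == pytest.approx(100 * tree.r2)

    def test_two_split_hand_computed(self):
        # y: three levels; x1 separates {0} vs {8,12}; x2 splits 8 vs 12
        y = np.array([0.0] * 4 + [8.0] * 3 + [12.0] * 3)
        x1 = np.array([0.0] * 4 + [1.0] * 6)
        x2 = np.array([0.0, 1.0, 0.0, 1.0] + [0.0] * 3 + [1.0] * 3)
        tree = fit_cart(
            _table(y, x1=x1, x2=x2), min_split=4, min_leaf=2, prune_frac=0.01
        )
        total = ((y - y.mean()) ** 2).sum()
        # hand-computed: root split on x1
        l, r = y[:4], y[4:]
        red1 = total - ((l - l.mean()) ** 2).sum() - ((r - r.mean()) ** 2).sum()
        # child split on x2 within the {8,12} node removes all remaining SS
        red2 = ((r - r.mean()) ** 2).sum()
        by_cov = {s.covariate: s.ss_reduction for s in tree.splits}
        assert by_cov["x1"] == pytest.approx(red1)
        assert by_cov["x2"] == pytest.approx(red2)
        c = contributions(tree)
        assert c.by_covariate["x1"] == pytest.approx(100 * red1 / total)
        assert c.by_covariate["x2"] == pytest.approx(100 * red2 / total)
        assert c.r2 == pytest.approx(1.0)

    def test_deterministic(self, rng):
        n = 15
        t = _table(rng.normal(size=n), a=rng.normal(size=n),
                   b=rng.normal(size=n))
        t1 = fit_cart(t)
        t2 = fit_cart(t.copy())
        assert [(s.covariate, s.threshold, s.ss_reduction) for s in t1.splits] \
            == [(s.covariate, s.threshold, s.ss_reduction) for s in t2.splits]


class TestDifferenceTable:
    def _explanatory(self, rng, n=10):
        cols = {m: rng.normal(size=n) for m in STOCK_METRIC_NAMES}
        for c in ("d_elevation", "m_elevation", "d_ranked_ndvi", "m_ranked_ndvi"):
            cols[c] = rng.normal(size=n)
        return pd.DataFrame(cols, index=[f"P{i}" for i in range(n)])

    def test_duplicated_column_dropped(self, rng):
        expl = self._explanatory(rng)
        expl["m_elevation"] = expl["d_elevation"]  # exact collinearity
        y = pd.Series(rng.normal(size=10), index=expl.index)
        table = build_difference_table(y, expl)
        assert "d_elevation" in table.columns
        assert "m_elevation" not in table.columns

    def test_stock_metrics_exempt_from_filter(self, rng):
        expl = self._explanatory(rng)
        # force perfect correlation among two stock metrics
        expl["max_nights"] = 2.0 * expl["mean_nights"]
        y = pd.Series(rng.normal(size=10), index=expl.index)
        table = build_difference_table(y, expl)
        assert "mean_nights" in table.columns
        assert "max_nights" in table.columns

    def test_near_constant_dropped(self, rng):
        expl = self._explanatory(rng)
        expl["d_ranked_ndvi"] = 1e-15 * np.arange(10)
        y = pd.Series(rng.normal(size=10), index=expl.index)
        table = build_difference_table(y, expl)
        assert "d_ranked_ndvi" not in table.columns

    def test_matches_greedy_filter_oracle(self, rng):
        expl = self._explanatory(rng, n=14)
        # random extra correlated columns
        expl["d_meadow_area"] = expl["d_elevation"] * 0.95 + rng.normal(
            0, 0.1, size=14
        )
        y = pd.Series(rng.normal(size=14), index=expl.index)
        table = build_difference_table(y, expl, corr_threshold=0.80)
        # oracle: greedy scan in column order over the physical blocks
        keep = []
        for col in expl.columns:
            v = expl[col].to_numpy()
            if np.std(v) < 1e-12:
                continue
            if col not in STOCK_METRIC_NAMES:
                drop = any(
                    abs(np.corrcoef(v, expl[p].to_numpy())[0, 1]) > 0.80
                    for p in keep
                    if p not in STOCK_METRIC_NAMES
                )
                if drop:
                    continue
            keep.append(col)
        assert [c for c in table.columns if c != "response"] == keep

    def test_too_few_rows_fatal(self, rng):
        expl = self._explanatory(rng)
        y = pd.Series(rng.normal(size=3), index=expl.index[:3])
        with pytest.raises(ValueError, match=">= 4"):
            build_difference_table(y, expl)


def test_category_mapping():
    assert category_of("max_nights_per_ha") == "StockUse"
    assert category_of("d_elevation") == "WithinPair"
    assert category_of("m_ranked_ndvi") == "BetweenPairs"
    with pytest.raises(ValueError):
        category_of("weird")
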
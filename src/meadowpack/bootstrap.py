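"""Bootstrapped stock-minus-control estimates with percentile 95% CIs.

For every retained (pair, stratum, response) cell, plots are resampled
with replacement within each meadow (B = 1000 replicates by default).
Mean differences (bare ground, species dispersion) subtract the control
replicate mean from the stock replicate mean; the estimate is the mean of
the replicate differences.  Species dissimilarity instead computes the
Bray-Curtis distance between the two replicate species-mean vectors, and
the estimate is the replicate median.  Confidence intervals are the
2.5/97.5 percentiles of the replicate distribution.

Each cell draws from an independent substream derived from the master
seed, so adding or removing a pair never perturbs the other cells.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np

from .responses import RESPONSES

__all__ = [
    "PairedDifferenceEstimate",
    "cell_rng",
    "boot_mean_diff",
    "boot_dissimilarity",
    "boot_dispersion_diff",
]


@dataclass(frozen=True)
class PairedDifferenceEstimate:
    """One bootstrapped stock-minus-control estimate with its 95% CI."""

    pair_id: str
    stratum: str
    response: str  # bare_ground_diff | dispersion_diff | dissimilarity
    estimate: float
    ci_low: float
    ci_high: float
    n_stock: int
    n_control: int
    b_reps: int
    seed: int

    @property
    def significant(self) -> bool:
        """CI excludes zero (meaningful for difference responses)."""
        return self.ci_low > 0.0 or self.ci_high < 0.0


def cell_rng(
    master_seed: int, pair_id: str, stratum: str, response: str
) -> np.random.Generator:
    """Independent, reproducible substream for one bootstrap cell."""
    key = (
        zlib.crc32(pair_id.encode()),
        zlib.crc32(stratum.encode()),
        RESPONSES.index(response) if response in RESPONSES else
        zlib.crc32(response.encode()),
    )
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=key)
    return np.random.default_rng(ss)


def _percentile_ci(reps: np.ndarray) -> tuple[float, float]:
    return (
        float(np.percentile(reps, 2.5)),
        float(np.percentile(reps, 97.5)),
    )


def boot_mean_diff(
    stock_values: np.ndarray,
    control_values: np.ndarray,
    pair_id: str,
    stratum: str,
    response: str = "bare_ground_diff",
    b_reps: int = 1000,
    seed: int = 0,
) -> PairedDifferenceEstimate:
    """Bootstrap the difference of means (stock minus control)."""
    sv = np.asarray(stock_values, dtype=float)
    cv = np.asarray(control_values, dtype=float)
    if sv.size == 0 or cv.size == 0:
        raise ValueError(f"empty sample in cell ({pair_id}, {stratum}, {response})")
    rng = cell_rng(seed, pair_id, stratum, response)
    s_idx = rng.integers(0, sv.size, size=(b_reps, sv.size))
    c_idx = rng.integers(0, cv.size, size=(b_reps, cv.size))
    diffs = sv[s_idx].mean(axis=1) - cv[c_idx].mean(axis=1)
    lo, hi = _percentile_ci(diffs)
    return PairedDifferenceEstimate(
        pair_id=pair_id, stratum=stratum, response=response,
        estimate=float(diffs.mean()), ci_low=lo, ci_high=hi,
        n_stock=int(sv.size), n_control=int(cv.size),
        b_reps=b_reps, seed=seed,
    )


def boot_dispersion_diff(
    stock_dispersions: np.ndarray,
    control_dispersions: np.ndarray,
    pair_id: str,
    stratum: str,
    b_reps: int = 1000,
    seed: int = 0,
) -> PairedDifferenceEstimate:
    """Bootstrap the difference of mean plot-level species dispersions."""
    return boot_mean_diff(
        stock_dispersions, control_dispersions, pair_id, stratum,
        response="dispersion_diff", b_reps=b_reps, seed=seed,
    )


def boot_dissimilarity(
    stock_plot_means: np.ndarray,
    control_plot_means: np.ndarray,
    pair_id: str,
    stratum: str,
    b_reps: int = 1000,
    seed: int = 0,
) -> PairedDifferenceEstimate:
    """Bootstrap the Bray-Curtis distance between meadow mean communities.

    Inputs are (n_plots x S) matrices of plot-level species-mean cover,
    aligned on the union species list of the pair.  Per replicate, plots
    are resampled within each meadow, mean vectors recomputed, and their
    Bray-Curtis distance taken; the estimate is the replicate median.
    Replicates where both resampled vectors are all-zero are recorded as
    missing.
    """
    sm = np.atleast_2d(np.asarray(stock_plot_means, dtype=float))
    cm = np.atleast_2d(np.asarray(control_plot_means, dtype=float))
    if sm.shape[0] == 0 or cm.shape[0] == 0:
        raise ValueError(f"empty plot set in cell ({pair_id}, {stratum})")
    rng = cell_rng(seed, pair_id, stratum, "dissimilarity")
    s_idx = rng.integers(0, sm.shape[0], size=(b_reps, sm.shape[0]))
    c_idx = rng.integers(0, cm.shape[0], size=(b_reps, cm.shape[0]))
    s_mean = sm[s_idx].mean(axis=1)  # B x S
    c_mean = cm[c_idx].mean(axis=1)
    num = np.abs(s_mean - c_mean).sum(axis=1)
    den = (s_mean + c_mean).sum(axis=1)
    vals = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    n_missing = int(np.isnan(vals).sum())
    if n_missing > 0.01 * b_reps:
        warnings.warn(
            f"cell ({pair_id}, {stratum}): {n_missing}/{b_reps} degenerate "
            "all-zero replicates recorded as missing"
        )
    ok = vals[~np.isnan(vals)]
    if ok.size == 0:
        raise ValueError(
            f"cell ({pair_id}, {stratum}): every replicate degenerate"
        )
    lo, hi = _percentile_ci(ok)
    return PairedDifferenceEstimate(
        pair_id=pair_id, stratum=stratum, response="dissimilarity",
        estimate=float(np.median(ok)), ci_low=lo, ci_high=hi,
        n_stock=int(sm.shape[0]), n_control=int(cm.shape[0]),
        b_reps=b_reps, seed=seed,
    )
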
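"""The three community response metrics.

* **Bare ground** — percent exposed mineral soil per 4 m^2 plot, a direct
  measure of soil disturbance and an indirect (inverse) measure of
  vegetation cover.
* **Species dissimilarity** — Bray-Curtis distance between the mean
  species-cover vectors of a stock meadow and its matched control within
  a vegetation community type, on untransformed cover.
* **Species dispersion** — local-scale compositional heterogeneity: the
  mean distance of a plot's eight 25x25 cm subplots to their centroid in
  the principal-coordinates embedding of the subplot Bray-Curtis matrix,
  with the standard negative-eigenvalue correction (imaginary axes
  subtract from squared distances, clamped at zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Dataset, PlotSample, SubplotCover

__all__ = [
    "bray_curtis",
    "bray_curtis_matrix",
    "plot_dispersion",
    "species_mean_vector",
    "bare_ground_summary",
    "subplot_matrix",
    "plot_dispersions_for_meadow",
    "bare_veg_correlation",
]

RESPONSES = ("bare_ground_diff", "dissimilarity", "dispersion_diff")


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) on aligned vectors.

    Two all-zero vectors return 0 (no community, no difference).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must be aligned on the same species list")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("cover values must be non-negative")
    denom = float((x + y).sum())
    if denom == 0.0:
        return 0.0
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_matrix(m: np.ndarray) -> np.ndarray:
    """Pairwise Bray-Curtis among the rows of a cover matrix."""
    m = np.asarray(m, dtype=float)
    if (m < 0).any():
        raise ValueError("cover values must be non-negative")
    diff = np.abs(m[:, None, :] - m[None, :, :]).sum(axis=2)
    tot = (m[:, None, :] + m[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(tot > 0, diff / np.where(tot > 0, tot, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    return d


def plot_dispersion(subplots: np.ndarray, eig_tol: float = 1e-10) -> float:
    """Mean distance of subplots to their ordinated centroid.

    ``subplots`` is the 8 x S cover matrix of one plot.  The subplot
    Bray-Curtis matrix is embedded by principal coordinates (double
    centering of -1/2 squared distances); axes with negative eigenvalues
    contribute negatively to squared distances, which are clamped at zero
    before the square root.  Because the embedding is centered, the group
    centroid is the origin.
    """
    m = np.asarray(subplots, dtype=float)
    if m.ndim != 2 or m.shape[0] != 8:
        raise ValueError(f"expected an 8 x S subplot matrix, got {m.shape}")
    if not (m.sum(axis=1) > 0).any():
        raise ValueError("all-zero subplot matrix: no community present")
    d = bray_curtis_matrix(m)
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    vals, vecs = np.linalg.eigh((g + g.T) / 2.0)
    scale = max(np.abs(vals).max(), 1.0)
    pos = vals > eig_tol * scale
    neg = vals < -eig_tol * scale
    sq_pos = (vecs[:, pos] ** 2 * vals[pos]).sum(axis=1) if pos.any() else 0.0
    sq_neg = (vecs[:, neg] ** 2 * (-vals[neg])).sum(axis=1) if neg.any() else 0.0
    sq = np.clip(sq_pos - sq_neg, 0.0, None)
    return float(np.sqrt(sq).mean())


def subplot_matrix(
    subplots: list[SubplotCover], species: list[str]
) -> np.ndarray:
    """Assemble an (n_subplots x S) cover matrix on a fixed species order."""
    idx = {sp: j for j, sp in enumerate(species)}
    m = np.zeros((len(subplots), len(species)))
    for i, s in enumerate(sorted(subplots, key=lambda s: s.subplot_index)):
        for sp, v in s.cover.items():
            if sp in idx:
                m[i, idx[sp]] = v
    return m


def species_mean_vector(
    plot_subplots: dict[int, list[SubplotCover]], species: list[str]
) -> np.ndarray:
    """Mean cover vector over a set of species plots.

    Subplot covers are averaged within each plot first, then plot means
    are averaged over the plot set, so unequal subplot richness cannot
    weight plots unevenly.
    """
    if not plot_subplots:
        raise ValueError("need at least one species plot")
    plot_means = [
        subplot_matrix(subs, species).mean(axis=0)
        for subs in plot_subplots.values()
    ]
    return np.vstack(plot_means).mean(axis=0)


def bare_ground_summary(plots: list[PlotSample]) -> tuple[float, np.ndarray]:
    """Plot-level bare-ground values and their mean for one meadow subset."""
    if not plots:
        raise ValueError("need at least one plot")
    vals = np.array([p.bare_ground_pct for p in plots], dtype=float)
    return float(vals.mean()), vals


def plot_dispersions_for_meadow(
    dataset: Dataset, meadow_id: str, plot_indices: list[int]
) -> dict[int, float]:
    """Species dispersion per plot; plots missing subplots are skipped."""
    species = dataset.species_names
    out: dict[int, float] = {}
    for pidx in plot_indices:
        subs = dataset.subplots_for(meadow_id, pidx)
        if len(subs) != 8:
            warnings.warn(
                f"plot ({meadow_id}, {pidx}) has {len(subs)} subplots, "
                "expected 8; excluded from dispersion"
            )
            continue
        m = subplot_matrix(subs, species)
        if not (m.sum(axis=1) > 0).any():
            warnings.warn(
                f"plot ({meadow_id}, {pidx}) has no recorded cover; excluded"
            )
            continue
        out[pidx] = plot_dispersion(m)
    return out


def bare_veg_correlation(plots: list[PlotSample]) -> dict[str, float]:
    """Diagnostic Pearson correlations of bare ground with cover.

    Reported (not asserted) to mirror the field check that bare ground is
    strongly anti-correlated with vegetation and vegetation-plus-litter
    cover.
    """
    bare = np.array([p.bare_ground_pct for p in plots])
    veg = np.array([p.total_veg_pct for p in plots])
    lit = np.array([p.litter_pct for p in plots])
    df = pd.DataFrame({"bare": bare, "veg": veg, "veg_litter": veg + lit})
    return {
        "bare_vs_veg": float(df["bare"].corr(df["veg"])),
        "bare_vs_veg_plus_litter": float(df["bare"].corr(df["veg_litter"])),
    }
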
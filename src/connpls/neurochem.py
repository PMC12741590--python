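"""Region importance scores and receptor-density spatial correlation.

The FDR-thresholded edge-loading map is collapsed to a per-region importance
score (sum of absolute loadings over a region's surviving edges), which is
then correlated across parcels against a panel of six receptor-density maps
(5HT1a, 5HT1b, 5HT2a, mGluR5, NMDA, GABAa) with BH-FDR over the six tests.

Plain Pearson correlation with parametric p-values is used, without
spatial-autocorrelation-preserving (spin) nulls; reports carry a warning to
that effect since parcellated brain maps are spatially smooth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import devectorize_edges
from .plsc import fdr_bh

__all__ = [
    "ImportanceVector",
    "importance_scores",
    "parcel_average",
    "receptor_correlation",
    "SPATIAL_NULL_WARNING",
]

SPATIAL_NULL_WARNING = (
    "receptor correlations use plain Pearson p-values; spatial autocorrelation "
    "is not accounted for (no spin test)"
)


@dataclass
class ImportanceVector:
    """Per-region importance derived from significant edge loadings."""

    scores: np.ndarray  # (n_regions,), nonnegative
    n_sig_edges: np.ndarray  # significant incident edges per region


def importance_scores(sig_loadings: np.ndarray, n_regions: int | None = None) -> ImportanceVector:
    """Sum of absolute significant edge loadings incident to each region.

    ``sig_loadings`` is the canonical edge vector with zeros where
    non-significant (a zero loading on a significant edge contributes nothing
    either way). Each edge contributes |loading| to both endpoints, so the
    scores sum to twice the total absolute loading.
    """
    M = np.abs(devectorize_edges(sig_loadings, n_regions))
    return ImportanceVector(scores=M.sum(axis=1), n_sig_edges=(M > 0).sum(axis=1))


def parcel_average(
    voxel_values: np.ndarray, voxel_labels: np.ndarray, n_regions: int = 246
):
    """Mean map value per parcel from voxel-level values and region labels.

    Labels are integers in 0..n_regions with 0 = background (dropped).
    Returns ``(means, missing)`` where ``missing`` flags regions without any
    voxel (their mean is NaN).
    """
    vals = np.asarray(voxel_values, dtype=float).ravel()
    labs = np.asarray(voxel_labels).ravel().astype(int)
    if vals.size != labs.size:
        raise ValueError("voxel_values and voxel_labels must have the same length")
    if labs.min() < 0 or labs.max() > n_regions:
        raise ValueError(f"labels must lie in 0..{n_regions}")
    keep = labs > 0
    if not keep.any():
        raise ValueError("all voxels are background (label 0); nothing to average")
    sums = np.bincount(labs[keep], weights=vals[keep], minlength=n_regions + 1)[1:]
    counts = np.bincount(labs[keep], minlength=n_regions + 1)[1:]
    missing = counts == 0
    with np.errstate(invalid="ignore"):
        means = np.where(missing, np.nan, sums / np.maximum(counts, 1))
    return means, missing


def receptor_correlation(
    importance: ImportanceVector | np.ndarray,
    panel: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of region importance against each receptor map.

    ``panel`` has one row per map (index = map name) and one column per
    parcel. Returns a per-map table with r, two-sided p, BH-FDR q across the
    maps, and the significance flag at ``q < alpha``.
    """
    imp = importance.scores if isinstance(importance, ImportanceVector) else np.asarray(importance, dtype=float)
    if imp.std() == 0:
        raise ValueError("importance scores are constant; correlation undefined")
    P = panel.to_numpy(dtype=float) if isinstance(panel, pd.DataFrame) else np.asarray(panel, dtype=float)
    names = list(panel.index) if isinstance(panel, pd.DataFrame) else [f"map_{i + 1}" for i in range(P.shape[0])]
    if P.shape[1] != imp.size:
        raise ValueError(f"panel has {P.shape[1]} parcels, importance has {imp.size}")
    rs, ps = [], []
    for name, row in zip(names, P):
        if row.std() == 0:
            raise ValueError(f"receptor map {name!r} is constant; correlation undefined")
        r, p = stats.pearsonr(imp, row)
        rs.append(r)
        ps.append(p)
    q, sig = fdr_bh(np.asarray(ps), alpha=alpha)
    return pd.DataFrame({"r": rs, "p": ps, "q_fdr": q, "sig": sig}, index=pd.Index(names, name="map"))
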
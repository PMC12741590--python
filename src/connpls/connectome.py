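"""Connectome feature engineering and motion quality control.

Node time series become Pearson correlation matrices, Fisher r-to-z
connectivity matrices, and canonical edge-feature vectors (the strict upper
triangle in row-major order, identical across subjects). Rigid-body motion
parameters are reduced to Jenkinson framewise displacement for subject
exclusion, and edge-level results can be averaged onto gyrus/lobe partitions.

Edge canonical order
--------------------
Edge ``k`` corresponds to region pair ``(i, j)`` with ``i < j``, enumerated
row-major over the strict upper triangle: (1,2), (1,3), ..., (1,n), (2,3), ...
For ``n`` regions there are ``n*(n-1)/2`` edges — 30,135 at ``n = 246``.

Motion convention
-----------------
Motion tables carry 6 columns in SPM order: 3 translations (mm) then 3
rotations (radians), rotations applied in x->y->z order about the volume
origin. The displacement formula integrates over a solid sphere of radius
80 mm centred at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import Parcellation

__all__ = [
    "n_edges",
    "edge_index",
    "pearson_fc",
    "fisher_z",
    "vectorize_edges",
    "devectorize_edges",
    "MotionTrace",
    "jenkinson_fd",
    "AggregatedLoadings",
    "aggregate_loadings",
]

FD_EXCLUSION_THRESHOLD_MM = 0.2
FD_SPHERE_RADIUS_MM = 80.0


def n_edges(n_regions: int) -> int:
    """Number of unordered region pairs: n*(n-1)/2."""
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    return n_regions * (n_regions - 1) // 2


def edge_index(n_regions: int) -> np.ndarray:
    """(m, 2) array of 0-based (i, j) pairs, i < j, in canonical row-major order."""
    iu = np.triu_indices(n_regions, k=1)
    return np.column_stack(iu)


def pearson_fc(timeseries: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Pearson correlation between node time courses.

    Parameters
    ----------
    timeseries : (frames, regions) array
        One column per region. At least 3 frames; no constant column.

    Returns
    -------
    (regions, regions) symmetric matrix with unit diagonal.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be 2-D (frames x regions)")
    if ts.shape[0] < 3:
        raise ValueError(f"need at least 3 frames, got {ts.shape[0]}")
    sd = ts.std(axis=0)
    const = np.flatnonzero(sd == 0)
    if const.size:
        raise ValueError(f"constant (zero-variance) time course for region(s) {(const + 1).tolist()}")
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return (r + r.T) / 2.0


def fisher_z(corr: np.ndarray) -> np.ndarray:
    """Fisher r-to-z transform, z = atanh(r), applied off-diagonal.

    The diagonal of the returned connectivity matrix is fixed at 0
    (self-connections are not features). Raises if any off-diagonal |r| = 1.
    """
    r = np.asarray(corr, dtype=float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValueError("corr must be square")
    off = ~np.eye(r.shape[0], dtype=bool)
    if np.any(np.abs(r[off]) >= 1.0):
        bad = np.argwhere((np.abs(r) >= 1.0) & off)[0]
        raise ValueError(
            f"|r| = 1 between regions {bad[0] + 1} and {bad[1] + 1}: Fisher z is infinite"
        )
    z = np.zeros_like(r)
    z[off] = np.arctanh(r[off])
    return (z + z.T) / 2.0


def vectorize_edges(cm: np.ndarray) -> np.ndarray:
    """Strict upper triangle of a symmetric zero-diagonal matrix, canonical order."""
    a = np.asarray(cm, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("connectivity matrix must be square")
    if not np.allclose(a, a.T, equal_nan=False):
        raise ValueError("connectivity matrix must be symmetric")
    return a[np.triu_indices(a.shape[0], k=1)]


def devectorize_edges(v: np.ndarray, n_regions: int | None = None) -> np.ndarray:
    """Inverse of :func:`vectorize_edges`; diagonal restored to 0."""
    vec = np.asarray(v, dtype=float).ravel()
    if n_regions is None:
        n_regions = int(round((1 + np.sqrt(1 + 8 * vec.size)) / 2))
    if n_edges(n_regions) != vec.size:
        raise ValueError(
            f"edge vector of length {vec.size} does not match n*(n-1)/2 for n={n_regions}"
        )
    out = np.zeros((n_regions, n_regions))
    iu = np.triu_indices(n_regions, k=1)
    out[iu] = vec
    out[(iu[1], iu[0])] = vec
    return out


@dataclass
class MotionTrace:
    """Rigid-body motion parameters with framewise-displacement QC summary."""

    params: np.ndarray  # (frames, 6): tx, ty, tz (mm), rx, ry, rz (rad)
    fd_series: np.ndarray = field(default=None)  # type: ignore[assignment]
    mean_fd: float = float("nan")
    excluded: bool = False
    threshold: float = FD_EXCLUSION_THRESHOLD_MM


def _rigid_transform(p: np.ndarray) -> np.ndarray:
    """4x4 homogeneous transform from (tx, ty, tz, rx, ry, rz), x->y->z rotation order."""
    tx, ty, tz, rx, ry, rz = p
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    T = np.eye(4)
    T[:3, :3] = Rz @ Ry @ Rx
    T[:3, 3] = (tx, ty, tz)
    return T


def jenkinson_fd(
    motion: np.ndarray | pd.DataFrame | MotionTrace,
    radius_mm: float = FD_SPHERE_RADIUS_MM,
    threshold: float = FD_EXCLUSION_THRESHOLD_MM,
) -> MotionTrace:
    """Jenkinson RMS framewise displacement and the exclusion decision.

    For consecutive rigid transforms ``T_{t-1}, T_t`` let
    ``M = T_t T_{t-1}^{-1} - I`` with rotation part ``A`` (3x3) and translation
    ``b`` (3-vector). Then::

        FD_t = sqrt(R^2/5 * trace(A.T A) + b.T b)

    which is the RMS displacement of points in a solid sphere of radius ``R``
    under the relative transform, to first order in the rotation. A subject is
    excluded when ``mean(FD) > threshold`` (0.2 mm by default).
    """
    params = motion.params if isinstance(motion, MotionTrace) else np.asarray(motion, dtype=float)
    if isinstance(params, pd.DataFrame):
        params = params.to_numpy(dtype=float)
    params = np.asarray(params, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError("motion parameters must have 6 columns (3 translations, 3 rotations)")
    if params.shape[0] < 2:
        raise ValueError("need at least 2 frames to compute framewise displacement")
    transforms = [_rigid_transform(p) for p in params]
    fd = np.empty(len(transforms) - 1)
    for t in range(1, len(transforms)):
        M = transforms[t] @ np.linalg.inv(transforms[t - 1]) - np.eye(4)
        A = M[:3, :3]
        b = M[:3, 3]
        fd[t - 1] = np.sqrt(radius_mm**2 / 5.0 * np.trace(A.T @ A) + b @ b)
    mean_fd = float(fd.mean())
    return MotionTrace(
        params=params,
        fd_series=fd,
        mean_fd=mean_fd,
        excluded=bool(mean_fd > threshold),
        threshold=threshold,
    )


@dataclass
class AggregatedLoadings:
    """Edge loadings averaged onto an anatomical partition."""

    values: pd.DataFrame  # partition x partition mean loading (0 where empty)
    edge_counts: pd.DataFrame  # number of contributing (significant) edges per block
    level: str

    @property
    def empty_blocks(self) -> pd.DataFrame:
        """Boolean frame flagging blocks with no contributing edges."""
        return self.edge_counts == 0


def aggregate_loadings(
    sig_loadings: np.ndarray,
    parc: Parcellation,
    level: str = "gyrus",
    include_nonsignificant: bool = False,
) -> AggregatedLoadings:
    """Average edge loadings within and between gyri or lobes.

    Parameters
    ----------
    sig_loadings : (n, n) symmetric matrix
        Edge loadings with zeros where non-significant (the FDR-thresholded
        map). The diagonal is ignored.
    parc : Parcellation
        Region -> gyrus/lobe lookup; must cover n regions.
    level : {"gyrus", "lobe"}
    include_nonsignificant : bool
        If True, zero-filled entries count in the denominator (mean over every
        edge in the block). Default averages over the surviving edges only;
        blocks without any surviving edge are 0 and flagged via edge_counts.
    """
    L = np.asarray(sig_loadings, dtype=float)
    if L.ndim != 2 or L.shape[0] != L.shape[1]:
        raise ValueError("loading matrix must be square")
    if not np.allclose(L, L.T):
        raise ValueError("loading matrix must be symmetric")
    if parc.n_regions != L.shape[0]:
        raise ValueError(f"parcellation covers {parc.n_regions} regions, matrix has {L.shape[0]}")
    labels = parc.labels(level).to_numpy()
    names = parc.partition_names(level)
    pos = {name: k for k, name in enumerate(names)}
    P = len(names)
    sums = np.zeros((P, P))
    sig_counts = np.zeros((P, P), dtype=int)
    all_counts = np.zeros((P, P), dtype=int)
    iu = np.triu_indices(L.shape[0], k=1)
    for i, j, w in zip(iu[0], iu[1], L[iu]):
        a, b = pos[labels[i]], pos[labels[j]]
        if a > b:
            a, b = b, a
        all_counts[a, b] += 1
        if w != 0.0:
            sums[a, b] += w
            sig_counts[a, b] += 1
    denom = all_counts if include_nonsignificant else sig_counts
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(denom > 0, sums / np.maximum(denom, 1), 0.0)
    means = means + np.triu(means, k=1).T
    counts_full = sig_counts + np.triu(sig_counts, k=1).T
    return AggregatedLoadings(
        values=pd.DataFrame(means, index=names, columns=names),
        edge_counts=pd.DataFrame(counts_full, index=names, columns=names),
        level=level,
    )
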
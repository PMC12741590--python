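"""Partial least-squares correlation (PLSC) with resampling inference.

PLSC finds pairs of weighted patterns ("saliences") of two variable blocks —
here edge-level connectivity X (n x m) and clinical measures Y (n x q) —
that maximally covary. Both blocks are column z-scored, so the decomposed
matrix is the q x m cross-correlation ``R = Yz' Xz / (n - 1)``. Its SVD
``R = V S U'`` yields, per latent component (LC): a brain salience (column
of U), a clinical salience (column of V), subject composite scores
``Lx = Xz U`` and ``Ly = Yz V``, and the covariance explained ``s_l^2 /
sum(s^2)``.

Inference follows standard behavioural-PLS practice: component significance
by permutation of the rows of Y (with Procrustes realignment of the permuted
solution before extracting singular values), loading stability by bootstrap
resampling of subjects (bootstrap SD -> z -> normal p), and
Benjamini-Hochberg FDR within each family (components; brain loadings;
clinical loadings).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LatentComponentSet",
    "BlockLoadings",
    "LoadingSet",
    "fit_plsc",
    "permutation_test",
    "compute_loadings",
    "bootstrap_loadings",
    "fdr_bh",
]


def _zscore(A: np.ndarray, what: str) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    sd = A.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance column(s) in {what}: {bad.tolist()}; cannot z-score")
    return (A - A.mean(axis=0)) / sd


@dataclass
class LatentComponentSet:
    """SVD of the z-scored cross-covariance plus permutation inference."""

    singular_values: np.ndarray  # (L,), descending
    brain_saliences: np.ndarray  # U, (m, L), unit-norm columns
    clinical_saliences: np.ndarray  # V, (q, L), unit-norm columns
    brain_scores: np.ndarray  # Lx = Xz U, (n, L)
    clinical_scores: np.ndarray  # Ly = Yz V, (n, L)
    cov_explained: np.ndarray  # (L,), sums to 1
    perm_p: np.ndarray | None = None
    perm_q: np.ndarray | None = None
    n_perm: int | None = None

    @property
    def n_components(self) -> int:
        return self.singular_values.size

    def latent_correlation(self, component: int = 0) -> float:
        """Pearson correlation between brain and clinical composite scores."""
        lx = self.brain_scores[:, component]
        ly = self.clinical_scores[:, component]
        return float(np.corrcoef(lx, ly)[0, 1])


def _svd_cross_correlation(Xz: np.ndarray, Yz: np.ndarray):
    n = Xz.shape[0]
    R = Yz.T @ Xz / (n - 1)
    V, s, Ut = np.linalg.svd(R, full_matrices=False)
    return R, V, s, Ut.T


def _apply_sign_convention(U: np.ndarray, V: np.ndarray) -> None:
    """Flip each (u, v) pair so the largest-|.| clinical salience entry is positive."""
    for l in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, l])))
        if V[j, l] < 0:
            V[:, l] *= -1.0
            U[:, l] *= -1.0


def fit_plsc(X: np.ndarray, Y: np.ndarray) -> LatentComponentSet:
    """Fit correlation-form PLSC of brain features X (n x m) vs measures Y (n x q).

    Both blocks are column z-scored (sample SD); zero-variance columns abort
    with an error naming the column, since silently dropping one would break
    the fixed edge order. SVD signs are fixed deterministically: each
    component is flipped so its largest-magnitude clinical salience entry is
    positive.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(getattr(Y, "values", Y), dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with matching row (subject) counts")
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    Xz = _zscore(X, "X")
    Yz = _zscore(Y, "Y")
    _, V, s, U = _svd_cross_correlation(Xz, Yz)
    _apply_sign_convention(U, V)
    total = float((s**2).sum())
    return LatentComponentSet(
        singular_values=s,
        brain_saliences=U,
        clinical_saliences=V,
        brain_scores=Xz @ U,
        clinical_scores=Yz @ V,
        cov_explained=s**2 / total if total > 0 else np.zeros_like(s),
    )


def _procrustes_rotation(V_ref: np.ndarray, V_new: np.ndarray) -> np.ndarray:
    """Orthogonal rotation R minimizing ||V_new R - V_ref||_F."""
    P, _, Qt = np.linalg.svd(V_new.T @ V_ref)
    return P @ Qt


def permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    align: str = "none",
    lcs: LatentComponentSet | None = None,
) -> LatentComponentSet:
    """Permutation test for latent-component significance.

    Rows of Y are shuffled (breaking the brain–clinical link while preserving
    each block's internal structure), the PLSC is refit, and the permuted
    singular values are compared rank-for-rank with the observed ones.
    ``p_l = (1 + #{perm >= obs}) / (1 + n_perm)`` (never 0), with BH FDR
    across the L components. Returns the fitted set with ``perm_p`` and
    ``perm_q`` filled in.

    ``align="procrustes"`` additionally rotates each permuted solution onto
    the observed clinical saliences before extracting singular values. That
    variant is offered for comparability with toolboxes that use it, but it
    is strongly anticonservative for the leading component (the rotation
    mixes permuted singular values downward while the observed maximum stays
    unrotated), so the calibrated rank-for-rank comparison is the default.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if align not in ("procrustes", "none"):
        raise ValueError("align must be 'procrustes' or 'none'")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(getattr(Y, "values", Y), dtype=float)
    if lcs is None:
        lcs = fit_plsc(X, Y)
    Xz = _zscore(X, "X")
    Yz = _zscore(Y, "Y")
    n = Xz.shape[0]
    s_obs = lcs.singular_values
    V_obs = lcs.clinical_saliences
    rng = np.random.default_rng(seed)
    exceed = np.zeros(s_obs.size, dtype=np.int64)
    for _ in range(n_perm):
        order = rng.permutation(n)
        _, Vp, sp, _ = _svd_cross_correlation(Xz, Yz[order])
        if align == "procrustes":
            R = _procrustes_rotation(V_obs, Vp)
            s_rot = np.linalg.norm(np.diag(sp) @ R, axis=0)
        else:
            s_rot = sp
        exceed += s_rot >= s_obs
    p = (1.0 + exceed) / (1.0 + n_perm)
    q, _ = fdr_bh(p)
    lcs.perm_p = p
    lcs.perm_q = q
    lcs.n_perm = n_perm
    return lcs


def _loadings_vs_score(A: np.ndarray, score: np.ndarray):
    """Pearson correlation of each column of A with a score vector.

    Zero-variance columns get loading 0 and a degenerate flag instead of an
    error (they occur legitimately in noise-free rank-1 data outside the
    salience support).
    """
    n = A.shape[0]
    sd_a = A.std(axis=0, ddof=1)
    sd_s = score.std(ddof=1)
    degenerate = sd_a == 0
    if sd_s == 0:
        raise ValueError("composite score has zero variance; loadings undefined")
    Ac = A - A.mean(axis=0)
    sc = (score - score.mean()) / sd_s
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ac.T @ sc) / (n - 1) / np.where(degenerate, 1.0, sd_a)
    r[degenerate] = 0.0
    return np.clip(r, -1.0, 1.0), degenerate


@dataclass
class BlockLoadings:
    """Loadings of one block (brain or clinical) with bootstrap inference."""

    loadings: np.ndarray
    degenerate: np.ndarray  # True where the loading is undefined (flagged, 0)
    boot_sd: np.ndarray | None = None
    z: np.ndarray | None = None
    p: np.ndarray | None = None
    q_fdr: np.ndarray | None = None
    sig_mask: np.ndarray | None = None


@dataclass
class LoadingSet:
    """Brain and clinical loadings for one latent component."""

    component: int
    brain: BlockLoadings
    clinical: BlockLoadings
    n_boot: int | None = None
    alpha: float | None = None
    redraws: int = 0  # degenerate bootstrap replicates that were redrawn


def compute_loadings(
    X: np.ndarray, Y: np.ndarray, lcs: LatentComponentSet, component: int = 0
) -> LoadingSet:
    """Point-estimate loadings: corr(variable, composite score) per block."""
    if not 0 <= component < lcs.n_components:
        raise ValueError(f"component {component} out of range (L={lcs.n_components})")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(getattr(Y, "values", Y), dtype=float)
    br, bdeg = _loadings_vs_score(X, lcs.brain_scores[:, component])
    cr, cdeg = _loadings_vs_score(Y, lcs.clinical_scores[:, component])
    return LoadingSet(
        component=component,
        brain=BlockLoadings(loadings=br, degenerate=bdeg),
        clinical=BlockLoadings(loadings=cr, degenerate=cdeg),
    )


def _finish_block(block: BlockLoadings, sd: np.ndarray, alpha: float) -> None:
    usable = (~block.degenerate) & (sd > 0)
    z = np.full(sd.shape, np.nan)
    p = np.full(sd.shape, np.nan)
    z[usable] = block.loadings[usable] / sd[usable]
    p[usable] = 2.0 * stats.norm.sf(np.abs(z[usable]))
    q = np.full(sd.shape, np.nan)
    sig = np.zeros(sd.shape, dtype=bool)
    if usable.any():
        q[usable], sig[usable] = fdr_bh(p[usable], alpha=alpha)
    block.boot_sd = sd
    block.z = z
    block.p = p
    block.q_fdr = q
    block.sig_mask = sig


def bootstrap_loadings(
    X: np.ndarray,
    Y: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    component: int = 0,
    lcs: LatentComponentSet | None = None,
    max_redraws: int = 100,
) -> LoadingSet:
    """Bootstrap stability of the loadings of one latent component.

    Subjects are resampled with replacement; each replicate is refit,
    Procrustes-aligned to the observed clinical saliences, and its loadings
    recorded. ``z = observed loading / bootstrap SD`` is converted to a
    two-sided normal p, then BH-FDR is applied separately within the brain
    and clinical families at level ``alpha``. Replicates with a
    zero-variance column are redrawn (counted in ``redraws``) up to
    ``max_redraws`` extra attempts.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(getattr(Y, "values", Y), dtype=float)
    n = X.shape[0]
    if n < 10:
        warnings.warn(f"bootstrap with only {n} subjects; SD estimates will be unstable")
    if lcs is None:
        lcs = fit_plsc(X, Y)
    point = compute_loadings(X, Y, lcs, component=component)
    V_obs = lcs.clinical_saliences
    rng = np.random.default_rng(seed)
    brain_reps = np.empty((n_boot, X.shape[1]))
    clin_reps = np.empty((n_boot, Y.shape[1]))
    redraws = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        try:
            Xb = _zscore(X[idx], "X (bootstrap replicate)")
            Yb = _zscore(Y[idx], "Y (bootstrap replicate)")
        except ValueError:
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError(
                    f"exceeded {max_redraws} redraws of degenerate bootstrap replicates"
                )
            continue
        _, Vb, sb, Ub = _svd_cross_correlation(Xb, Yb)
        R = _procrustes_rotation(V_obs, Vb)
        u_rot = (Ub @ R)[:, component]
        v_rot = (Vb @ R)[:, component]
        brain_reps[b], _ = _loadings_vs_score(Xb, Xb @ u_rot)
        clin_reps[b], _ = _loadings_vs_score(Yb, Yb @ v_rot)
        b += 1
    _finish_block(point.brain, brain_reps.std(axis=0, ddof=1), alpha)
    _finish_block(point.clinical, clin_reps.std(axis=0, ddof=1), alpha)
    point.n_boot = n_boot
    point.alpha = alpha
    point.redraws = redraws
    return point


def fdr_bh(p: np.ndarray, alpha: float = 0.05):
    """Benjamini-Hochberg step-up FDR.

    Returns ``(q_values, rejection_mask)`` with monotone q-values; the mask is
    True where ``q < alpha``.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q < alpha
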
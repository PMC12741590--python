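"""Synthetic cohorts with planted ground truth.

Emulates a case–control resting-state connectivity study: patients carry a
rank-1 latent axis linking edge features to nine clinical measures, controls
lack the axis but differ in mean on the signal-carrying edges, patients split
into subgroups via a mean shift on a second disjoint edge set, and treatment
improvements are linear in the edge features. Every downstream stage (QC,
PLSC, receptor correlation, classification, clustering, outcome prediction)
is therefore testable against known truth without any external data.

Generative model (patients)
---------------------------
With ``s ~ N(0, 1)`` per subject, unit-norm planted saliences ``u*`` (edges)
and ``v*`` (clinical), and i.i.d. standard-normal noise::

    X = latent_effect * s u*^T + eps
    Y_std = latent_effect * s v*^T + eta

``u*`` has equal-magnitude entries (+/- 1/sqrt(k)) on its edge support so
every supported edge is detectable in principle. ``v*`` follows the sign
pattern of the clinical profile (positive for illness duration, headache
intensity, anxiety and depression scores; negative for the three
quality-of-life subscales; zero for attack-day count and attack duration).
Clinical columns are then rescaled to realistic questionnaire units
(per-measure mean/SD). Controls: ``X = eps + control_offset`` on the support
edges. All draws flow from one integer seed via named sub-streams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import stream_rng
from .connectome import n_edges

__all__ = [
    "CLINICAL_MEASURES",
    "RECEPTOR_NAMES",
    "CohortSpec",
    "SyntheticGroundTruth",
    "Cohort",
    "generate_cohort",
    "generate_timeseries",
    "generate_receptor_panel",
    "generate_outcomes",
    "generate_motion",
    "write_cohort",
    "read_cohort",
]

#: The nine clinical measures, in fixed column order.
CLINICAL_MEASURES = [
    "duration_of_illness",
    "migraine_attack_days",
    "headache_intensity",
    "attack_duration_hours",
    "msq_role_restrictive",
    "msq_role_preventive",
    "msq_emotional",
    "sas",
    "sds",
]

#: Default sign of each measure's association with the planted latent axis:
#: worse burden = longer illness, more intense headache, higher anxiety and
#: depression scores, lower quality-of-life subscales.
DEFAULT_CLINICAL_SIGNS = (1, 0, 1, 0, -1, -1, -1, 1, 1)

#: Realistic per-measure means and SDs used to place the standardized
#: clinical columns on questionnaire units (months, days, VAS points, hours,
#: three 0-100 MSQ subscales, SAS, SDS).
DEFAULT_MEASURE_MEANS = (65.91, 5.53, 5.74, 8.39, 57.46, 65.38, 68.23, 45.18, 45.39)
DEFAULT_MEASURE_SDS = (35.83, 4.68, 1.24, 8.81, 17.44, 20.56, 19.08, 8.97, 10.78)

RECEPTOR_NAMES = ["5HT1a", "5HT1b", "5HT2a", "mGluR5", "NMDA", "GABAa"]

OUTCOME_MEASURES = ["improvement_vas", "improvement_sas", "improvement_sds"]


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    latent_effect is the SD of the planted latent-score axis relative to the
    unit cell noise; 0 removes the brain–clinical association entirely.
    """

    n_patients: int = 80
    n_controls: int = 94
    n_regions: int = 246
    latent_effect: float = 3.0
    n_support_edges: int = 50
    brain_support: np.ndarray | None = None  # explicit 0-based edge indices
    clinical_signs: tuple = DEFAULT_CLINICAL_SIGNS
    n_subgroups: int = 2
    subgroup_shift: float = 1.0
    subgroup_props: tuple | None = None  # None = equal split
    control_offset: float = 1.0
    measure_means: tuple = DEFAULT_MEASURE_MEANS
    measure_sds: tuple = DEFAULT_MEASURE_SDS
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.n_controls < 0:
            raise ValueError("n_controls must be >= 0")
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if not np.isfinite(self.latent_effect) or self.latent_effect < 0:
            raise ValueError(f"latent_effect must be finite and >= 0, got {self.latent_effect}")
        if len(self.clinical_signs) != 9:
            raise ValueError("clinical_signs must have exactly 9 entries")
        if not set(np.sign(self.clinical_signs)) <= {-1.0, 0.0, 1.0}:
            raise ValueError("clinical_signs entries must be in {-1, 0, +1}")
        m = n_edges(self.n_regions)
        if self.brain_support is not None:
            sup = np.asarray(self.brain_support, dtype=int)
            if sup.size == 0 and self.latent_effect > 0:
                raise ValueError("brain_support must be non-empty when latent_effect > 0")
            if sup.size and (sup.min() < 0 or sup.max() >= m):
                raise ValueError(f"brain_support index out of range for {m} edges")
        elif self.latent_effect > 0 and self.n_support_edges < 1:
            raise ValueError("need a non-empty edge support when latent_effect > 0")
        if self.n_subgroups < 1:
            raise ValueError("n_subgroups must be >= 1")
        if self.subgroup_props is not None:
            if len(self.subgroup_props) != self.n_subgroups:
                raise ValueError("subgroup_props length must equal n_subgroups")
            if not np.isclose(sum(self.subgroup_props), 1.0):
                raise ValueError("subgroup_props must sum to 1")

    @property
    def n_edges(self) -> int:
        return n_edges(self.n_regions)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        if d["brain_support"] is not None:
            d["brain_support"] = np.asarray(d["brain_support"]).tolist()
        for k in ("clinical_signs", "measure_means", "measure_sds", "subgroup_props"):
            if d[k] is not None:
                d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if d.get("brain_support") is not None:
            d["brain_support"] = np.asarray(d["brain_support"], dtype=int)
        for k in ("clinical_signs", "measure_means", "measure_sds", "subgroup_props"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class SyntheticGroundTruth:
    """Planted quantities retained for recovery tests."""

    u_star: np.ndarray  # unit-norm edge salience (length m)
    v_star: np.ndarray  # unit-norm clinical salience (length 9)
    latent_scores: np.ndarray  # s, per patient
    subgroup_labels: np.ndarray  # 1..k per patient
    subgroup_edges: list  # list of disjoint edge-index arrays, one per shifted subgroup
    outcome_weights: np.ndarray  # edge weights generating treatment improvements
    brain_support: np.ndarray  # edge indices carrying u*


@dataclass
class Cohort:
    """Generated cohort: edge features, clinical tables, and ground truth."""

    X_patients: np.ndarray  # (n_patients, m) Fisher-z-scale edge features
    Y_patients: pd.DataFrame  # (n_patients, 9) clinical measures
    X_controls: np.ndarray  # (n_controls, m)
    truth: SyntheticGroundTruth
    spec: CohortSpec


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a full case–control cohort under ``spec`` (deterministic per seed)."""
    spec.validate()
    m = spec.n_edges
    n = spec.n_patients

    rng_support = stream_rng(spec.seed, "support")
    if spec.brain_support is not None:
        support = np.sort(np.asarray(spec.brain_support, dtype=int))
    else:
        k = min(spec.n_support_edges, m)
        support = np.sort(rng_support.choice(m, size=k, replace=False))

    # equal-magnitude random-sign salience on the support
    u_star = np.zeros(m)
    if support.size:
        signs = rng_support.choice([-1.0, 1.0], size=support.size)
        u_star[support] = signs / np.sqrt(support.size)

    signs9 = np.asarray(spec.clinical_signs, dtype=float)
    if np.all(signs9 == 0):
        v_star = np.zeros(9)
    else:
        v_star = signs9 / np.linalg.norm(signs9)

    s = stream_rng(spec.seed, "latent").standard_normal(n)
    X = spec.latent_effect * np.outer(s, u_star) + stream_rng(spec.seed, "noise_x").standard_normal((n, m))
    Y_std = spec.latent_effect * np.outer(s, v_star) + stream_rng(spec.seed, "noise_y").standard_normal((n, 9))

    # subgroup structure: mean shift on disjoint edge sets (one per extra group)
    rng_sub = stream_rng(spec.seed, "subgroups")
    if spec.subgroup_props is None:
        props = np.full(spec.n_subgroups, 1.0 / spec.n_subgroups)
    else:
        props = np.asarray(spec.subgroup_props, dtype=float)
    sizes = np.floor(props * n).astype(int)
    sizes[-1] = n - sizes[:-1].sum()
    labels = np.repeat(np.arange(1, spec.n_subgroups + 1), sizes)
    labels = rng_sub.permutation(labels)
    free = np.setdiff1d(np.arange(m), support)
    subgroup_edges: list[np.ndarray] = []
    for g in range(2, spec.n_subgroups + 1):
        take = min(spec.n_support_edges, free.size)
        if take == 0:
            subgroup_edges.append(np.array([], dtype=int))
            continue
        edges_g = np.sort(rng_sub.choice(free, size=take, replace=False))
        free = np.setdiff1d(free, edges_g)
        subgroup_edges.append(edges_g)
        X[np.ix_(labels == g, edges_g)] += spec.subgroup_shift

    # controls: no latent axis, fixed mean offset on the support edges
    Xc = stream_rng(spec.seed, "controls").standard_normal((spec.n_controls, m))
    if support.size:
        Xc[:, support] += spec.control_offset

    # outcome weights: the planted axis plus the first subgroup contrast, so
    # improvements track both overall burden and subgroup membership
    w = u_star.copy()
    if subgroup_edges and subgroup_edges[0].size:
        d = np.zeros(m)
        d[subgroup_edges[0]] = 1.0 / np.sqrt(subgroup_edges[0].size)
        w = w + d
    nw = np.linalg.norm(w)
    if nw > 0:
        w = w / nw

    means = np.asarray(spec.measure_means, dtype=float)
    sds = np.asarray(spec.measure_sds, dtype=float)
    Y = pd.DataFrame(means + sds * Y_std, columns=CLINICAL_MEASURES)

    truth = SyntheticGroundTruth(
        u_star=u_star,
        v_star=v_star,
        latent_scores=s,
        subgroup_labels=labels,
        subgroup_edges=subgroup_edges,
        outcome_weights=w,
        brain_support=support,
    )
    return Cohort(X_patients=X, Y_patients=Y, X_controls=Xc, truth=truth, spec=spec)


def generate_timeseries(
    target_corr: np.ndarray, n_timepoints: int, seed: int = 0
) -> np.ndarray:
    """Gaussian node time series with population correlation ``target_corr``.

    The target must be symmetric positive semi-definite with unit diagonal;
    sampling uses its eigen square root. Sample correlation converges to the
    target at the usual 1/sqrt(T) rate.
    """
    C = np.asarray(target_corr, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("target_corr must be square")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("target_corr must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-10):
        raise ValueError("target_corr must have unit diagonal")
    p = C.shape[0]
    if n_timepoints <= p:
        raise ValueError(f"n_timepoints must exceed n_regions ({p})")
    w, V = np.linalg.eigh((C + C.T) / 2.0)
    if w.min() < -1e-8:
        raise ValueError(
            f"target_corr is not positive semi-definite (smallest eigenvalue {w.min():.6g})"
        )
    L = V * np.sqrt(np.clip(w, 0.0, None))
    Z = stream_rng(seed, "timeseries").standard_normal((n_timepoints, p))
    return Z @ L.T


def generate_receptor_panel(
    importance: np.ndarray,
    target_rho: np.ndarray = (0.6, 0.0, 0.6, 0.6, 0.0, 0.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Parcel-level receptor-density panel with planted spatial correlation.

    Each of the 6 maps is ``rho * z(importance) + sqrt(1 - rho^2) * z(noise)``
    so its population correlation with the importance profile is ``rho``.
    Rows are the fixed map names (5HT1a, 5HT1b, 5HT2a, mGluR5, NMDA, GABAa);
    columns are parcels. The default plants positive correlation on the
    serotonin 5HT1a/5HT2a and mGluR5 maps.
    """
    imp = np.asarray(importance, dtype=float)
    if not np.all(np.isfinite(imp)):
        raise ValueError("importance must be finite")
    if imp.std() == 0:
        raise ValueError("importance vector is constant; cannot calibrate correlations")
    rho = np.asarray(target_rho, dtype=float)
    if rho.size != len(RECEPTOR_NAMES):
        raise ValueError(f"target_rho must have {len(RECEPTOR_NAMES)} entries")
    if np.any(np.abs(rho) >= 1):
        raise ValueError("target_rho entries must lie in (-1, 1)")
    z_imp = (imp - imp.mean()) / imp.std()
    rng = stream_rng(seed, "receptors")
    rows = []
    for r in rho:
        noise = rng.standard_normal(imp.size)
        z_noise = (noise - noise.mean()) / noise.std()
        rows.append(r * z_imp + np.sqrt(1.0 - r**2) * z_noise)
    return pd.DataFrame(rows, index=RECEPTOR_NAMES, columns=np.arange(1, imp.size + 1))


def generate_outcomes(
    X: np.ndarray,
    truth: SyntheticGroundTruth,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Treatment-improvement table (VAS, SAS, SDS) linear in the edge features.

    ``improvement = X @ outcome_weights + noise`` with independent noise per
    outcome column; deterministic under the seed.
    """
    X = np.asarray(X, dtype=float)
    w = np.asarray(truth.outcome_weights, dtype=float)
    if X.ndim != 2 or X.shape[1] != w.size:
        raise ValueError(f"X has {X.shape[1] if X.ndim == 2 else '?'} columns, weights have {w.size}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    base = X @ w
    rng = stream_rng(seed, "outcomes")
    cols = {
        name: base + noise_sd * rng.standard_normal(X.shape[0]) for name in OUTCOME_MEASURES
    }
    return pd.DataFrame(cols)


def generate_motion(
    n_frames: int,
    burst_amplitude: float = 0.0,
    seed: int = 0,
    base_amplitude: float = 0.02,
    n_bursts: int = 3,
) -> pd.DataFrame:
    """Per-frame rigid-body motion table (tx, ty, tz in mm; rx, ry, rz in rad).

    A smooth low-amplitude drift (Gaussian-smoothed noise scaled to
    ``base_amplitude``) plus ``n_bursts`` brief high-motion episodes: 10-frame
    windows in which one translation axis alternates by
    ``+/- burst_amplitude / 2``, so consecutive-frame displacement within a
    burst is about ``burst_amplitude``. With the defaults (200 frames, 3
    bursts) a 2 mm burst amplitude pushes mean FD past the 0.2 mm exclusion
    threshold. Rotational drift is scaled by ``1 / radius`` so its
    displacement contribution matches the translations. Zero amplitudes give
    an all-zero trace.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = stream_rng(seed, "motion")
    width = 8
    kernel = np.exp(-0.5 * (np.arange(-3 * width, 3 * width + 1) / width) ** 2)
    kernel /= kernel.sum()

    def smooth(col: np.ndarray) -> np.ndarray:
        return np.convolve(col, kernel, mode="same")

    params = np.zeros((n_frames, 6))
    if base_amplitude > 0:
        for c in range(6):
            tr = smooth(rng.standard_normal(n_frames))
            sd = tr.std() or 1.0
            scale = base_amplitude if c < 3 else base_amplitude / FD_ROT_SCALE_MM
            params[:, c] = scale * tr / sd
    else:
        rng.standard_normal(n_frames * 6)  # keep the stream position stable
    if burst_amplitude > 0 and n_bursts > 0:
        burst_len = min(10, n_frames)
        starts = rng.integers(0, max(n_frames - burst_len, 1), size=n_bursts)
        axes = rng.integers(0, 3, size=n_bursts)
        for f, a in zip(starts, axes):
            window = np.arange(f, min(f + burst_len, n_frames))
            params[window, a] += burst_amplitude / 2.0 * (-1.0) ** np.arange(window.size)
    return pd.DataFrame(params, columns=["tx_mm", "ty_mm", "tz_mm", "rx_rad", "ry_rad", "rz_rad"])


FD_ROT_SCALE_MM = 80.0  # rotations scaled relative to the FD sphere radius


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write a cohort as delimited text plus a JSON ground-truth sidecar."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    m = cohort.X_patients.shape[1]
    edge_cols = [f"edge_{k + 1}" for k in range(m)]
    pd.DataFrame(cohort.X_patients, columns=edge_cols).to_csv(
        out / "X_patients.tsv", sep="\t", index_label="subject"
    )
    pd.DataFrame(cohort.X_controls, columns=edge_cols).to_csv(
        out / "X_controls.tsv", sep="\t", index_label="subject"
    )
    cohort.Y_patients.to_csv(out / "Y_patients.tsv", sep="\t", index_label="subject")
    t = cohort.truth
    sidecar = {
        "spec": cohort.spec.to_dict(),
        "u_star": t.u_star.tolist(),
        "v_star": t.v_star.tolist(),
        "latent_scores": t.latent_scores.tolist(),
        "subgroup_labels": t.subgroup_labels.tolist(),
        "subgroup_edges": [e.tolist() for e in t.subgroup_edges],
        "outcome_weights": t.outcome_weights.tolist(),
        "brain_support": t.brain_support.tolist(),
    }
    (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_cohort(indir) -> Cohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    d = Path(indir)
    Xp = pd.read_csv(d / "X_patients.tsv", sep="\t", index_col=0).to_numpy(dtype=float)
    Xc = pd.read_csv(d / "X_controls.tsv", sep="\t", index_col=0).to_numpy(dtype=float)
    Y = pd.read_csv(d / "Y_patients.tsv", sep="\t", index_col=0)
    sidecar = json.loads((d / "ground_truth.json").read_text())
    truth = SyntheticGroundTruth(
        u_star=np.asarray(sidecar["u_star"], dtype=float),
        v_star=np.asarray(sidecar["v_star"], dtype=float),
        latent_scores=np.asarray(sidecar["latent_scores"], dtype=float),
        subgroup_labels=np.asarray(sidecar["subgroup_labels"], dtype=int),
        subgroup_edges=[np.asarray(e, dtype=int) for e in sidecar["subgroup_edges"]],
        outcome_weights=np.asarray(sidecar["outcome_weights"], dtype=float),
        brain_support=np.asarray(sidecar["brain_support"], dtype=int),
    )
    return Cohort(Xp, Y, Xc, truth, CohortSpec.from_dict(sidecar["spec"]))
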
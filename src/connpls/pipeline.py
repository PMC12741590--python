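"""End-to-end orchestration: simulate -> QC -> PLSC -> aggregation ->
neurochemistry -> clinical utility, with a self-contained JSON report.

The report embeds the exact configuration (including every derived seed), so
rerunning from the embedded config reproduces it byte-identically. Subjects
excluded by motion QC are dropped before any statistics are computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._seeds import stream_seed
from .atlas import synthetic_parcellation
from .clinical import classify_patients, cluster_patients, compare_subgroups, regress_measure
from .connectome import aggregate_loadings, devectorize_edges, jenkinson_fd
from .neurochem import SPATIAL_NULL_WARNING, importance_scores, receptor_correlation
from .plsc import bootstrap_loadings, fit_plsc, permutation_test
from .synthetic import (
    CLINICAL_MEASURES,
    Cohort,
    CohortSpec,
    generate_cohort,
    generate_motion,
    generate_outcomes,
    generate_receptor_panel,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "validate_inputs"]


@dataclass
class RunConfig:
    """Everything needed to reproduce one full analysis run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    alpha: float = 0.05
    n_perm: int = 1000
    n_boot: int = 1000
    component: int = 0
    n_splits: int = 10
    n_perm_ml: int = 200
    k_max: int = 8
    pca_components: int | None = None
    interpret_measures: bool = True
    receptor_rho: tuple = (0.6, 0.0, 0.6, 0.6, 0.0, 0.0)
    outcome_noise_sd: float = 1.0
    motion_frames: int = 200
    n_high_motion_patients: int = 0
    n_high_motion_controls: int = 0
    motion_burst_mm: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        self.cohort.validate()
        for name in ("n_perm", "n_boot"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "cohort"}
        d["receptor_rho"] = list(self.receptor_rho)
        d["cohort"] = self.cohort.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["cohort"] = CohortSpec.from_dict(d.get("cohort", {}))
        if "receptor_rho" in d:
            d["receptor_rho"] = tuple(d["receptor_rho"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def default(cls, seed: int = 0, **overrides) -> "RunConfig":
        """Config whose cohort seed is derived from the top-level seed."""
        cohort_kwargs = overrides.pop("cohort", {})
        cohort = CohortSpec(seed=stream_seed(seed, "cohort"), **cohort_kwargs)
        return cls(cohort=cohort, seed=seed, **overrides)


@dataclass
class RunReport:
    """Structured result of one pipeline run."""

    data: dict

    def to_json(self) -> str:
        return json.dumps(self.data, sort_keys=True, indent=1, default=_jsonify)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json())


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.bool_,)):
        return bool(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


def _motion_qc(config: RunConfig, n_patients: int, n_controls: int):
    """Simulated motion traces; returns kept-index arrays and the QC record."""
    seed = stream_seed(config.seed, "motion")
    rng = np.random.default_rng(seed)
    high_p = set(rng.choice(n_patients, size=config.n_high_motion_patients, replace=False).tolist())
    high_c = set(rng.choice(n_controls, size=min(config.n_high_motion_controls, n_controls), replace=False).tolist())
    record = {"threshold_mm": 0.2, "patients": [], "controls": []}

    def scan(n_subj, high, group):
        keep = []
        for i in range(n_subj):
            burst = config.motion_burst_mm if i in high else 0.0
            trace = generate_motion(config.motion_frames, burst_amplitude=burst, seed=seed + 7 * i + (0 if group == "patients" else 1))
            mt = jenkinson_fd(trace.to_numpy())
            record[group].append({"subject": i, "mean_fd_mm": round(mt.mean_fd, 6), "excluded": mt.excluded})
            if not mt.excluded:
                keep.append(i)
        return np.asarray(keep, dtype=int)

    keep_p = scan(n_patients, high_p, "patients")
    keep_c = scan(n_controls, high_c, "controls")
    return keep_p, keep_c, record


def run_pipeline(config: RunConfig, outdir=None) -> RunReport:
    """Run the full analysis under ``config``; optionally write artifacts.

    Stage order: cohort simulation, motion QC (excluded subjects are dropped
    everywhere downstream), PLSC with permutation and bootstrap inference,
    gyrus/lobe aggregation of the thresholded loading map, region importance
    and receptor correlation, then the clinical battery (classification,
    interpretation, clustering, outcome prediction, subgroup comparison).
    """
    config.validate()
    warnings: list[str] = []
    cohort = generate_cohort(config.cohort)
    n_regions = config.cohort.n_regions

    keep_p, keep_c, qc = _motion_qc(config, config.cohort.n_patients, config.cohort.n_controls)
    X = cohort.X_patients[keep_p]
    Y = cohort.Y_patients.iloc[keep_p].reset_index(drop=True)
    Xc = cohort.X_controls[keep_c]
    truth_labels = cohort.truth.subgroup_labels[keep_p]

    # --- PLSC core ---
    lcs = fit_plsc(X, Y)
    lcs = permutation_test(X, Y, n_perm=config.n_perm, seed=stream_seed(config.seed, "perm"), lcs=lcs)
    loadings = bootstrap_loadings(
        X, Y, n_boot=config.n_boot, seed=stream_seed(config.seed, "boot"),
        alpha=config.alpha, component=config.component, lcs=lcs,
    )
    sig_any_lc = bool((lcs.perm_q < config.alpha).any())
    if not sig_any_lc:
        warnings.append("no latent component significant after FDR")

    brain_vec = loadings.brain.loadings.copy()
    thresholded = np.where(loadings.brain.sig_mask, brain_vec, 0.0)
    sig_edges = np.flatnonzero(loadings.brain.sig_mask)

    # --- anatomical aggregation ---
    parc = synthetic_parcellation(n_regions)
    thr_matrix = devectorize_edges(thresholded, n_regions)
    agg_gyrus = aggregate_loadings(thr_matrix, parc, level="gyrus")
    agg_lobe = aggregate_loadings(thr_matrix, parc, level="lobe")

    # --- neurochemistry ---
    imp = importance_scores(thresholded, n_regions)
    receptor = None
    if imp.scores.std() > 0:
        panel = generate_receptor_panel(
            imp.scores, target_rho=config.receptor_rho, seed=stream_seed(config.seed, "receptors")
        )
        receptor = receptor_correlation(imp, panel, alpha=config.alpha)
        warnings.append(SPATIAL_NULL_WARNING)
    else:
        warnings.append("no significant edges; receptor correlation skipped")

    # --- clinical battery on the significant-edge mask ---
    ml: dict = {}
    if sig_edges.size:
        feats = np.vstack([X[:, sig_edges], Xc[:, sig_edges]])
        labels01 = np.concatenate([np.ones(len(X), dtype=int), np.zeros(len(Xc), dtype=int)])
        clf = classify_patients(
            feats, labels01, n_splits=config.n_splits, n_perm=config.n_perm_ml,
            seed=stream_seed(config.seed, "svc"),
        )
        ml["classification"] = asdict(clf)

        if config.interpret_measures:
            interp = {}
            for j, name in enumerate(CLINICAL_MEASURES):
                rep = regress_measure(
                    X[:, sig_edges], Y.iloc[:, j].to_numpy(), n_splits=config.n_splits,
                    n_perm=config.n_perm_ml, seed=stream_seed(config.seed, f"svr_{name}"),
                )
                interp[name] = asdict(rep)
            ml["interpretation"] = interp

        clus = cluster_patients(
            X[:, sig_edges], k_max=config.k_max, seed=stream_seed(config.seed, "kmeans"),
            pca_components=config.pca_components,
        )
        if clus.weak_structure:
            warnings.append(f"weak cluster structure (silhouette {clus.silhouette:.3f})")
        ml["clustering"] = {
            "k": clus.k,
            "labels": clus.labels.tolist(),
            "cluster_sizes": np.bincount(clus.labels)[1:].tolist(),
            "silhouette": clus.silhouette,
            "inertia_curve": {str(k): v for k, v in clus.inertia_curve.items()},
            "weak_structure": clus.weak_structure,
        }

        outcomes = generate_outcomes(
            X, cohort.truth, noise_sd=config.outcome_noise_sd,
            seed=stream_seed(config.seed, "outcomes"),
        )
        pred = {}
        for name in outcomes.columns:
            rep = regress_measure(
                X[:, sig_edges], outcomes[name].to_numpy(), n_splits=config.n_splits,
                n_perm=config.n_perm_ml, seed=stream_seed(config.seed, f"predict_{name}"),
            )
            pred[name] = asdict(rep)
        ml["outcome_prediction"] = pred

        if clus.k == 2:
            comp = compare_subgroups(Y, outcomes, clus.labels, alpha=config.alpha)
            ml["subgroup_comparison"] = {
                m: {"test": row["test"], "statistic": row["statistic"], "p": row["p"],
                    "q_fdr": row["q_fdr"], "sig": bool(row["sig"])}
                for m, row in comp.iterrows()
            }
    else:
        warnings.append("no significant edges; clinical battery skipped")

    report = RunReport(
        data={
            "package_version": __version__,
            "config": config.to_dict(),
            "qc": {
                "n_patients_excluded": int(config.cohort.n_patients - keep_p.size),
                "n_controls_excluded": int(config.cohort.n_controls - keep_c.size),
                "n_patients_retained": int(keep_p.size),
                "n_controls_retained": int(keep_c.size),
                "detail": qc,
            },
            "plsc": {
                "n_components": int(lcs.n_components),
                "singular_values": lcs.singular_values.tolist(),
                "cov_explained": lcs.cov_explained.tolist(),
                "perm_p": lcs.perm_p.tolist(),
                "perm_q": lcs.perm_q.tolist(),
                "n_perm": lcs.n_perm,
                "latent_correlation_lc1": lcs.latent_correlation(config.component),
                "any_significant_lc": sig_any_lc,
                "clinical_loadings": {
                    name: {
                        "loading": float(loadings.clinical.loadings[j]),
                        "boot_sd": float(loadings.clinical.boot_sd[j]),
                        "q_fdr": float(loadings.clinical.q_fdr[j]),
                        "sig": bool(loadings.clinical.sig_mask[j]),
                    }
                    for j, name in enumerate(CLINICAL_MEASURES)
                },
                "n_significant_edges": int(sig_edges.size),
                "bootstrap_redraws": loadings.redraws,
            },
            "aggregation": {
                "gyrus": agg_gyrus.values.to_dict(),
                "lobe": agg_lobe.values.to_dict(),
            },
            "neurochem": None if receptor is None else {
                m: {"r": float(row["r"]), "p": float(row["p"]),
                    "q_fdr": float(row["q_fdr"]), "sig": bool(row["sig"])}
                for m, row in receptor.iterrows()
            },
            "clinical_ml": ml,
            "recovery": {
                "salience_corr_u": _truth_corr(lcs.brain_saliences[:, config.component], cohort.truth.u_star),
                "salience_corr_v": _truth_corr(lcs.clinical_saliences[:, config.component], cohort.truth.v_star),
                "cluster_truth_agreement": _label_agreement(ml.get("clustering", {}).get("labels"), truth_labels),
            },
            "warnings": warnings,
            "seeds": {
                stage: stream_seed(config.seed, stage)
                for stage in ("cohort", "motion", "perm", "boot", "svc", "kmeans", "outcomes", "receptors")
            },
        }
    )
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        report.write(out / "report.json")
        config.to_yaml(out / "config.yaml")
        full_matrix = devectorize_edges(loadings.brain.loadings, n_regions)
        pd.DataFrame(full_matrix).to_csv(out / "brain_loadings_unthresholded.tsv", sep="\t")
        pd.DataFrame(thr_matrix).to_csv(out / "brain_loadings_thresholded.tsv", sep="\t")
        agg_gyrus.values.to_csv(out / "loadings_gyrus.tsv", sep="\t")
        agg_lobe.values.to_csv(out / "loadings_lobe.tsv", sep="\t")
    return report


def _truth_corr(estimate, truth) -> float | None:
    truth = np.asarray(truth, dtype=float)
    if truth.std() == 0 or np.asarray(estimate).std() == 0:
        return None
    return float(abs(np.corrcoef(np.asarray(estimate, dtype=float), truth)[0, 1]))


def _label_agreement(labels, truth_labels) -> float | None:
    """Best one-to-one label-matching agreement between two groupings."""
    if labels is None:
        return None
    a = np.asarray(labels)
    b = np.asarray(truth_labels)
    if a.size != b.size:
        return None
    from scipy.optimize import linear_sum_assignment

    cats_a, ai = np.unique(a, return_inverse=True)
    cats_b, bi = np.unique(b, return_inverse=True)
    cont = np.zeros((cats_a.size, cats_b.size))
    np.add.at(cont, (ai, bi), 1.0)
    rows, cols = linear_sum_assignment(-cont)
    return float(cont[rows, cols].sum() / a.size)


def validate_inputs(paths: dict) -> list[str]:
    """Schema checks for user-supplied delimited inputs.

    ``paths`` may contain: ``connectivity`` (one file or a list; square,
    symmetric, finite, zero diagonal), ``clinical`` (the 9 canonical columns,
    in order), ``atlas`` (contiguous region_id with gyrus/lobe labels),
    ``motion`` (6 numeric columns). Returns a list of violation strings
    (empty = valid); it never raises on content problems.
    """
    violations: list[str] = []

    conn = paths.get("connectivity")
    if conn is not None:
        files = conn if isinstance(conn, (list, tuple)) else [conn]
        for f in files:
            try:
                mat = pd.read_csv(f, sep="\t", index_col=0).to_numpy(dtype=float)
            except Exception as e:
                violations.append(f"{f}: unreadable connectivity matrix ({e})")
                continue
            if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
                violations.append(f"{f}: matrix is {mat.shape}, not square")
                continue
            if not np.all(np.isfinite(mat)):
                violations.append(f"{f}: non-finite entries")
            asym = float(np.abs(mat - mat.T).max())
            if asym > 1e-8:
                violations.append(f"{f}: asymmetric (max |A - A'| = {asym:.3g})")
            if np.abs(np.diag(mat)).max() > 1e-8:
                violations.append(f"{f}: nonzero diagonal")

    clin = paths.get("clinical")
    if clin is not None:
        try:
            df = pd.read_csv(clin, sep="\t", index_col=0)
            cols = list(df.columns)
            missing = [c for c in CLINICAL_MEASURES if c not in cols]
            for c in missing:
                violations.append(f"{clin}: missing clinical column {c!r}")
            if not missing and cols[: len(CLINICAL_MEASURES)] != CLINICAL_MEASURES:
                violations.append(f"{clin}: clinical columns out of canonical order")
            if df.isna().any().any():
                violations.append(f"{clin}: missing values present")
        except Exception as e:
            violations.append(f"{clin}: unreadable clinical table ({e})")

    atlas_path = paths.get("atlas")
    if atlas_path is not None:
        try:
            from .atlas import load_parcellation

            load_parcellation(atlas_path)
        except Exception as e:
            violations.append(f"{atlas_path}: invalid atlas table ({e})")

    motion = paths.get("motion")
    if motion is not None:
        files = motion if isinstance(motion, (list, tuple)) else [motion]
        for f in files:
            try:
                mp = pd.read_csv(f, sep="\t").to_numpy(dtype=float)
                if mp.shape[1] != 6:
                    violations.append(f"{f}: motion table has {mp.shape[1]} columns, expected 6")
            except Exception as e:
                violations.append(f"{f}: unreadable motion table ({e})")

    return violations
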
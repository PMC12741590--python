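# Methods

This note documents the statistical model, the synthetic-data generative
process, the numerical conventions, and the design choices that were
genuinely open, in the order a user meets them in the pipeline.

## Connectome features

Node time series are correlated pairwise (Pearson), Fisher r-to-z
transformed (`z = atanh(r)`, variance-stabilizing), and the strict upper
triangle is vectorized in a fixed row-major order: edge k ↔ (i, j), i < j,
enumerated (1,2), (1,3), …, (1,p), (2,3), … This order is identical across
subjects — the cross-subject feature alignment the PLSC step relies on — and
is documented in file headers. Self-connections are excluded throughout;
connectivity matrices carry a structural zero diagonal. A 246-region
parcellation yields 30,135 edges. Zero-variance node time courses and
|r| = 1 off-diagonal correlations are hard errors (they cannot be
z-transformed and silently dropping a column would corrupt the edge order).

### Motion QC

Rigid-body parameter tables use the SPM column convention — three
translations (mm) then three rotations (radians), rotations applied in
x→y→z order about the volume origin. This convention is an assumption (the
field stores motion parameters in several conventions) and is declared here
and in the I/O docstrings. For consecutive transforms the Jenkinson
framewise displacement is

    FD_t = sqrt(R²/5 · tr(AᵀA) + bᵀb),   M = T_t T_{t−1}⁻¹ − I = [A | b]

the RMS displacement of points uniform in a solid sphere of radius
R = 80 mm; subjects with mean FD > 0.2 mm are excluded before any analysis.
FD depends only on relative motion (right-composition invariance), which the
test suite checks, and the rotation term is validated against a Monte-Carlo
sphere-integration oracle.

## PLSC

Correlation-form PLSC: both blocks are column z-scored (sample SD, ddof 1)
before the cross-product, because the nine clinical measures live on wildly
different scales (months, days, hours, 0–100 questionnaire scores). The
decomposed matrix is therefore the q × m cross-correlation. SVD signs are
fixed deterministically — each (u, v) pair is flipped jointly so the
largest-magnitude clinical salience entry is positive — making runs and
reruns comparable. The brain–clinical composite-score correlation of a
component is automatically nonnegative (its covariance is the singular
value).

Note one consequence of the z-scoring: on exactly rank-1 data `X = s u*ᵀ`
the fitted brain salience equals the *sign pattern* of `u*`, not `u*`
itself, because per-column scale information is removed. Equal-magnitude
saliences (the synthetic generator's choice, below) are invariant under
this.

### Permutation test

Rows of Y are permuted (clinical block; permuting X instead is equivalent in
distribution), the model is refit, and permuted singular values are compared
rank-for-rank with the observed ones; `p_ℓ = (1 + #{s_perm,ℓ ≥ s_ℓ}) /
(1 + n_perm)` (add-one estimator, never 0), BH-FDR across the L components.

A Procrustes variant — rotating each permuted solution onto the observed
clinical saliences before extracting singular values, as some toolboxes do —
is available (`align="procrustes"`) but is *not* the default: the rotation
is a convex mixing of permuted singular values, which can only shrink the
leading permuted value while the observed maximum stays unrotated. Measured
on 200 null cohorts this inflates LC1 rejection at α = 0.05 to ≈ 0.58. The
rank-for-rank comparison is exactly exchangeable under the permutation group
(measured null rejection 0.04–0.06) and is therefore the default.

### Bootstrap

Subjects are resampled with replacement; each replicate is refit and
Procrustes-aligned (rotation from the SVD of V_repᵀV_obs) to the observed
solution — here the alignment is essential, preventing axis swaps and sign
flips from inflating the loading SD. `z = observed loading / bootstrap SD`
is converted to a two-sided normal p. FDR families are kept separate:
components (L tests), brain loadings (m tests), clinical loadings (q tests),
matching how such results are reported (a scree-level decision, an edge map,
a clinical profile). Replicates containing a zero-variance column are
redrawn (counted and reported) up to a cap; loadings with zero bootstrap SD
are flagged degenerate and excluded from the FDR family rather than given an
infinite z.

`fdr_bh` is a thin, validated wrapper over the standard Benjamini–Hochberg
step-up (statsmodels backend); the test suite checks it against a literal
independently-written step-up rule.

## Anatomy and neurochemistry

Gyrus/lobe aggregation averages the FDR-surviving edge loadings within and
between partitions. The default denominator is the number of *surviving*
edges in the block — "averaging the significant loadings" — with the
zero-filled variant (all edges in the block) behind a switch; empty blocks
are 0 and flagged via their edge count. Region importance is the sum of
absolute significant edge loadings incident to a region (each edge credits
both endpoints, so scores sum to twice the total absolute loading);
summing unthresholded loadings is available behind a switch but the
thresholded map is the default since the importance step consumes the
FDR-thresholded result of the previous stage. Receptor panels are consumed
at parcel level (a voxel-to-parcel averaging helper on label vectors is
provided; volumetric resampling is out of scope). Correlations are plain
Pearson over parcels with BH-FDR over the six maps; spatial-autocorrelation-
preserving nulls (spin tests) are *not* applied, and reports carry a warning
noting that parcellated brain maps are spatially smooth, so these p-values
are optimistic on real data.

## Clinical-utility battery

Linear-kernel SVC/SVR with unit regularization, no nested tuning: fixed,
simple settings keep the permutation null exchangeable and runs
reproducible. Cross-validation is stratified (classification) or plain
(regression) 10-fold, shuffled once under a recorded seed; metrics are
pooled over held-out folds (accuracy, case-recall sensitivity,
control-recall specificity, AUC from pooled decision scores; Pearson r and
MSE between observed values and out-of-fold predictions). Permutation
p-values refit the entire CV under label/target shuffles with the add-one
estimator. Features entering every model are the PLSC-significant edges
only; no further selection.

k-means (k-means++, 50 restarts, fixed seed) runs for k = 1..8; the elbow is
operationalized as the maximum second difference of the inertia curve
(including k = 1, so k = 2 is selectable), and the mean silhouette at the
chosen k is reported, with silhouette < 0.3 flagged as weak structure. An
optional PCA projection precedes clustering only when the user specifies a
dimension. Group comparisons use the pooled-variance (Student) two-sample t
for continuous measures — pooled, not Welch, because pooled t reproduces the
printed statistics of the reference summary tables — and Pearson χ² without
continuity correction for categorical ones, with BH-FDR across the tested
measures.

## Synthetic cohorts

The generator emulates a case–control connectivity study with one planted
brain–clinical axis:

    X = e · s u*ᵀ + ε,   Y_std = e · s v*ᵀ + η,   s, ε, η ~ N(0, 1) i.i.d.

- `e` (`latent_effect`, default 3) is the SD of the planted axis relative to
  unit cell noise; 0 removes the association entirely.
- `u*` has equal-magnitude entries ±1/√k on a k-edge support (default 50).
  Equal magnitudes make every supported edge detectable in principle (a
  Gaussian draw would plant near-zero coordinates that no method could
  flag) and survive column z-scoring unchanged.
- `v*` is the normalized clinical sign pattern: positive for illness
  duration, headache intensity, anxiety and depression; negative for the
  three quality-of-life subscales; zero for the two attack-timing measures —
  seven informative measures of nine. Standardized clinical columns are then
  mapped to realistic questionnaire units via fixed per-measure means/SDs
  (positive scalings, so the sign structure is preserved).
- Controls lack the latent axis and differ by a fixed mean offset (default
  1.0) on the support edges — the separation the classifier exploits.
- Patients split into subgroups (default 2) by a mean shift on a second edge
  set *disjoint* from the support, so subtype separation is tunable
  independently of the latent component. A consequence worth knowing: in the
  full pipeline, clustering runs on the PLSC-significant edge mask, which by
  construction excludes the subgroup edges, so pipeline-level subtype
  recovery is near chance; subtype recovery is demonstrated at the operation
  level on features that include the subgroup contrast.
- Treatment improvements are linear in the edge features,
  `X w + noise`, with `w` the normalized sum of `u*` and the first subgroup
  contrast — so improvements track both overall burden and subgroup
  membership, mirroring cohorts where the more affected subgroup improves
  more under treatment.
- Motion traces are Gaussian-smoothed drift (default 0.02 mm) plus optional
  10-frame high-motion bursts; a 2 mm burst amplitude pushes mean FD past
  the 0.2 mm exclusion threshold at 200 frames.

All randomness flows from one integer seed through named, counter-based
streams (crc32 of the stream name spawns a child of the master
SeedSequence), so each stage's draws are independent of call order and the
reproducibility contract — same spec + seed ⇒ byte-identical outputs — holds
per stage.

What the generator does **not** emulate: spatial autocorrelation of edge
noise, site/scanner effects, non-Gaussian questionnaire distributions
(bounded, skewed scores), missing data, or any volumetric/physiological
structure. Passing tests therefore certify the statistical machinery —
calibration, recovery, error control under the stated model — not
performance on real fMRI cohorts. The clinical measures are modelled as
Gaussian; that is an implementation choice, not an inference about real
questionnaire data.

## Problem sizes

Recovery and calibration suites run at deliberately reduced dimensionality,
chosen from signal-to-noise theory rather than trial and error: the planted
rank-1 component is recoverable only while its singular value dominates the
noise edge of the 9 × m cross-correlation matrix (which grows like
(√m + 3)/√n). At latent effect 3 with n = 80 and a 50-edge support this
holds comfortably at 12 regions (66 edges) — where |corr(û, u*)| ≥ 0.9
across seeds — and fails by an order of magnitude at the full 246-region
scale, where only shape/count identities are exercised. Calibration uses 200
null cohorts × 200 permutations at n = 40; the acceptance script's full run
takes about a minute on one CPU.

## Known limitations

- Permutation and bootstrap refits are serial Python loops over SVDs; at
  the full 30,135-edge scale with 1000 resamples a run takes minutes, and
  no parallelism is attempted.
- The elbow criterion (max second difference of inertia) is one of several
  reasonable operationalizations and can be unstable when the inertia curve
  is nearly linear; the silhouette and the weak-structure flag should be
  read together with it.
- Receptor correlations lack spin-test nulls (above); on real parcellated
  maps the reported p-values are anti-conservative.
- `validate_inputs` checks schema-level properties (shape, symmetry,
  finiteness, column contract), not scientific plausibility.
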
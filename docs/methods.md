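# Methods

This document describes the statistical model implemented by `abtau`, the
assumptions behind it, the synthetic cohort generator used to exercise it,
and the numerical choices made along the way.

## 1. Data model

A study is a set of subjects, each carrying per-vertex surface overlays:

- **amyloid PET SUVR** (`abeta`), one value per vertex;
- **tau PET SUVR** (`tau`), one value per vertex;
- **cortical thickness** (`thickness`), in mm, defined on gray vertices.

The surface geometry labels every vertex with a tissue class (`gray`,
`white`, `meninges`, or `excluded`), a hemisphere, and — for gray vertices —
a parcel of a Desikan-Killiany-style atlas (34 regions per hemisphere, 68
total). Subjects carry age, sex, intracranial volume (ICV), diagnosis
(HC/MCI), and cohort (`young` normative reference or `old` study cohort).

SUVR values are assumed already normalized to a cerebellar gray reference;
`compute_suvr` is provided for dividing raw uptake by a reference mean.

## 2. Composites

Three composite SUVRs summarize each subject (unweighted mean of the pooled
regional means; regions missing from a geometry are skipped unless strict
resolution is requested):

- **global amyloid**: frontal, parietal, lateral-temporal, cingulate and
  precuneus regions;
- **global tau**: fusiform, parahippocampal, entorhinal, inferior and middle
  temporal regions (plus amygdala when the parcellation has one — cortical
  surface parcellations usually do not);
- **MTL tau**: entorhinal + parahippocampal, a sensitive early-abnormality
  composite.

## 3. Normative cut-points

For each composite a normal distribution is fitted to the young cohort
(sample mean and SD with `ddof=1`; a Shapiro-Wilk check warns if normality
is doubtful). The abnormality cut-point is the 96th percentile of that
normal:

    cut = mu + z(0.96) * sigma,   z(0.96) = 1.750686

The degenerate `sigma = 0` case returns `mu`. A subject is amyloid-abnormal
iff global amyloid is **strictly** greater than its cut; tau-abnormal iff
global tau *or* MTL tau strictly exceeds its cut. Crossing the two flags
yields the four groups `nAb/nTau`, `aAb/nTau`, `nAb/aTau`, `aAb/aTau`.

Published cut-points (1.256 / 1.150 / 1.110) are shipped as
`PUBLISHED_CUTPOINTS` for reference, but note they are *not* reproducible
from the published young moments via the formula above (1.11 + 1.750686 ×
0.06 = 1.215, not 1.256); derived cut-points are therefore the default
throughout the pipeline, and the published constants are provided for
users who want to reproduce the published thresholds verbatim.

## 4. Partial-volume correction (PVC)

Gray-matter PET signal is contaminated by spill-in from adjacent
non-specific-binding tissue (white matter, meninges). The correction:

1. **Spill-in synthesis.** A truncated Gaussian kernel (σ = FWHM/2.3548,
   default FWHM 6 mm, support cut at 3.5 σ) propagates source-vertex
   activity to gray vertices. Kernel columns are normalized per source over
   all live (non-excluded) vertices, so each source's activity is conserved
   and the synthesis is linear.
2. **Model fit.** On the young cohort — whose gray signal is assumed to be
   spill-in only — a per-gray-vertex simple regression of observed gray
   uptake on synthesized spill-in yields an intercept and slope per vertex.
   Vertices with (numerically) constant regressors are flagged degenerate
   and fall back to the mean observed uptake.
3. **Correction.** For any subject, the model's prediction from that
   subject's own source field is subtracted from the gray uptake. Negative
   corrected values are retained by default (clamping at zero is optional)
   so that downstream statistics stay unbiased.

## 5. Group-level analyses

All models code sex as M=0, F=1 and control age, sex, and ICV.

- **Probabilistic atlases**: per group and modality, the per-vertex fraction
  of subjects whose SUVR strictly exceeds the global cut-point.
- **Cross-correlograms**: per group, the region-by-region Pearson (or
  Spearman) correlation matrix between amyloid and tau regional SUVRs
  across subjects.
- **Model 1 (vertex-wise)**: `thickness ~ global_abeta + global_tau + age +
  sex + icv`, fitted by batched OLS across vertices; two-sided p-values
  from t(n−k); Benjamini-Hochberg FDR at q = 0.05 across gray vertices
  (degenerate vertices are excluded from the multiplicity count and never
  flagged).
- **Model 2 (regional, two-step)**: regional thickness is residualized on
  the other modality's regional SUVR plus covariates, then regressed on the
  target regional SUVR. Family-wise error control uses an empirical null
  built by permuting the regressor (`n_perm` = 10,000 by default), fitting
  a normal to the null t sample and thresholding at its 5th/95th
  percentiles (a stricter 2.5/97.5 option exists; exhaustive enumeration is
  available for tiny n).
- **Resonance (model 3)**: per subject, the Pearson correlation between the
  amyloid and tau gray-vertex maps. The vertex-wise resonance model adds
  this score to model 1's covariate set (controlling both global burdens),
  isolating the joint spatial-overlap effect.

A summary report reduces each vertex map to a dominant direction (`+`, `-`,
`0`): a sign is called only if the FDR-surviving vertices of that sign
number at least 0.5% of gray vertices and outnumber the opposite sign.

## 6. Synthetic cohort generator

The generator's defaults *are* the study conditions: 97 young amyloid and
47 young tau subjects, 200 subjects per old group, a 64 × 64 gray grid
(4,096 vertices, 1.5 mm spacing) with the 68 parcels laid out in row bands.

**Geometry.** The gray patch is sandwiched between a white-matter sheet
2 mm below and a meningeal sheet 2 mm above. Both sheets extend 6 cells
(9 mm) beyond the patch rim — more than the 3.5 σ kernel reach — so edge
and interior gray vertices receive comparable spill-in.

**Young subjects** have *no* specific binding: gray uptake is spill-in from
their (randomly modulated) source sheets plus i.i.d. measurement noise,
scaled so composite SUVRs follow the configured normals (amyloid
N(1.11, 0.06²), tau N(0.90, 0.10²)).

**Flattened spill shape.** The deterministic unit-source spill field is
divided out of every synthesized spill pattern (and the result rescaled by
its mean), making the *expected* spill flat across gray. Without this, one
shared anatomical pattern would appear in every subject's amyloid and tau
maps and dominate the resonance score in all groups. The per-vertex
rescaling is exactly what the per-vertex PVC regression absorbs.

**Old groups.** Composite targets are drawn from the configured group
normals, truncated at cut-points estimated from the generated young sample
itself (its mean + 1.750686 × SD) so that generator-side group membership
agrees with the cut-points the analysis later derives from the same young
cohort. A margin of 0.05 SUVR around each cut is excluded, keeping
membership robust to cut-point estimation drift and composite observation
noise. In tau-abnormal groups whose global tau lands near its cut, MTL tau
is drawn clearly above its cut instead (abnormality via the MTL composite).
In `aAb/aTau` only, the amyloid and tau targets are coupled through a
Gaussian copula (ρ = 0.7), which makes that group's cross-correlogram
strongly positive while the others stay near zero.

**Spatial patterns.** Specific binding is seeded on smoothed parcel
indicators: amyloid on the amyloid-composite parcels, tau on the temporal/
medial-temporal parcels — disjoint enough that resonance is low — except in
`aAb/aTau`, where both pathologies cover the whole cortex (tau's pattern is
a random rotation of the full-cortex pattern up to 60°), giving high
positive resonance in that group only.

**Thickness** is a smooth base field (2.5 mm ± 0.1 mm spatial variation)
plus covariate effects (−0.01 mm/yr age, −0.05 mm female, 2 × 10⁻⁷ mm/mm³
ICV) plus regime effects keyed to the *generating* group: +1.0 mm per SUVR
of (group-centered) amyloid on the amyloid territory in amyloid-normal
groups; +1.0 mm per SUVR of tau on the tau territory in tau-normal groups;
−0.6 in tau-abnormal groups; and −1.5 mm per unit of (group-centered)
resonance, cortex-wide, in `aAb/aTau` only; plus N(0, 0.15²) noise, clamped
at zero.

## 7. Numerical choices

- OLS via the normal equations with an explicit rank check (QR-based
  naming of collinear columns); batch fits share one `(XᵀX)⁻¹`.
- Exact-fit responses (zero residual variance) are flagged rather than
  producing spurious infinite t-values silently.
- Permutations are drawn as `argsort` of uniform draws, vectorized over the
  whole permutation block; the fitted-normal threshold convention follows
  the two-step procedure described above.
- Spill-in kernels are built with a KD-tree ball query and stored sparse;
  synthesis is a sparse matrix-vector product.
- File formats round-trip float64 bit-exactly (`%.17g` on write,
  round-trip float parsing on read). FreeSurfer MGH and GIFTI overlay
  readers are provided via nibabel.
- All randomness flows from explicit seeds; the pipeline splits one root
  seed per stage, so any stage can be re-run from cached files and
  reproduce the full-run outputs.

## 8. Limitations

- The surface is a flat grid, not a folded cortical mesh; geodesic and
  Euclidean distances coincide here but would not on real anatomy.
- The PSF is an isotropic, spatially invariant Gaussian; real scanners
  vary across the field of view.
- Young and old cohorts are assumed to share scanner characteristics and
  the spill-in model transfers across age groups unchanged.
- Group composite distributions are truncated normals by construction;
  heavy upper tails (notably aAb/aTau tau) are approximated, not modeled.
- The thickness model is linear in its predictors with regime switches at
  the group level; threshold or saturating dose-response shapes are out of
  scope.
- The regional FWE convention (normal fitted to the permutation null,
  5th/95th percentiles) spends ~5% per tail; users wanting a strict
  two-sided 5% family-wise level should pass `percentiles=(2.5, 97.5)`.
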
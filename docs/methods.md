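# Methods

This note documents the models, conventions and numerical choices
behind `neurodrain`, and what the synthetic validation does and does
not establish.

## Inputs and geometry

The pipeline consumes two co-registered 3-D probability volumes per
scan (ICH and drain, values in [0, 1], NIfTI) and, for evaluation,
binary ground-truth masks.  Clinical CT voxels are strongly anisotropic
(in-plane ~0.4–0.5 mm, slice spacing up to 5 mm), so all geometry —
distances, moment tensors, profile positions — is computed in world
millimetres through the NIfTI affine.  Inputs are first resampled to a
1-mm isotropic working grid (trilinear for probabilities, nearest for
masks); quantification internally regrids to 0.5 mm.  Resampling is
implemented as separable 1-D linear interpolation anchored at voxel
(0,0,0), which preserves the field of view to within one voxel and
leaves constant volumes exactly constant.

## Detection

The drain map is binarized at a baseline threshold of 0.5 (inclusive
`>=`; inclusivity keeps the 0.99 end of the sweep usable when
segmentations saturate near 0.99).  Its 26-connected components form a
fixed object universe; 26-connectivity is chosen because thin oblique
drains fragment under 6-connectivity at 1 mm.  Each object is labeled
*drain* if it shares at least one voxel with the GT drain mask, else
*noise*.  An object is *retained* at threshold *t* iff its maximum
probability ≥ *t*; this per-baseline-object rule keeps the accuracy
denominator fixed across the sweep even when an object would split at a
higher threshold.  No minimum-size filter is applied.  When two GT
drains map onto one component (touching drains) the component is
flagged rather than split — a documented failure mode of the method.
Proportions carry exact Clopper–Pearson 95% intervals.

## Coverage quantification

**Volume of touch.**  A drain voxel belongs to V iff its nearest
non-drain voxel (Euclidean, world mm) lies in the ICH.  This is
computed with a single Euclidean feature transform over the non-drain
set.  Voxels claimed by both masks count as drain ("drain wins"), since
V is defined over drain voxels.  Equidistant ties between an ICH and a
background site are resolved by the feature transform's deterministic
nearest-site assignment; they are a measure-zero set and are excluded
from the oracle comparison in the tests.  The ICH map is binarized at
0.5 for quantification; the drain mask used for quantification is the
component of the 0.44-threshold mask that contains the 0.9-detected
object, which grows the detected drain to a stable extent without
resurrecting noise.

**Frame and profile.**  Drain and V masks are regridded to 0.5-mm
isotropic voxels and Gaussian-smoothed with FWHM 1.0 mm
(σ ≈ 0.4247 mm) — "smoothing to 1-mm voxels" is interpreted as 1-mm
effective resolution.  The profile axis is the leading eigenvector of
the smoothed V's second central moment tensor; when V has fewer than 10
voxels on the 0.5-mm grid (a contact-free or barely touching drain) the
drain's own tensor is used instead so a near-zero profile is still
produced for classification.  Smoothed masses (not binary counts) are
ratioed per 0.5-mm slab: value = ΣV-weight / Σdrain-weight, zero where
the drain mass is < 1e-6, clipped to [0, 1].  Because smoothing is
linear and V ⊆ drain, the ratio never exceeds 1 before clipping.  Slabs
are centered on the 0.5-mm sample positions so that grid points never
sit exactly on a bin edge; this makes the profile exactly invariant
under world translation and axis-permutation rotations.  The profile
spans the full drain extent, not only V's extent, so zero-contact
segments appear as zeros.

**Tip rule.**  The two extreme 0.5-mm end slabs along the axis are
candidate ends; each candidate point is the slab's support centroid
(which lands on the drain axis rather than a rim voxel).  The tip is
the candidate farther from the nearest face of the image volume —
drains enter the head near the volume surface, so the deep end is the
tip.  Near-ties (< 0.5 mm) are broken toward the larger axis coordinate
with a warning; an explicit override point always wins.  On phantoms
the located tip falls within 1 mm of the true tip.

**Features.**  The classifier consumes the profile linearly
interpolated at 0.5, 1.5, …, 14.5 mm from the tip (15 values).  Drains
shorter than 15 mm are zero-padded beyond their extent and flagged.

## Classification

Ridge-penalized logistic regression: minimize mean binomial deviance +
λ‖w‖² by Newton/IRLS (intercept unpenalized; converged when the
parameter step < 1e-8, at most 100 iterations; the penalized gradient
norm at the solution is < 1e-6).  Features are standardized with
training-set mean and SD (n−1 denominator; constant columns pass
through).  λ is tuned by leave-one-out cross-validation: 60 candidates
drawn log-uniformly from [1e-6, 10] with a seeded generator, each
scored by pooling the n held-out probabilities into one ROC-AUC; ties
break toward the larger λ (the simpler model).  With near-separable
synthetic features many candidates tie at AUC 1, so the tie rule
selects a strongly shrunk model whose probabilities compress toward the
class prevalence; ranking (AUC) is unaffected but accuracy at the 0.5
decision threshold can trail it.  The default penalty is the
pre-selected λ = 6.619512e-04.  With string labels, the positive
(detected) class is "not correct" — malposition detection; reports
state the orientation explicitly.

## Agreement statistics

ICC(2,1): absolute agreement, single measure, from two-way
random-effects ANOVA mean squares, with the Shrout–Fleiss F-based 95%
interval (Satterthwaite df; the exact-agreement limit MSE → 0 uses
df = k − 1).  Zero between-subject variance returns 0 with a warning.
Bland–Altman: bias = mean(x−y), limits of agreement bias ± 1.96·SD
(n−1); a pair is an outlier when it falls outside the limits of
agreement, the convention that yields the expected ≈ 5% rate under
normal differences.  Fleiss' κ uses the standard category-proportion
formula and is undefined (error) when all ratings coincide.  ROC-AUC is
the Mann–Whitney statistic with ties counted ½; its CI is DeLong's
(cross-checked against R pROC).  Exact binomial intervals use the beta
quantile (Clopper–Pearson) form.

## Phantoms

A phantom is a cylindrical drain (default radius 1.5 mm — the caliber
of a typical drainage catheter — length 40 mm) entering a 48×48×64 mm
grid at 1-mm voxels through one face, with the hemorrhage modeled as a
half-space whose boundary is orthogonal to the drain at an *embedded
fraction* f of its length from the tip (ellipsoidal and absent-ICH
variants cover the fully-embedded and disjoint cases).  Probability
maps are the rasterized masks blurred with σ = 0.5 mm plus clipped
additive Gaussian noise (SD 0.02); distractor blobs of chosen amplitude
emulate bone fragments and calcifications in the drain map.  The drain
axis passes through voxel centers so that a blurred radius-1.5-mm drain
keeps core probabilities ≈ 1, matching the saturated maps a trained
segmentation network produces.  The analytic truth profile is a step:
1 on the embedded segment, 0 beyond.  Synthetic position labels follow
a transparent rule — "correct" iff mean analytic coverage over the
distal 15 mm ≥ 0.5 — which is *not* claimed to reproduce radiologists'
judgment.

What the phantoms do not emulate: curved drains, CT texture, skull and
ventricles, partial-volume anisotropy of real acquisitions, and
inter-rater ambiguity of borderline positions.  Passing the synthetic
benchmarks therefore validates the geometry and statistics of the
implementation, not clinical performance.

## Validation problem sizes

The reproduction script and acceptance tests use: 50 random grids
(≤ 20³, anisotropic) for the touch-volume oracle; one phantom per
coverage geometry; 100 distractor phantoms (300 objects) for the
detection sweep; 200 training / 100 test phantoms with f ~ U[0, 1] for
the classifier; 10⁴ simulated pairs for the Bland–Altman outlier rate.
All randomness derives from the script's `--seed`.

## Known limitations

- Straight-axis projection only; a strongly curved drain foreshortens.
- Touching drains form one object (flagged, not split).
- The tip rule assumes the entry end is nearer the volume surface; an
  override point is accepted where that fails.
- The probability-to-mask conventions (baseline 0.5, detection 0.9,
  quantification 0.44, ICH 0.5) are fixed defaults; sweeps are provided
  for the detection threshold only.
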
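# neurodrain

Quantitative evaluation of drain position after minimally invasive
surgery (MIS) for intracerebral hemorrhage (ICH), from CT segmentation
probability maps.

After a drain is placed into a supratentorial hematoma, follow-up CT is
read to decide whether the catheter tip actually sits in the bleeding.
That reading is subjective; `neurodrain` turns it into numbers.  Given
two co-registered probability volumes per scan — per-voxel probability
of ICH and of drain, from any voxelwise segmentation model — the
package:

1. **Detects** drains as discrete 26-connected objects.  The object
   universe is defined at a baseline probability threshold of 0.5; an
   object is retained at a stricter threshold *t* iff its maximum
   probability ≥ *t* (operating point *t* = 0.9), and retention
   accuracy can be swept over *t* ∈ [0.50, 0.99].
2. **Quantifies** each drain's contact with the hemorrhage.  The
   *volume of touch* V is the set of drain voxels whose spatially
   nearest non-drain voxel is ICH rather than background (computed with
   a Euclidean feature transform in world mm).  Drain and V are
   regridded to 0.5-mm isotropic voxels, Gaussian-smoothed to ~1-mm
   resolution, and projected onto the major eigenvector **e₁** of V's
   second-moment tensor.  The *coverage profile* is the slab-wise mass
   ratio V/drain in 0.5-mm slabs, reported as a function of distance
   from the drain tip.
3. **Classifies** the drain position ("correct" / "not correct") with a
   ridge-penalized logistic regression on the 15 coverage values in the
   distal 15 mm of the profile (where the drain openings are).  The L2
   penalty λ is tuned by leave-one-out cross-validation over a seeded
   random grid of 60 candidates maximizing pooled ROC-AUC; the default
   penalty is λ = 6.619512 × 10⁻⁴.

Agreement statistics used to validate each stage ship in
`neurodrain.metrics`: ICC(2,1) (two-way random effects, absolute
agreement, single measure, with F-based CI), Bland–Altman limits of
agreement with the ±1.96·SD outlier rule, Fleiss' κ, exact
Clopper–Pearson intervals for accuracy/sensitivity/specificity, and
Mann–Whitney ROC-AUC with a DeLong CI.  A phantom generator
(`neurodrain.phantom`) produces cylindrical drains and
half-space/ellipsoid hemorrhages with analytic truth profiles, so the
whole pipeline is testable without patient data.

## Worked example

```python
import numpy as np
from neurodrain import PhantomSpec, make_phantom, analyze_scan

# a 40-mm drain embedded 40% of its length in the hemorrhage
case = make_phantom(PhantomSpec(embedded_fraction=0.4, seed=7))
analysis = analyze_scan(case.drain_prob, case.ich_prob,
                        gt_drain=case.gt_drain)
drain = analysis.drains[0]
print(f"objects: {analysis.outcome.n_objects}, "
      f"max prob: {drain.max_prob:.2f}")
print("coverage at 5/20/35 mm from tip:",
      np.round(np.interp([5, 20, 35], drain.profile.positions,
                         drain.profile.values), 3))
print("distal 15-mm features:", np.round(drain.features.values, 2))
```

prints

```
objects: 1, max prob: 1.00
coverage at 5/20/35 mm from tip: [1. 0. 0.]
distal 15-mm features: [1. 1. 1. 1. 1. 1. 1. 1. 1. 1. 1. 1. 1. 1. 1.]
```

The single detected object is the drain (maximum probability 1.0).  Its
profile is ≈ 1 over the embedded distal 16 mm (0.4 × 40 mm) and ≈ 0
beyond, so all 15 distal features are 1 — a drain whose tip segment is
fully surrounded by the hematoma, i.e. correctly placed.

The same steps are exposed on the command line:

```sh
neurodrain phantom --out-dir case/
neurodrain detect --drain-prob case/drain_prob.nii.gz \
    --gt case/gt_drain.nii.gz --sweep --out report.json
neurodrain profile --drain-prob case/drain_prob.nii.gz \
    --ich-prob case/ich_prob.nii.gz --out profiles.csv
```

## Scope

The package consumes segmentation probability maps; it does not include
the CNN that produces them, DICOM conversion, registration, or any
reading-room tooling.  Profiles use a straight principal-axis
parameterization (no centerline extraction), and touching drains merge
into a single object — both documented limitations of the method.
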
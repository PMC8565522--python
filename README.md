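# callosum-topography

Connectivity-based parcellation of the corpus callosum (CC) and analysis of
its subregional aging, runnable entirely offline on synthetic tractography
phantoms with known ground truth.

The CC is the main commissure linking the two hemispheres, and its fibers are
not interchangeable: different sectors carry the interhemispheric traffic of
different functional systems, and they do not age at the same rate. This
package implements the full analysis chain a diffusion-MRI study of that
question needs — for methodologists who want every stage testable without
access to restricted MRI data:

1. **Streamline-to-network assignment.** A tractogram streamline is attributed
   to functional network *n* (of the 7- or 17-network resting-state atlas:
   VIS, SM, DA, VA, LN, FPN, DMN) iff both endpoints lie in 2-mm-dilated
   network-*n* cortical labels, in opposite hemispheres, and its voxel path
   crosses the CC mask.
2. **Probabilistic connection maps.** With FN(s,v,n) the number of accepted
   network-*n* streamlines of subject *s* through CC voxel *v* (each
   streamline counted once per voxel),

       P(s,v,n) = FN(s,v,n) / Σₙ FN(s,v,n),      P(v,n) = (1/S) Σₛ P(s,v,n).

   The **hard segmentation** labels each voxel argmaxₙ P(v,n), partitioning
   the CC into network-specific subregions; split-half reproducibility is
   scored with per-label Dice coefficients, 2|A∩B|/(|A|+|B|).
3. **Subregional scalars.** Connection probability P(s,n) = Σᵥ P(s,v,n)/V
   over the V template CC voxels, and probability-weighted diffusion indices

       DI(s,n) = Σᵥ w(v,n)·DI(s,v) / Σᵥ w(v,n),   over voxels with FA > 0.2,

   for FA, MD, RD, AD, residualized on TIV, sex and education.
4. **Aging trajectories.** Per subregion × index, a quadratic lifespan model
   DI = A·age + B·age² + C, with adjusted R² (p = 2 regressors) and the
   turning-point age −A/(2B) — the age of peak FA or minimum diffusivity.
5. **Group statistics.** ANCOVA-style comparison of P(s,n) across seven
   decade age groups (21–90 years) with Bonferroni-corrected post hocs, and
   paired between-subregion contrasts of the diffusion indices.

Because real tractograms and DTI volumes are not distributable, a first-class
synthetic module generates everything the pipeline consumes: a midsagittal CC
phantom crossed by homotopic bundles with network-specific crossing zones
(the ground truth the real study never has), cohort demographics, and
diffusion-index volumes drawn from the quadratic lifespan model with noise
calibrated to each trajectory's R² (σ² = Var_age[quadratic]·(1−R²)/R²).

## Worked example

```python
import numpy as np
from callosum import (make_phantom, make_cohort, make_tractogram,
                      dilate_labels, count_connections, normalize,
                      build_atlas, split_half)

phantom = make_phantom(7)                      # CC slab + 7 bilateral networks
cohort  = make_cohort(200, "table1", seed=0)   # decade-binned demographics
dilated = dilate_labels(phantom.network_labels, 2.0, phantom.grid.voxel_size)

maps = []
for i, sid in enumerate(cohort["id"]):
    tg   = make_tractogram(phantom, {n: 48 for n in range(1, 8)}, seed=i)
    cmap = count_connections(tg, phantom.cc_mask, dilated, phantom.grid,
                             k=7, subject_id=sid)
    maps.append(normalize(cmap))

atlas = build_atlas(maps, template_cc_mask=phantom.cc_mask)
res   = split_half(cohort, maps, seed=1, template_cc_mask=phantom.cc_mask)
print(res.report.weighted_mean)
```

The same study, with narrative output, is driven by the numbered scripts in
`analysis/` (each standalone and deterministic, writing tables to
`results/`). Running them prints, among other things:

```
atlas over S=200 subjects, V=408 template CC voxels
hard segmentation vs ground truth: weighted Dice 1.0000
split-half weighted Dice 1.0000 (unweighted 1.0000)
...
recovery at n=1086: worst |z| over 84 coefficients = 2.17
|R2 error|: median 0.0096, max 0.0347
...
FA: subregions ranked VIS > DA > DMN > VA > FPN > SM > LN
```

Read: the two matched half-cohorts produce identical hard segmentations
(the phantom's crossing topography is stable by construction, so Dice scores
the pipeline, not anatomy); refitting the quadratic trajectories on a
simulated reference-size cohort (n = 1086) recovers all 84 generative
coefficients within ~2 standard errors; and the posterior subregions (VIS,
DA) carry the highest FA, as their generative intercepts dictate.

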
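# tensorcut

Interactive (seeded) graph-cut segmentation for scalar medical images and
diffusion-tensor imaging (DTI) volumes, with a synthetic bilateral-lesion
phantom generator and utilities for two-group inference from published
summary statistics.

## The problem and who this is for

Delayed post-hypoxic encephalopathy (e.g. after severe carbon monoxide
poisoning) typically produces bilateral, roughly mirror-symmetric white-matter
lesions around the lateral ventricles. Delineating such lesions on DTI is
harder than on scalar maps because the quantity at each voxel is a symmetric
positive-definite (SPD) 3×3 diffusion tensor, not a number. This package is
for image-analysis researchers who want a small, exactly-solvable,
well-tested reference implementation of seeded graph-cut segmentation that
works identically on scalar images and on tensor fields.

## The model

A user marks a few voxels as target (set *O*) and background (set *B*);
everything else is unknown (*U*). A binary labeling *x* is scored by

    E(x) = α · Σᵢ Rᵢ(xᵢ)  +  (1 − α) · Σ_{(i,j)∈N, xᵢ≠xⱼ} W_ij ,   0 < α < 1

with four penalties inside the two sums:

* **Seeds (hard constraints).** For i ∈ O, Rᵢ(target) = 0 and
  Rᵢ(background) = K; mirrored for i ∈ B. K is resolved per instance so a
  seed flip can never be part of a minimum cut.
* **Unknown voxels (closest set).** Rᵢ(target) = Dᵢᴼ / (Dᵢᴼ + Dᵢᴮ) and
  Rᵢ(background) = Dᵢᴮ / (Dᵢᴼ + Dᵢᴮ), where the *effective distance*
  Dᵢˢ = (1/|S|) Σ_{s∈S} d(fᵢ, f_s) is the mean feature dissimilarity from
  voxel i to seed set S.
* **Boundary.** W_ij = exp(−d(fᵢ, fⱼ)² / 2σ²) across 8-neighbor pairs,
  charged only where labels disagree, so cuts through homogeneous tissue are
  maximally expensive.

For scalar images the feature distance d is |Pᵢ − Pⱼ|. For tensor fields it
is a pluggable SPD dissimilarity, by default the **log-Euclidean distance**
‖log Tᵢ − log Tⱼ‖_F — zero iff the tensors are equal and divergent as either
tensor approaches singularity. E(x) is minimized *exactly* by a minimum s/t
cut: t-link capacities are α·Rᵢ(·), n-links carry (1 − α)·W_ij, and the cut
value equals the energy of the induced labeling.

The statistics module re-derives the unsigned two-sample t statistic
t = |m₁ − m₂| / √(s₁²/n + s₂²/n) from mean ± SD summary cells (with equal n
this coincides with the pooled-variance form) and Pearson's χ² for 2×2 count
tables; the three clinical comparison tables that motivated it ship as a TSV
fixture.

## Worked example

```python
import numpy as np
from tensorcut import (PhantomSpec, make_tensor_phantom, default_phantom_seeds,
                       segment_tensor, dice)

spec = PhantomSpec(noise=0.05, seed=3)          # 64×64 slice, two mirrored lesions
field, truth = make_tensor_phantom(spec)        # SPD tensors everywhere
result = segment_tensor(field, default_phantom_seeds(spec))
print(f"dice={dice(result.labeling, truth):.3f}",
      f"energy={result.energy:.3f}", f"flow={result.flow_value:.3f}",
      f"sigma={result.params.sigma:.4f}")
```

prints

```
dice=1.000 energy=375.743 flow=375.743 sigma=0.2144
```

Dice 1.000 means the recovered mask equals the ground truth exactly; energy
and flow agree because the min-cut value *is* the energy of the returned
labeling; σ is the data-adaptive boundary scale (mean neighbor dissimilarity,
here in log-tensor units).

The same pipelines are scriptable from the shell:

```bash
tensorcut phantom --out p/                     # phantom + seeds + ground truth
tensorcut segment-dti --in p/tensors.nii.gz --seeds p/seeds.nii.gz --out r/
tensorcut stats verify                         # re-derive the packaged tables
```

`r/` receives the 0/1 mask and an `audit.json` with the metric, α, σ, K, seed
counts, energy and flow value; re-running with the audited parameters
reproduces the labeling exactly.

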
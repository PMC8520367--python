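# Methods

## Segmentation energy

The package segments a 2D slice or 3D volume into target and background from
user seeds by exact minimization of the standard two-term seeded-cut energy

    E(x) = α · Σᵢ Rᵢ(xᵢ) + (1 − α) · Σ_{(i,j)∈N, xᵢ≠xⱼ} W_ij ,  α ∈ (0, 1).

Assumptions: the image is a single connected component of interest against
background (binary labeling only), seeds are trustworthy hard constraints,
and voxel features (intensities or diffusion tensors) are locally homogeneous
within each region relative to the between-region contrast.

The regional term comprises four penalties. Target seeds pay 0 to be target
and K to be background; background seeds are mirrored. Unknown voxels pay the
normalized effective distance D/(Dᴼ + Dᴮ), where Dᵢˢ is the *mean* feature
dissimilarity from voxel i to every seed in S — so a voxel is pushed toward
whichever seed set it resembles more, with the two penalties summing to one.
When both distances vanish (e.g. a perfectly uniform image) both penalties
are 0.5: no information, symmetric prior. The boundary term
W_ij = exp(−d²/2σ²) is charged only across label discontinuities, making
cuts through homogeneous tissue expensive and cuts along feature edges cheap.

Which sum α multiplies is a convention; here α scales the regional term
(α = 0.5 by default, balancing the two). Neighborhoods are the 8-neighborhood
in 2D; 3D volumes are processed slice-wise with the in-plane 8-neighborhood
by default, with an opt-in 6-neighborhood full-3D mode.

## Tensor dissimilarity

Diffusion tensors live on the SPD manifold, so plain Euclidean differences
understate contrast near the boundary of the cone. The default dissimilarity
is the log-Euclidean distance d(A, B) = ‖log A − log B‖_F: a true metric,
zero iff A = B, invariant under simultaneous rotation, and divergent as
either tensor approaches singularity. It is a pluggable strategy —
`frobenius` (‖A − B‖_F) and `affine_invariant`
(‖log(A^{−1/2} B A^{−1/2})‖_F) can be swapped in by name, and the chosen
name is recorded in every audit. The log-Euclidean default was chosen over
affine-invariant because it admits a flat embedding (matrix logs compared by
Frobenius norm), which makes whole-field distance computations vectorizable;
on commuting tensors the two coincide.

Tensors are stored as 6 lower-triangular components
(Dxx, Dxy, Dyy, Dxz, Dyz, Dzz), the common NIfTI convention. SPD validation
uses a strict eigenvalue tolerance of 1e-10; invalid tensors are rejected
(or masked out with a logged count when reading files), never silently
repaired.

## Parameters

| parameter | default | meaning |
|---|---|---|
| α | 0.5 | regional-vs-boundary trade-off, open interval (0, 1) |
| σ | data-adaptive | boundary kernel scale; mean neighbor dissimilarity over the image (fallback 1.0 when that mean is 0), in the feature's units (intensity or log-tensor) |
| K | per instance | hard-constraint weight; (1 + (1 − α)·max incident boundary-weight sum)/α |
| metric | log_euclidean | tensor dissimilarity strategy |
| SPD tol | 1e-10 | smallest admissible tensor eigenvalue |

The data-adaptive σ exists because no single scale suits both raw
intensities (contrasts of ~100) and log-tensor units (contrasts of ~1); the
mean neighbor dissimilarity puts the Gaussian kernel's knee at the image's
own typical contrast.

K deserves a note: since t-links carry α·R and n-links (1 − α)·W, the seed
guarantee needs α·K to exceed the largest incident n-link sum. Defining
K = (1 + (1 − α)·max incident sum)/α makes the effective t-link capacity
α·K = 1 + (1 − α)·max sum, strictly larger than any alternative cut around a
seed, so seeds provably keep their labels; the simpler
K = 1 + (1 − α)·max sum fails this once scaled by α ≤ 0.5.

## Exact optimization

The s/t graph has one node per in-mask voxel plus two terminals. The cut
capacity equals E(x) of the induced labeling term by term, so the minimum
cut is the global optimum over seed-consistent labelings. The solver is an
iterative Dinic's algorithm (BFS level phases + blocking flows with a
current-arc DFS) written directly against float capacities: termination does
not require integer capacities, and residuals ≤ 1e-12 are treated as
saturated. Among multiple minimum cuts the tie-break is deterministic:
nodes reachable from s in the final residual network are labeled target.
Every segmentation run recomputes E(x) from the labeling and checks it
against the flow value at relative 1e-6; a mismatch aborts the run.

Two independent oracles guard the solver: an exhaustive min-cut enumeration
(all 2^n source-side sets, vectorized, refused above 20 nodes) and an
exhaustive energy enumeration over all 2^|U| seed-consistent labelings
(refused above 12 unknowns). Problem sizes in the test and acceptance runs —
100 random graphs of ≤ 12 nodes, 50 random seeded instances of ≤ 12 unknowns,
and 64×64 phantom slices — were chosen so both oracles stay exact while the
whole suite runs in well under a minute per check.

## Synthetic phantom

The phantom emulates the bilateral symmetric periventricular lesion geometry
seen in delayed post-hypoxic encephalopathy: two ellipses mirrored exactly
about the midline column of a 64×64 axial slice (semi-axes 5 rows × 8
columns). Background tensors are isotropic diag(1,1,1)·10⁻³ mm²/s; lesion
tensors are anisotropic diag(1.8,0.6,0.6)·10⁻³ with the principal axis along
x, giving a log-Euclidean contrast of √(ln 1.8² + 2 ln 0.6²) ≈ 0.9313.

Noise is applied in log-tensor space: independent Gaussian perturbations
(SD 0.05 by default) of the 6 free matrix-log components, then the matrix
exponential. This guarantees SPD outputs at any noise level; adding noise to
raw components and clipping eigenvalues was rejected because clipping
distorts the noise distribution exactly where validity matters. The scalar
phantom is the same geometry with levels 0/1 and additive Gaussian noise.

What the phantom does *not* model: Rician acquisition noise on
diffusion-weighted images, partial-volume voxels, blurred lesion margins,
anatomical texture, or spatially correlated noise. Passing the phantom
recovery checks therefore demonstrates correctness of the energy model and
solver under the stated noise model, not clinical-grade robustness on real
DTI.

The default seeding protocol is deliberately minimal (one target seed per
lesion center, five fixed background positions): recovery from near-minimal
interaction is the harder test of the regional term.

## Summary-statistics module

The unsigned two-sample t statistic is computed as
|m₁ − m₂| / √(s₁²/n₁ + s₂²/n₂). With equal group sizes — the only case in
the packaged tables (n = 36 per arm) — this is algebraically identical to
the pooled-variance two-sample t, so no pooled/Welch choice is needed.
Unsigned, because the source tables print positive t regardless of
direction. Pearson's χ² for 2×2 tables is computed from expected counts
without the Yates continuity correction (the continuity-corrected variant is
a different statistic; the uncorrected one matches the closed-form 2×2
identity used as the test oracle). Within-group before/after comparisons
would need the paired correlation, which summary tables do not carry; they
are out of scope. P-values are reported only as the printed bounds, not
recomputed.

The fixture preserves the source tables verbatim, including unit oddities
(ET-1 in µmol/L, NOS/iNOS on a ~0.03 U/L scale); two rows (CK-MB after,
hsCRP after) reproduce within ±0.001 but round to a different third decimal
than printed — consistent with rounding of the source's own intermediate
values.

## Numerical choices and degenerate inputs

* Effective distances with a singleton seed set reduce to the plain feature
  distance; empty seed sets are a configuration error, surfaced before any
  graph is built.
* A fully seeded image needs no effective distances; the pipeline handles it
  uniformly (the cut then runs along the seed interface).
* Labelings violating seed constraints are legal inputs to the energy
  (scoring K per violation) so optimality probes can explore the full space.
* Ties D = Dᴼ = Dᴮ = 0 → both penalties 0.5. Uniform images → σ fallback 1.0
  (the boundary weights are all 1 regardless of σ in that case).
* Flow-graph text dumps stringify node ids; reloading yields string ids with
  identical cut values, which is sufficient for oracle replay and debugging.

## Known limitations

Binary labels only (no multi-label expansion moves); no automatic seed
proposal; no tensor estimation from raw diffusion-weighted data; slice-wise
default in 3D means out-of-plane boundary coherence is only enforced in the
opt-in full-3D mode; the affine-invariant metric has no flat embedding and
is quadratic-cost on large fields, so it is intended for small problems and
cross-checks.
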
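# Methods

## Model

Pathology spread is modelled as a linear, first-order diffusion process on a
region-level structural brain graph. With symmetric non-negative
connectivity *C* (zero diagonal) over an atlas of *N* regions, the
degree-normalized graph Laplacian is

    H = I − D⁻¹C,   D = diag(d),   d_i = Σ_j c_ij ,

and the model is dx/dt = −βHx with closed-form solution
x(t) = exp(−βHt)·x₀. Degree normalization makes each row of H sum to zero,
so the all-ones vector is a stationary right eigenvector and diffusion from
any seed relaxes toward a spatially flat pattern on a connected graph. The
one-sided normalization does **not** conserve total pathology mass;
trajectories are deliberately not renormalized, since only the correlation
with atrophy (scale-free) is ever used.

For a non-symmetric (directional) connectome C^dir, in/out degrees differ
(d_row = row sums, d_col = column sums) and the directional Laplacian is

    H^dir = I − diag(g)⁻¹ C^dir,   g_i = √(d_row,i · d_col,i).

Where d_row,i = 0 or d_col,i = 0 the scale is set to g_i = 1: this avoids
division by zero, leaves an all-zero row inert (identity row of H), and is
otherwise a no-op on realistic connectomes, where every region carries
weight in both directions.

### Directional connectome construction

Tracer experiments give a directed matrix over (typically finer) tracer
regions plus injection-region voxel counts. The pipeline is:

1. **Projection density** — scale row *i* of the tracer matrix by the voxel
   count of injection region *i*.
2. **Homolog aggregation** — sum directed density over the tracer regions
   assigned to each atlas region by a many-to-one homolog map. Pairs where
   either region has no tracer homolog are flagged unavailable.
3. **Anterograde ratio** — r_ij = M_ij/(M_ij + M_ji) on available pairs
   with mass; r = 0.5 (flagged "defaulted") for unavailable or all-zero
   pairs, so no directionality is imputed where none was measured.
4. **Edge split** — C^ant_ij = r_ij·c_ij and C^ret_ij = (1−r_ij)·c_ij.

Because r_ij + r_ji = 1 wherever defined (and exactly 1 by construction for
defaulted pairs), the split conserves connection mass:
C^ant + (C^ant)ᵀ = C, and C^ret = (C^ant)ᵀ. The retrograde mode is defined
as the complementary ratio — the only self-consistent reading once
conservation is required. Ratios are per directed edge, not per region, so
the two modes genuinely reorder seeds rather than merely rescaling the
matrix. The per-edge directionality index (C_ij − C_ji)/(C_ij + C_ji)
equals 2r − 1 on edges carried by C, an identity the tests assert.

The connectome is ACS-normalized by a single scalar (the grand total of the
matrix), which leaves relative weights untouched; any global scale is
absorbed by β·t in the diffusion anyway. Normalization and region removal
are separate composable operations, so either order is available; the
bundled pipeline normalizes at construction and does not renormalize after
removal, since the difference is a pure rescaling of model time. The same
argument is why the directional split is not re-normalized.

### Atrophy vector

Per subject, regional volumes are divided by intracranial volume (ICV).
Per region, a pooled-variance two-sample t-statistic is computed with the
sign convention t = (mean controls − mean patients)/SE, so **atrophy is
positive**; this convention flips every downstream correlation and is fixed
package-wide. (A Welch option exists; two-tailedness affects only p-values,
and the signed statistic itself is what the model is correlated against.)
The t-vector is mapped to (0,1) by the logistic
v = 1/(1 + exp(−slope·(t − midpoint))).

`compute_atrophy` z-scores the t-vector across regions before the logistic
(switchable). Rationale: t magnitudes scale with cohort size and inversely
with measurement noise, so any fixed slope saturates the transform for
well-powered cohorts — mapping nearly all regions to ≈1 and erasing exactly
the regional contrast the vector must carry — while standardization makes
the transform scale-free with the same fixed slope. `logistic_transform`
itself applies slope/midpoint (defaults 1 and 0) to whatever it is given.

### Scoring and epicenter inference

An R–t curve is the Pearson correlation across all regions (seed regions
included — their inclusion is what pins the t = 0 correlation to a value
independent of the connectome) between x(t) and the atrophy vector at each
grid time. Constant trajectory columns (reachable at numerical steady
state) yield an undefined correlation recorded as missing, never as 0;
peak-finding skips missing values, breaks ties toward the earliest time,
and flags a peak as *interior* when it is at neither end of the grid — the
signature of genuine spread (the model first approaches, then overshoots,
the data).

Repeated seeding evolves the model from every bilateral pair (unit mass in
both homologs; N/2 runs) and ranks pairs by R_max. The implementation
computes the diffusion kernel once per time point and reads each pair's
trajectory off the kernel's columns, which is algebraically identical to
per-seed evolution (asserted by tests) and makes an 84-region, 42-seed,
100-time search take milliseconds. A model-free check correlates mean seed
connectivity (bilaterally averaged to pair level) with pair-level atrophy.

### Permutation nulls

* **Connectome scramble** — C ↦ PCPᵀ for a uniform random permutation P,
  preserving edge and degree statistics. The seed is defined by atlas
  position and *not* permuted: permuting it along with the network is a
  pure relabeling that reproduces the observed curve exactly (a control
  experiment the tests run). Consequently all scrambles share the observed
  t = 0 correlation, which is a hard lower limit on every null R_max.
* **Atrophy scramble** — atrophy values randomly reassigned across regions,
  connectome untouched.

Empirical p-value: (1 + #{null R_max ≥ observed})/(1 + n permutations), the
add-one estimator (never exactly zero). Under exchangeable (pure-noise)
atrophy this p is uniform up to lattice discreteness, which the acceptance
suite verifies by KS test.

## Parameters

| parameter | default | meaning |
|---|---|---|
| β | 0.15 | global diffusivity (inverse model-time units) |
| time grid | 100 points on [0, 50] | model times; unitless, only β·t matters |
| logistic slope / midpoint | 1 / 0 | transform of the (standardized) t-vector |
| n_permutations | 2000 | null-distribution size (tests/acceptance use 200) |

β and the grid are chosen so that typical peak times of slow tauopathy-like
spread fall well inside the grid; evolve(H, x₀, β, t) ≡ evolve(H, x₀, 1, βt)
exactly, so the pair (β, t_max) is one effective parameter. Neither β nor t
is fitted to data — that requires longitudinal observations and is out of
scope.

## Numerics

The matrix exponential is evaluated through one eigendecomposition reused
across all grid times. For the nondirectional Laplacian the similarity
D^{1/2} H D^{−1/2} = I − D^{−1/2} C D^{−1/2} is symmetric, so a symmetric
eigendecomposition (orthogonal, perfectly conditioned) is used; for
directional Laplacians a general eigendecomposition is used when the
eigenvector basis is well conditioned (condition number < 1e8), otherwise
the code falls back to scaling-and-squaring `expm` per time point. The two
routes agree to ~1e-9 and both match adaptive ODE integration to <1e-8
(asserted). The kernel at t = 0 is the identity by definition and is set
exactly, pinning trajectory column 0 to the seed vector.

Degenerate inputs: all-zero connectomes are rejected by ACS normalization;
zero-degree regions are rejected by name for the nondirectional Laplacian
and handled by the g = 1 guard in the directional one; zero pooled variance
is rejected per region by the t-test; constant atrophy is rejected by the
curve computation.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* of the emulated study: a
bilaterally paired atlas (42 pairs, 9 of them subcortical — 18 subcortical
regions; 43 pairs for the 86-region variant whose last pair stands in for
the cerebellum), a symmetric connectome with homotopic edges on every pair
and random ipsilateral/contralateral edges (cross-hemisphere weights
halved), a directed tracer bundle whose subcortical edges carry strong
anterograde bias (default ratio 0.9, oriented subcortex → cortex) while
cortico-cortical edges are near-symmetric, ~10% of regions left without
tracer homologs, and cohorts of 60 patients vs 150 controls whose group
difference is a forward-NDM pattern from a known bilateral seed (planted at
model time 15 by default) with log-normal ICV and additive volume noise at
10% of the planted signal's SD.

It does **not** emulate: spatial geometry (no distance-dependent
connectivity), realistic degree distributions or modularity of real
connectomes, covariate structure (age/sex), site effects, or segmentation
error correlated across regions. Passing tests therefore demonstrate the
correctness and statistical behavior of the *method* under its own model
assumptions, not performance on real imaging cohorts.

Volumes are in arbitrary units with log-normal ICV so that ICV correction
is non-trivial; the deficit is injected bilaterally symmetrically (the
model is seeded bilaterally and group atrophy is essentially bilateral).
At exactly zero noise the per-region t-statistic is 0/0 (no within-group
variance survives ICV correction); the noiseless ground-truth checks
therefore use the ICV-corrected group mean difference, which is exactly
proportional to the planted pattern.

## Problem sizes used by tests and the acceptance script

Unit tests run on 4–24-region networks; study-scale properties use the
native 84/86-region design with 100 grid points. Replicate counts: 50 for
epicenter recovery and null power (200 permutations), 200 replicates × 100
permutations for null calibration, 50 for the directional-advantage
property; the acceptance script uses 20 replicates and 200 permutations per
null. These sizes give stable Monte-Carlo estimates for the ≥80–90%
thresholds being checked.

## Known limitations

* Linear, time-invariant dynamics: no protein production/clearance terms,
  no network remodeling over disease course.
* Directionality is transferred from another species at edge level;
  unmapped edges silently carry the neutral ratio 0.5 (flagged, but still a
  modelling choice).
* β and t are not estimable from a single cross-sectional atrophy vector;
  only their product is meaningful.
* The nulls permute labels only; degree-preserving rewiring nulls are out
  of scope.
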
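# ndmkit

Network diffusion modelling of neurodegenerative pathology spread on brain
connectomes, with directional (anterograde/retrograde) connectome
construction, epicenter inference by repeated seeding, and permutation null
models.

## The problem

In tauopathies such as progressive supranuclear palsy (PSP), misfolded
protein pathology appears to propagate trans-neuronally along white-matter
connections, producing stereotyped regional atrophy patterns. The network
diffusion model (NDM) formalizes this as linear diffusion on the structural
connectome: for a region-level graph with symmetric connectivity matrix *C*,

    dx/dt = -β H x(t),        H = I - D⁻¹ C,   D = diag(row degrees),

where *x(t)* is the regional pathology burden, β a global diffusivity, and
*H* the degree-normalized graph Laplacian. The closed-form solution
*x(t) = e^(-βHt) x₀* propagates an initial seed pattern *x₀* through the
network; *e^(-βHt)* is the diffusion kernel.

Diffusion MRI cannot resolve fiber polarity, so dMRI connectomes are
undirected. ndmkit additionally builds *directional* connectomes by
transferring direction from axonal-tracer data (e.g. a mesoscale mouse
connectome): tracer regions are aggregated onto the human atlas through a
homolog map, each edge gets an anterograde ratio
r_ij = M_ij / (M_ij + M_ji) from the aggregated directed projection mass,
and the undirected edge weight is split as C^ant_ij = r_ij · c_ij (with
C^ret = (C^ant)ᵀ). The directional Laplacian is
H^ant = I - diag(√(d_row · d_col))⁻¹ C^ant.

Given an empirical atrophy vector — per-region two-sample t-statistics
between patient and control ICV-corrected volumes, squashed to (0,1) by a
logistic transform — the model is scored by the Pearson correlation *R(t)*
between *x(t)* and atrophy at every model time (an "R–t curve"). Seeding
every bilateral region pair in turn and ranking by the peak correlation
R_max "runs the model backwards" to infer the most likely disease
epicenter. Significance comes from two permutation nulls: symmetric
row/column scrambles of the connectome (seed held at its atlas position)
and random reassignment of atrophy values across regions.

Because cohort volumetry and normative connectomes of this kind are
access-controlled, the package ships a synthetic-data module that generates
structurally faithful stand-ins (bilaterally paired atlas, homotopic/
ipsilateral connectome, directed tracer bundle with homolog map, and
two-cohort volume tables with a planted diffusion deficit), so the entire
pipeline is testable offline.

## Worked example

```python
from ndmkit import (SyntheticSpec, gen_atlas, gen_connectome,
                    gen_cohort_volumes, compute_atrophy,
                    laplacian_nondirectional, DiffusionParams,
                    repeated_seeding, null_distribution, empirical_pvalue)

spec = SyntheticSpec(n_pairs=42, rng_seed=1)          # 84-region study
atlas = gen_atlas(spec)
conn = gen_connectome(atlas, spec)                    # ACS-normalized
cohort = gen_cohort_volumes(atlas, conn, "subcortical01_left",
                            beta=0.15, t_true=15.0, spec=spec)
atrophy = compute_atrophy(cohort.table, atlas)        # t-test + logistic
H = laplacian_nondirectional(conn)
ranking = repeated_seeding(H, atlas, atrophy, DiffusionParams())
print(ranking.table.head(5).to_string(index=False))

nd = null_distribution(conn, atrophy, "subcortical01_left",
                       DiffusionParams(), kind="atrophy_scramble",
                       n_permutations=200, rng_seed=1)
print("observed R_max = %.3f, null p = %.4g"
      % (nd.observed, empirical_pvalue(nd)))
```

Output:

```
         seed  pair_id    r_max     t_max  interior
subcortical01       33 0.953710 39.898990      True
subcortical08       40 0.665951 50.000000     False
subcortical03       35 0.332411 50.000000     False
   parietal05       17 0.222281 50.000000     False
  occipital08       30 0.155789 22.727273      True
observed R_max = 0.954, null p = 0.004975
```

The true planted seed pair (`subcortical01`) ranks first with an interior
peak (R_max = 0.954 at model time ≈ 40, inside the grid), the model-data
correspondence rises and falls as diffusion first matches and then
overshoots the empirical pattern, and the peak is far outside the
atrophy-scramble null (p ≈ 0.005 at 200 permutations, the smallest value
the add-one estimator can produce).

The same analysis runs from the shell:

```
ndmkit all --outdir results/ --seed 1 --n-permutations 200
ndmkit seedsearch --connectome C.csv --atlas atlas.csv \
    --atrophy a.csv --kind anterograde --ratio r.csv --out ranking.csv
```

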
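import numpy as np
import pytest

from ndmkit import (Connectome, DiffusionParams, SyntheticSpec, gen_atlas,
                    gen_cohort_volumes, gen_connectome)


@pytest.fixture
def small_spec():
    return SyntheticSpec(n_pairs=6, rng_seed=7)


@pytest.fixture
def small_atlas(small_spec):
    return gen_atlas(small_spec)


@pytest.fixture
def small_connectome(small_spec, small_atlas):
    return gen_connectome(small_atlas, small_spec)


@pytest.fixture
def params_coarse():
    # planting times used in tests (multiples of 2.5) fall on this grid
    return DiffusionParams.with_grid(beta=0.15, t_max=50.0, n_times=21)


def random_connectome(n: int, rng: np.random.Generator,
                      density: float = 0.5) -> Connectome:
    """Random connected symmetric connectome on a generic n-region atlas."""
    from ndmkit import RegionAtlas

    while True:
        W = np.triu(rng.random((n, n)) * (rng.random((n, n)) < density), k=1)
        W = W + W.T
        if _connected(W):
            break
    labels = tuple(f"r{i:02d}" for i in range(n))
    atlas = RegionAtlas(labels=labels,
                        hemisphere=tuple("left" if i % 2 == 0 else "right"
                                         for i in range(n)),
                        lobe=tuple("frontal" for _ in range(n)),
                        pair_id=tuple(i // 2 for i in range(n)))
    return Connectome(atlas=atlas, weights=W)


def _connected(W) -> bool:
    from scipy.sparse import csgraph, csr_matrix

    ncomp, _ = csgraph.connected_components(csr_matrix(W > 0), directed=False)
    return ncomp == 1


def planted_study(n_pairs: int, rng_seed: int, noise_sd: float,
                  t_true: float = 15.0, beta: float = 0.15):
    """Synthetic cohort with a planted bilateral subcortical seed; returns
    (atlas, connectome, cohort, true pair label)."""
    spec = SyntheticSpec(n_pairs=n_pairs, rng_seed=rng_seed, noise_sd=noise_sd)
    atlas = gen_atlas(spec)
    conn = gen_connectome(atlas, spec)
    seed_label = next(lab for lab, lb in zip(atlas.labels, atlas.lobe)
                      if lb == "subcortical")
    cohort = gen_cohort_volumes(atlas, conn, seed_label, beta, t_true, spec)
    true_pair = atlas.pair_label(atlas.pair_id[atlas.index(seed_label)])
    return atlas, conn, cohort, true_pair
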
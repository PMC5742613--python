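"""Synthetic study data: atlases, connectomes, tracer bundles and cohort
volume tables with a planted network-diffusion signal.

Real inputs of this kind (normative dMRI connectomes, access-controlled
patient volumetry, mesoscale tracer atlases) are not redistributable, so
this module generates structurally faithful stand-ins:

* a bilaterally paired atlas (default 42 pairs = 84 regions, ~18 of them
  subcortical, mirroring a Desikan-Killiany-style cerebrum);
* a symmetric non-negative connectome with strong homotopic (left-right)
  edges and random ipsilateral structure, ACS-normalized;
* a directed tracer-style connectome over finer "tracer" regions with a
  many-to-one homolog map onto the atlas, strong directionality on
  subcortical edges and near-symmetric cortico-cortical edges;
* two-cohort volume tables (default 60 patients vs 150 controls) whose
  group difference is a noisy forward-NDM pattern from a known seed, with
  log-normal intracranial volume so ICV correction is non-trivial.

All draws come from ``numpy.random.default_rng`` seeded from
``SyntheticSpec.rng_seed`` (one independent substream per generator), so
identical specs give byte-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import LOBES, RegionAtlas
from .connectome import (Connectome, LaplacianMatrix, laplacian_nondirectional,
                         normalize_acs, write_matrix_csv)
from .directionality import HomologMap
from .ndm import Propagator, seed_vector

_CORTICAL_LOBES = ("frontal", "parietal", "occipital", "temporal")
_CONNECT_RETRY_CAP = 20


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study.

    Defaults mirror the emulated study: 42 bilateral pairs (84 regions),
    9 subcortical pairs (18 regions), 60 patients vs 150 controls, strong
    anterograde bias on subcortical tracer edges, and volume noise at 10%
    of the planted signal's standard deviation.
    """

    n_pairs: int = 42
    homotopic_strength: float = 3.0
    ipsilateral_density: float = 0.35
    subcortical_fraction: float = 9 / 42
    directional_bias: float = 0.9
    noise_sd: float = 0.1
    n_patients: int = 60
    n_controls: int = 150
    rng_seed: int = 0
    unmapped_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be at least 2")
        if self.homotopic_strength <= 0:
            raise ValueError("homotopic_strength must be positive")
        if not (0 < self.ipsilateral_density <= 1):
            raise ValueError("ipsilateral_density must be in (0, 1]")
        if not (0 <= self.subcortical_fraction <= 1):
            raise ValueError("subcortical_fraction must be in [0, 1]")
        if not (0.5 < self.directional_bias <= 1):
            raise ValueError("directional_bias must be in (0.5, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("cohorts need at least 2 subjects each")
        if not (0 <= self.unmapped_fraction < 1):
            raise ValueError("unmapped_fraction must be in [0, 1)")


@dataclass(frozen=True)
class TracerBundle:
    """Directed tracer connectome with injection voxel counts and the
    homolog map onto the human-style atlas."""

    labels: tuple[str, ...]
    matrix: np.ndarray          # directed, non-negative, K x K
    voxels: np.ndarray          # injection-region voxel counts, length K
    homolog_map: HomologMap

    def to_csv(self, matrix_path, voxels_path, map_path) -> None:
        write_matrix_csv(matrix_path, self.matrix, self.labels)
        pd.DataFrame({"tracer_label": self.labels,
                      "voxels": self.voxels}).to_csv(voxels_path, index=False)
        self.homolog_map.to_csv(map_path)


@dataclass(frozen=True)
class CohortVolumes:
    """Per-subject regional volume table with the planted ground truth.

    ``table`` has one row per subject: subject_id, group (patient|control),
    icv, then one column per atlas region (arbitrary mm^3-like units).
    ``x_true`` is the planted per-region deficit pattern (bilaterally
    symmetric, before the ``scale`` factor).
    """

    table: pd.DataFrame
    atlas: RegionAtlas
    true_seed: str
    x_true: np.ndarray = field(compare=False)
    scale: float = np.nan
    beta: float = np.nan
    t_true: float = np.nan

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _rng(spec: SyntheticSpec, stage: int) -> np.random.Generator:
    # one independent, reproducible substream per generator stage
    return np.random.default_rng([stage, spec.rng_seed])


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def gen_atlas(spec: SyntheticSpec) -> RegionAtlas:
    """Bilaterally paired atlas of 2*n_pairs regions.

    round(subcortical_fraction * n_pairs) pairs are subcortical; cortical
    pairs cycle through the four cortical lobes.  Fully deterministic.
    """
    n_sub = int(round(spec.subcortical_fraction * spec.n_pairs))
    n_ctx = spec.n_pairs - n_sub
    labels, hemisphere, lobe, pair_id = [], [], [], []
    per_lobe: dict[str, int] = {lb: 0 for lb in LOBES}
    for pid in range(spec.n_pairs):
        lb = _CORTICAL_LOBES[pid % 4] if pid < n_ctx else "subcortical"
        per_lobe[lb] += 1
        stem = f"{lb}{per_lobe[lb]:02d}"
        for hemi in ("left", "right"):
            labels.append(f"{stem}_{hemi}")
            hemisphere.append(hemi)
            lobe.append(lb)
            pair_id.append(pid)
    return RegionAtlas(labels=tuple(labels), hemisphere=tuple(hemisphere),
                       lobe=tuple(lobe), pair_id=tuple(pair_id))


def gen_connectome(atlas: RegionAtlas, spec: SyntheticSpec) -> Connectome:
    """Symmetric non-negative connectome with homotopic edges on every pair
    and random ipsilateral/contralateral edges (cross-hemisphere weights
    halved), ACS-normalized.

    Redraws (up to a retry cap) if the sampled graph is disconnected.
    """
    rng = _rng(spec, 1)
    n = atlas.n_regions
    pairs = atlas.pairs()
    hemi = np.asarray(atlas.hemisphere)
    pid = np.asarray(atlas.pair_id)
    for _ in range(_CONNECT_RETRY_CAP):
        W = np.zeros((n, n))
        for _, li, ri in pairs:
            w = spec.homotopic_strength * rng.lognormal(0.0, 0.25)
            W[li, ri] = W[ri, li] = w
        for i in range(n):
            for j in range(i + 1, n):
                if pid[i] == pid[j]:
                    continue  # homotopic already placed
                same_hemi = hemi[i] == hemi[j]
                if rng.random() < spec.ipsilateral_density:
                    w = rng.lognormal(0.0, 0.5)
                    if not same_hemi:
                        w *= 0.5  # cross-hemisphere coupling is weaker
                    W[i, j] = W[j, i] = w
        conn = Connectome(atlas=atlas, weights=W)
        if conn.is_connected():
            return normalize_acs(conn)
    raise RuntimeError(
        f"failed to draw a connected connectome in {_CONNECT_RETRY_CAP} tries; "
        "increase ipsilateral_density"
    )


def gen_tracer_connectome(atlas: RegionAtlas, spec: SyntheticSpec) -> TracerBundle:
    """Directed tracer-style connectome over K >= atlas-size tracer regions.

    Each mapped atlas region owns 1-3 tracer subregions (the homolog map is
    many-to-one); a configurable fraction of atlas regions is left unmapped.
    Directed mass is laid down so that, after projection-density scaling and
    homolog aggregation, edges touching subcortex have anterograde ratio
    ~ ``directional_bias`` (oriented subcortical -> cortical) and
    cortico-cortical edges are near-symmetric (ratio ~ 0.5).
    """
    rng = _rng(spec, 2)
    n = atlas.n_regions
    n_unmapped = int(round(spec.unmapped_fraction * n))
    if n_unmapped >= n:
        raise ValueError("homolog map would cover zero regions")
    unmapped = set(rng.choice(n, size=n_unmapped, replace=False).tolist())

    tracer_labels: list[str] = []
    entries: dict[str, str] = {}
    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(atlas.labels):
        if i in unmapped:
            continue
        k_sub = int(rng.integers(1, 4))
        idxs = []
        for s in range(k_sub):
            t_lab = f"t_{lab}_{s}"
            entries[t_lab] = lab
            idxs.append(len(tracer_labels))
            tracer_labels.append(t_lab)
        groups[i] = idxs
    # pad with orphan tracer regions (no human homolog) so K >= atlas size
    orphan = 0
    while len(tracer_labels) < n:
        tracer_labels.append(f"t_orphan_{orphan}")
        orphan += 1
    if not entries:
        raise ValueError("homolog map covers zero regions")

    K = len(tracer_labels)
    voxels = rng.integers(50, 151, size=K).astype(float)
    density = np.zeros((K, K))  # desired projection density, filled per edge
    is_sub = np.asarray([lb == "subcortical" for lb in atlas.lobe])

    mapped = sorted(groups)
    for ai in mapped:
        for aj in mapped:
            if aj <= ai:
                continue
            mass = rng.lognormal(0.0, 0.5)
            if is_sub[ai] or is_sub[aj]:
                # orient the bias from subcortex outward; random orientation
                # for subcortical-subcortical edges
                if is_sub[ai] and not is_sub[aj]:
                    r = spec.directional_bias
                elif is_sub[aj] and not is_sub[ai]:
                    r = 1.0 - spec.directional_bias
                else:
                    r = spec.directional_bias if rng.random() < 0.5 \
                        else 1.0 - spec.directional_bias
            else:
                r = float(np.clip(rng.normal(0.5, 0.02), 0.35, 0.65))
            gi, gj = groups[ai], groups[aj]
            share = 1.0 / (len(gi) * len(gj))
            for a in gi:
                for b in gj:
                    density[a, b] = r * mass * share
                    density[b, a] = (1.0 - r) * mass * share
    # tracer matrix is density divided back by injection voxel counts, so
    # projection_density(matrix, voxels) reproduces the intended mass exactly
    matrix = density / voxels[:, None]
    return TracerBundle(labels=tuple(tracer_labels), matrix=matrix,
                        voxels=voxels, homolog_map=HomologMap(entries))


def gen_cohort_volumes(atlas: RegionAtlas, conn: Connectome, true_seed: str,
                       beta: float, t_true: float, spec: SyntheticSpec,
                       laplacian: LaplacianMatrix | None = None,
                       scale: float | None = None) -> CohortVolumes:
    """Two-cohort volume table with a planted forward-NDM deficit.

    The ground-truth pattern is the model state x(t_true) from a bilateral
    seed at ``true_seed`` (under the nondirectional Laplacian of ``conn``
    unless another is given), averaged over hemispheres so the deficit is
    bilaterally symmetric.  Control volumes are per-region baselines times a
    subject ICV factor plus noise; patients additionally lose
    ``scale * x_true`` per region.  Noise SD is ``spec.noise_sd`` times the
    standard deviation of the planted signal across regions.
    """
    if t_true < 0:
        raise ValueError("t_true must be non-negative")
    rng = _rng(spec, 3)
    H = laplacian if laplacian is not None else laplacian_nondirectional(conn)
    x0 = seed_vector(atlas, true_seed, bilateral=True)
    x_t = Propagator(H, beta).kernel(t_true) @ x0
    x_t = np.maximum(x_t, 0.0)  # scrub numerical negatives
    # bilaterally symmetric deficit: average homologs, assign to both
    x_true = np.empty_like(x_t)
    for _, li, ri in atlas.pairs():
        m = 0.5 * (x_t[li] + x_t[ri])
        x_true[li] = x_true[ri] = m

    n = atlas.n_regions
    baselines = rng.lognormal(np.log(100.0), 0.3, size=n)
    if scale is None:
        scale = 0.2 * baselines.min() / x_true.max()
    patient_means = baselines - scale * x_true
    if np.any(patient_means <= 0):
        raise ValueError("scale too large: some noiseless patient volume <= 0")

    n_subj = spec.n_patients + spec.n_controls
    icv_ref = 1500.0
    icv = rng.lognormal(np.log(icv_ref), 0.1, size=n_subj)
    factor = icv / icv_ref
    signal_sd = float(np.std(scale * x_true))
    noise = rng.normal(0.0, spec.noise_sd * signal_sd, size=(n_subj, n)) \
        if spec.noise_sd > 0 else np.zeros((n_subj, n))

    means = np.vstack([np.tile(patient_means, (spec.n_patients, 1)),
                       np.tile(baselines, (spec.n_controls, 1))])
    volumes = means * factor[:, None] + noise
    if np.any(volumes <= 0):
        raise RuntimeError("noise produced a non-positive volume; lower noise_sd")

    subject_id = [f"P{i + 1:03d}" for i in range(spec.n_patients)] + \
                 [f"C{i + 1:03d}" for i in range(spec.n_controls)]
    group = ["patient"] * spec.n_patients + ["control"] * spec.n_controls
    table = pd.DataFrame({"subject_id": subject_id, "group": group, "icv": icv})
    table[list(atlas.labels)] = volumes
    return CohortVolumes(table=table, atlas=atlas, true_seed=true_seed,
                         x_true=x_true, scale=float(scale), beta=beta,
                         t_true=t_true)


def with_seed(spec: SyntheticSpec, rng_seed: int) -> SyntheticSpec:
    """Copy of the spec with a different RNG seed (for replicate studies)."""
    return replace(spec, rng_seed=rng_seed)
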
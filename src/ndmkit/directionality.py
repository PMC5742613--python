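"""Transfer of directionality from a directed tracer connectome onto an
undirected human-style connectome.

Axonal tracer experiments (e.g. the Allen mouse connectivity atlas) measure
directed projection strength between regions, which diffusion MRI cannot.
The workflow here: (1) scale the tracer matrix to projection densities using
injection-region voxel counts; (2) aggregate tracer regions into human atlas
regions through a homolog map, summing afferent and efferent connections;
(3) form the per-edge anterograde ratio r_ij = M_ij / (M_ij + M_ji); and
(4) split each undirected edge of the human connectome into anterograde and
retrograde components, C^ant_ij = r_ij * c_ij and C^ret_ij = (1-r_ij) * c_ij.

Because r_ij + r_ji = 1 wherever both directions are measured, the split
conserves connection mass: C^ant + (C^ant)^T = C for symmetric C, and the
retrograde connectome is the transpose of the anterograde one.  Edges whose
regions lack a tracer homolog (or whose aggregated mass is zero in both
directions) get the neutral ratio 0.5 and are flagged, so no directionality
is imputed where none was measured.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import RegionAtlas
from .connectome import Connectome, write_matrix_csv


@dataclass(frozen=True)
class HomologMap:
    """Many-to-one map from tracer-region labels to human-region labels."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("homolog map is empty")

    def mapped_human_labels(self) -> set[str]:
        return set(self.entries.values())

    def groups(self, atlas: RegionAtlas) -> dict[int, list[str]]:
        """Tracer labels grouped by human atlas index; validates that every
        mapped human label is in the atlas."""
        unknown = self.mapped_human_labels() - set(atlas.labels)
        if unknown:
            raise ValueError(f"homolog map targets unknown regions: {sorted(unknown)}")
        out: dict[int, list[str]] = {}
        for tracer, human in self.entries.items():
            out.setdefault(atlas.index(human), []).append(tracer)
        return out

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"tracer_label": list(self.entries), "human_label": list(self.entries.values())}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "HomologMap":
        df = pd.read_csv(path)
        return cls(dict(zip(df["tracer_label"].astype(str), df["human_label"].astype(str))))


@dataclass(frozen=True)
class AggregatedTracer:
    """Directed tracer mass aggregated onto the human atlas, with a mask of
    pairs where both regions had tracer homologs."""

    atlas: RegionAtlas
    mass: np.ndarray        # directed, >= 0
    available: np.ndarray   # bool, True where both regions mapped


@dataclass(frozen=True)
class RatioTable:
    """Per-edge anterograde ratios r in [0, 1] with r_ij + r_ji = 1 on
    defined pairs; ``defaulted`` marks pairs set to the neutral 0.5."""

    values: np.ndarray
    defaulted: np.ndarray  # bool; True where 0.5 was imputed

    def __post_init__(self) -> None:
        r = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", r)
        object.__setattr__(self, "defaulted", np.asarray(self.defaulted, dtype=bool))
        if r.min() < 0 or r.max() > 1:
            raise ValueError("ratios must lie in [0, 1]")
        if np.abs((r + r.T) - 1.0).max() > 1e-12:
            raise ValueError("ratio table must satisfy r_ij + r_ji = 1")

    @property
    def n_defaulted_edges(self) -> int:
        return int(np.triu(self.defaulted, k=1).sum())


@dataclass(frozen=True)
class DirectionalConnectome:
    """Non-symmetric split of a symmetric connectome along tracer-informed
    edge directions."""

    atlas: RegionAtlas
    weights: np.ndarray
    mode: str  # anterograde | retrograde
    ratio: RatioTable | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", W)
        if W.min() < 0:
            raise ValueError("directional weights must be non-negative")
        if self.mode not in ("anterograde", "retrograde"):
            raise ValueError(f"unknown mode: {self.mode!r}")
        if W.shape != (self.atlas.n_regions,) * 2:
            raise ValueError("weights shape does not match atlas")

    def to_csv(self, path) -> None:
        write_matrix_csv(path, self.weights, self.atlas.labels)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def projection_density(tracer: np.ndarray, voxels: np.ndarray) -> np.ndarray:
    """Scale each row of the tracer connectivity matrix by the voxel count of
    its injection region, giving total projection density."""
    T = np.asarray(tracer, dtype=float)
    v = np.asarray(voxels, dtype=float)
    if v.ndim != 1 or v.size != T.shape[0]:
        raise ValueError(f"voxel counts length {v.size} != tracer dimension {T.shape[0]}")
    if np.any(v <= 0):
        raise ValueError("voxel counts must be positive")
    return T * v[:, None]


def aggregate_to_human(density: np.ndarray, homolog_map: HomologMap,
                       atlas: RegionAtlas,
                       tracer_labels: list[str]) -> AggregatedTracer:
    """Sum directed tracer mass over homolog groups: M_ij is the total density
    from tracer regions mapping to human region i into those mapping to j.

    Pairs where either region has no tracer homolog are flagged unavailable.
    """
    D = np.asarray(density, dtype=float)
    if D.shape != (len(tracer_labels),) * 2:
        raise ValueError("density shape does not match tracer labels")
    groups = homolog_map.groups(atlas)
    tracer_index = {lab: k for k, lab in enumerate(tracer_labels)}
    n = atlas.n_regions
    # membership matrix B: human x tracer
    B = np.zeros((n, len(tracer_labels)))
    for hi, tlabs in groups.items():
        for t in tlabs:
            if t not in tracer_index:
                raise ValueError(f"homolog map names unknown tracer region {t!r}")
            B[hi, tracer_index[t]] = 1.0
    mass = B @ D @ B.T
    mapped = B.sum(axis=1) > 0
    available = np.outer(mapped, mapped)
    np.fill_diagonal(mass, 0.0)
    return AggregatedTracer(atlas=atlas, mass=mass, available=available)


def anterograde_ratio(agg: AggregatedTracer) -> RatioTable:
    """Per-edge anterograde ratio r_ij = M_ij / (M_ij + M_ji).

    A ratio of 1 is a purely anterograde connection, 0 purely retrograde,
    0.5 bidirectional.  Unavailable or all-zero pairs default to 0.5 and are
    flagged.
    """
    M = np.asarray(agg.mass, dtype=float)
    if M.min() < 0:
        raise ValueError("aggregated mass must be non-negative")
    total = M + M.T
    defined = agg.available & (total > 0)
    r = np.full_like(M, 0.5)
    r[defined] = M[defined] / total[defined]
    defaulted = ~defined
    np.fill_diagonal(r, 0.5)  # diagonal is unused; keeps r + r.T == 1
    return RatioTable(values=r, defaulted=defaulted)


def apply_direction(conn: Connectome, ratio: RatioTable, mode: str) -> DirectionalConnectome:
    """Split the symmetric connectome along the ratio table.

    anterograde: w_ij = r_ij * c_ij;  retrograde: w_ij = (1 - r_ij) * c_ij.
    With r_ij + r_ji = 1 and symmetric C, the retrograde connectome equals
    the transpose of the anterograde one and their sum reconstructs C.
    """
    if not isinstance(ratio, RatioTable):
        ratio = RatioTable(values=np.asarray(ratio, dtype=float),
                           defaulted=np.zeros(np.shape(ratio), dtype=bool))
    r = ratio.values
    if r.shape != conn.weights.shape:
        raise ValueError("ratio table dimensions do not match connectome")
    if mode == "anterograde":
        W = r * conn.weights
    elif mode == "retrograde":
        W = (1.0 - r) * conn.weights
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    return DirectionalConnectome(atlas=conn.atlas, weights=W, mode=mode, ratio=ratio)


def directionality_index(W: np.ndarray) -> np.ndarray:
    """Per-edge index (W_ij - W_ji) / (W_ij + W_ji) in [-1, 1]; +1 is purely
    anterograde, -1 purely retrograde, 0 bidirectional.  NaN where neither
    direction carries weight."""
    W = np.asarray(W, dtype=float)
    if W.min() < 0:
        raise ValueError("weights must be non-negative")
    total = W + W.T
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = np.where(total > 0, (W - W.T) / total, np.nan)
    return idx


def export_ratio(ratio: RatioTable, atlas: RegionAtlas, path, mask_path=None) -> None:
    """Write the ratio table (and optionally its defaulted-edge 0/1 mask) as
    labeled CSV matrices."""
    write_matrix_csv(path, ratio.values, atlas.labels)
    if mask_path is not None:
        write_matrix_csv(mask_path, ratio.defaulted.astype(int), atlas.labels)
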
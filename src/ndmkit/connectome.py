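"""Connectome data model, anatomical-connection-strength (ACS) normalization,
region removal, degrees, and both graph-Laplacian constructions.

The diffusion generator used throughout is the degree-normalized Laplacian

    H = I - D^{-1} C,        D = diag(row degrees),

for a symmetric connectome ``C``, and its directional analogue

    H_dir = I - diag(g)^{-1} C_dir,   g_i = sqrt(d_row,i * d_col,i),

for a non-symmetric (anterograde or retrograde) connectome.  Row degree is
the sum of weighted connections emanating from a node.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import RegionAtlas

_SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class Connectome:
    """Symmetric, non-negative, zero-diagonal weight matrix over an atlas."""

    atlas: RegionAtlas
    weights: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", W)
        n = self.atlas.n_regions
        if W.shape != (n, n):
            raise ValueError(f"weights shape {W.shape} != atlas size ({n}, {n})")
        if not np.all(np.isfinite(W)):
            raise ValueError("connectome weights must be finite")
        if W.min() < 0:
            raise ValueError("connectome weights must be non-negative")
        if np.abs(np.diag(W)).max(initial=0.0) > 0:
            raise ValueError("connectome diagonal must be zero")
        if np.abs(W - W.T).max() > _SYMMETRY_TOL * max(1.0, np.abs(W).max()):
            raise ValueError("connectome must be symmetric")

    @property
    def n_regions(self) -> int:
        return self.atlas.n_regions

    def total_weight(self) -> float:
        return float(self.weights.sum())

    def is_connected(self) -> bool:
        from scipy.sparse import csgraph, csr_matrix

        ncomp, _ = csgraph.connected_components(
            csr_matrix(self.weights > 0), directed=False
        )
        return ncomp == 1

    # -- I/O ----------------------------------------------------------------
    def to_csv(self, path) -> None:
        write_matrix_csv(path, self.weights, self.atlas.labels)

    @classmethod
    def from_csv(cls, path, atlas: RegionAtlas | None = None) -> "Connectome":
        """Read a labeled square matrix; validates symmetry within 1e-9 and
        symmetrizes by averaging with a warning if violated."""
        labels, W = read_matrix_csv(path)
        if atlas is None:
            atlas = _atlas_from_labels(labels)
        elif tuple(labels) != atlas.labels:
            raise ValueError("CSV region labels do not match the given atlas")
        asym = np.abs(W - W.T).max()
        if asym > _SYMMETRY_TOL * max(1.0, np.abs(W).max()):
            warnings.warn(
                f"connectome not symmetric (max asymmetry {asym:.3g}); "
                "symmetrizing by averaging",
                stacklevel=2,
            )
            W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0.0)
        return cls(atlas=atlas, weights=W)


@dataclass(frozen=True)
class LaplacianMatrix:
    """A (possibly directional) graph Laplacian H; beta-free — the global
    diffusivity lives in :class:`ndmkit.ndm.DiffusionParams`."""

    values: np.ndarray
    kind: str  # nondirectional | anterograde | retrograde
    atlas: RegionAtlas | None = None
    # optional diagonal scale s such that diag(s) H diag(s)^-1 is symmetric;
    # lets the propagator use a symmetric eigendecomposition
    sym_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        H = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", H)
        if H.ndim != 2 or H.shape[0] != H.shape[1]:
            raise ValueError("Laplacian must be square")
        if not np.all(np.isfinite(H)):
            raise ValueError("Laplacian entries must be finite")
        if self.kind not in ("nondirectional", "anterograde", "retrograde"):
            raise ValueError(f"unknown Laplacian kind: {self.kind!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def normalize_acs(conn: Connectome) -> Connectome:
    """Scale the whole matrix by its grand total so connection strengths sum
    to one.  A single scalar normalization leaves relative weights untouched."""
    total = conn.total_weight()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero connectome")
    return Connectome(atlas=conn.atlas, weights=conn.weights / total)


def remove_regions(conn: Connectome, labels) -> Connectome:
    """Drop named regions from atlas and weights (principal submatrix)."""
    new_atlas = conn.atlas.remove(labels)  # raises on unknown labels
    keep = conn.atlas.keep_indices(labels)
    W = conn.weights[np.ix_(keep, keep)]
    return Connectome(atlas=new_atlas, weights=W)


def degrees(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row degrees (out) and column degrees (in) of a weight matrix."""
    W = np.asarray(W, dtype=float)
    if W.min() < 0:
        raise ValueError("weights must be non-negative")
    return W.sum(axis=1), W.sum(axis=0)


def laplacian_nondirectional(conn: Connectome) -> LaplacianMatrix:
    """Degree-normalized Laplacian H = I - D^{-1} C.

    Every row of H sums to zero, so the all-ones vector is a right
    eigenvector with eigenvalue 0.  Raises if any region is isolated.
    """
    d_row, _ = degrees(conn.weights)
    zero = np.flatnonzero(d_row == 0)
    if zero.size:
        names = [conn.atlas.labels[i] for i in zero]
        raise ValueError(f"zero-degree region(s): {names}")
    H = np.eye(conn.n_regions) - conn.weights / d_row[:, None]
    # D^{1/2} H D^{-1/2} = I - D^{-1/2} C D^{-1/2} is symmetric
    return LaplacianMatrix(values=H, kind="nondirectional", atlas=conn.atlas,
                           sym_scale=np.sqrt(d_row))


def laplacian_directional(cdir: "DirectionalConnectome | np.ndarray",
                          kind: str | None = None,
                          atlas: RegionAtlas | None = None) -> LaplacianMatrix:
    """Directional Laplacian H = I - diag(g)^{-1} C_dir with
    g_i = sqrt(d_row,i * d_col,i).

    Where d_row,i = 0 or d_col,i = 0 the scale g_i is set to 1, so row i is
    used unnormalized (inert when the row is all zero).
    """
    if hasattr(cdir, "weights"):
        W = np.asarray(cdir.weights, dtype=float)
        kind = kind or getattr(cdir, "mode", None) or "anterograde"
        atlas = atlas or cdir.atlas
    else:
        W = np.asarray(cdir, dtype=float)
        kind = kind or "anterograde"
    if W.min() < 0:
        raise ValueError("directional weights must be non-negative")
    d_row, d_col = degrees(W)
    g = np.sqrt(d_row * d_col)
    g = np.where((d_row == 0) | (d_col == 0), 1.0, g)
    H = np.eye(W.shape[0]) - W / g[:, None]
    return LaplacianMatrix(values=H, kind=kind, atlas=atlas)


# ---------------------------------------------------------------------------
# labeled-matrix CSV helpers (shared with directionality exports)
# ---------------------------------------------------------------------------

def write_matrix_csv(path, M: np.ndarray, labels) -> None:
    pd.DataFrame(M, index=list(labels), columns=list(labels)).to_csv(path)


def read_matrix_csv(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise ValueError("matrix CSV row and column labels differ")
    return [str(c) for c in df.columns], df.to_numpy(dtype=float)


def _atlas_from_labels(labels) -> RegionAtlas:
    """Minimal atlas for a bare matrix file: infers left/right pairing from
    label suffixes where possible, otherwise marks singleton pairs."""
    from .atlas import _common_stem

    n = len(labels)
    hemisphere = ["left"] * n
    pair_id = list(range(n))
    used = set()
    for i in range(n):
        if i in used:
            continue
        for j in range(i + 1, n):
            if j in used:
                continue
            stem = _common_stem(labels[i], labels[j])
            if stem is not None:
                lab_i = labels[i]
                left_first = ("left" in lab_i.lower().replace(stem.lower(), "")
                              or lab_i.endswith("_L"))
                hemisphere[i] = "left" if left_first else "right"
                hemisphere[j] = "right" if left_first else "left"
                pair_id[j] = pair_id[i]
                used.update((i, j))
                break
    return RegionAtlas(
        labels=tuple(labels),
        hemisphere=tuple(hemisphere),
        lobe=tuple("subcortical" for _ in labels),
        pair_id=tuple(pair_id),
    )
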
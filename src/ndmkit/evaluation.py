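"""Scoring model trajectories against empirical atrophy.

For a seed region (pair), the NDM trajectory is correlated with the
empirical atrophy vector at every model time, giving an R-t curve.  The
curve's maximum R_max scores the seed's plausibility as the disease
epicenter; repeating this for every bilateral pair "runs the model
backwards" and yields a ranking of candidate epicenters.  A plausible seed
shows an interior peak: the model matches the data best at some intermediate
diffusion time, before the pattern flattens toward the network's consensus.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import RegionAtlas
from .atrophy import AtrophyVector, bilateral_average
from .connectome import Connectome, LaplacianMatrix
from .ndm import DiffusionParams, Propagator, Trajectory, seed_vector

# a trajectory column whose standard deviation is below this (relative to its
# magnitude) is treated as constant: its correlation is undefined/missing
_CONST_REL_TOL = 1e-12


@dataclass(frozen=True)
class RTCurve:
    """Pearson correlation between model and atrophy per model time."""

    times: np.ndarray
    r_values: np.ndarray          # NaN where the correlation is undefined
    seed: tuple[str, ...] = ()
    kind: str = "nondirectional"
    p_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.r_values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "r_values", r)
        if r.shape != t.shape:
            raise ValueError("r_values and times must have equal length")
        finite = r[np.isfinite(r)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")


@dataclass(frozen=True)
class SeedRanking:
    """One row per bilateral seed pair, sorted by R_max descending."""

    table: pd.DataFrame  # columns: seed, pair_id, r_max, t_max, interior

    def rank_of(self, seed_label: str) -> int:
        """1-based rank of a seed pair (by pair label)."""
        pos = np.flatnonzero(self.table["seed"].to_numpy() == seed_label)
        if pos.size == 0:
            raise KeyError(f"seed {seed_label!r} not in ranking")
        return int(pos[0]) + 1

    @property
    def best(self) -> pd.Series:
        return self.table.iloc[0]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _corr_columns(X: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Pearson r between each column of X and the vector a; NaN for columns
    that are (numerically) constant."""
    a = np.asarray(a, dtype=float)
    ac = a - a.mean()
    na = np.linalg.norm(ac)
    if na == 0:
        raise ValueError("atrophy vector has zero variance")
    Xc = X - X.mean(axis=0)
    nx = np.linalg.norm(Xc, axis=0)
    scale = np.abs(X).max(axis=0)
    defined = nx > _CONST_REL_TOL * np.maximum(scale, 1e-300) * np.sqrt(X.shape[0])
    r = np.full(X.shape[1], np.nan)
    r[defined] = (Xc[:, defined].T @ ac) / (nx[defined] * na)
    return np.clip(r, -1.0, 1.0, out=r)


def r_t_curve(traj: Trajectory, atrophy: AtrophyVector,
              with_p: bool = False) -> RTCurve:
    """Correlate the trajectory with empirical atrophy at every model time.

    All regions are included (seed regions are not excluded).  Times where
    the trajectory column is constant yield a missing (NaN) correlation.
    """
    if traj.atlas is not None and traj.atlas.labels != atrophy.atlas.labels:
        raise ValueError("trajectory and atrophy use different atlases")
    if traj.n_regions != atrophy.atlas.n_regions:
        raise ValueError("trajectory and atrophy dimensions differ")
    r = _corr_columns(traj.values, atrophy.values)
    p = None
    if with_p:
        n = traj.n_regions
        p = np.full_like(r, np.nan)
        ok = np.isfinite(r) & (np.abs(r) < 1)
        tstat = r[ok] * np.sqrt((n - 2) / (1 - r[ok] ** 2))
        p[ok] = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
        p[np.isfinite(r) & (np.abs(r) >= 1)] = 0.0
    return RTCurve(times=traj.times, r_values=r, seed=traj.seed_labels,
                   kind=traj.kind, p_values=p)


def peak(curve: RTCurve) -> tuple[float, float, bool]:
    """(R_max, t_max, interior) of an R-t curve.

    Missing values are skipped; ties break toward the earliest time; the
    peak is interior iff its index is neither the first nor last grid point.
    """
    r = curve.r_values
    if not np.any(np.isfinite(r)):
        raise ValueError("R-t curve has no defined values")
    k = int(np.nanargmax(r))  # first occurrence on ties
    interior = 0 < k < r.size - 1
    return float(r[k]), float(curve.times[k]), interior


def repeated_seeding(H: LaplacianMatrix, atlas: RegionAtlas,
                     atrophy: AtrophyVector, params: DiffusionParams,
                     bilateral: bool = True,
                     return_curves: bool = False):
    """Seed every region (pair) in turn, evolve the NDM, and rank seeds by
    peak model-atrophy correlation.

    The diffusion kernel is computed once per time point and shared across
    all seeds: the kernel's columns are the unit-seed trajectories, so a
    bilateral pair's trajectory is the sum of its two homolog columns.
    """
    if bilateral and not atlas.fully_paired:
        raise ValueError("bilateral seeding requires a fully paired atlas")
    n = atlas.n_regions
    if H.n != n or atrophy.atlas.labels != atlas.labels:
        raise ValueError("Laplacian, atlas and atrophy must share regions")
    if bilateral:
        pairs = atlas.pairs()
        seeds = [(atlas.pair_label(pid), pid, (li, ri)) for pid, li, ri in pairs]
        cols_a = np.array([li for _, li, _ in pairs])
        cols_b = np.array([ri for _, _, ri in pairs])
    else:
        seeds = [(lab, pid, (i,)) for i, (lab, pid)
                 in enumerate(zip(atlas.labels, atlas.pair_id))]
        cols_a = np.arange(n)
        cols_b = None

    prop = Propagator(H, params.beta)
    times = params.time_grid
    R = np.empty((len(seeds), times.size))
    for k, t in enumerate(times):
        K = prop.kernel(t)
        X = K[:, cols_a] + K[:, cols_b] if cols_b is not None else K[:, cols_a]
        R[:, k] = _corr_columns(X, atrophy.values)

    rows = []
    curves: dict[str, RTCurve] = {}
    for (label, pid, idx), r in zip(seeds, R):
        curve = RTCurve(times=times, r_values=r,
                        seed=tuple(atlas.labels[i] for i in idx), kind=H.kind)
        try:
            r_max, t_max, interior = peak(curve)
        except ValueError as exc:
            raise ValueError(f"seed {label!r}: {exc}") from exc
        rows.append((label, pid, r_max, t_max, interior))
        if return_curves:
            curves[label] = curve
    table = pd.DataFrame(rows, columns=["seed", "pair_id", "r_max", "t_max",
                                        "interior"])
    # stable sort: ties keep atlas (pair_id) order, so ranking is deterministic
    table = table.sort_values("r_max", ascending=False,
                              kind="stable").reset_index(drop=True)
    ranking = SeedRanking(table=table)
    return (ranking, curves) if return_curves else ranking


def curves_to_long_frame(curves: dict[str, RTCurve]) -> pd.DataFrame:
    """Long-format table (seed, time, r) for export/plotting."""
    frames = [pd.DataFrame({"seed": label, "time": c.times, "r": c.r_values})
              for label, c in curves.items()]
    return pd.concat(frames, ignore_index=True)


def seed_connectivity_correlation(conn: Connectome, seed_label: str,
                                  atrophy: AtrophyVector) -> tuple[float, float]:
    """Model-free check: correlate mean connectivity from the (bilateral)
    seed with atrophy across bilateral pairs.

    Predictor: the mean of the two seed regions' connectivity rows,
    bilaterally averaged; response: bilaterally averaged atrophy.  Returns
    Pearson R and its two-tailed p over all pairs (the seed pair included).
    """
    atlas = conn.atlas
    li, ri = atlas.pair_indices(seed_label)
    predictor_full = 0.5 * (conn.weights[li] + conn.weights[ri])
    predictor = bilateral_average(predictor_full, atlas)
    response = bilateral_average(atrophy.values, atlas)
    if np.std(predictor) == 0:
        raise ValueError("seed connectivity predictor has zero variance")
    res = stats.pearsonr(predictor, response)
    return float(res.statistic), float(res.pvalue)
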
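"""Empirical atrophy vectors from two-cohort regional volume tables.

Pipeline: divide each subject's regional volumes by their intracranial
volume (ICV) to correct for head size; compute a per-region two-sample
t-statistic between controls and patients; squash it onto (0, 1) with a
logistic transform; optionally average homotopic pairs.

Sign convention (important — it flips every downstream correlation):
t = (mean_controls - mean_patients) / SE, so regions where patients have
*smaller* volumes (atrophy) get *positive* t and transformed values above
0.5.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import RegionAtlas

META_COLUMNS = ("subject_id", "group", "icv")


@dataclass(frozen=True)
class AtrophyVector:
    """Per-region atrophy statistic: raw t and its logistic transform."""

    atlas: RegionAtlas
    t_raw: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t_raw, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "t_raw", t)
        object.__setattr__(self, "values", v)
        n = self.atlas.n_regions
        if t.shape != (n,) or v.shape != (n,):
            raise ValueError("atrophy vector length must equal atlas size")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError("atrophy values must be finite")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("transformed atrophy must lie in [0, 1]")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"region": self.atlas.labels, "t_raw": self.t_raw, "value": self.values}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, atlas: RegionAtlas) -> "AtrophyVector":
        df = pd.read_csv(path)
        if tuple(df["region"].astype(str)) != atlas.labels:
            raise ValueError("atrophy CSV regions do not match atlas")
        return cls(atlas=atlas, t_raw=df["t_raw"].to_numpy(),
                   values=df["value"].to_numpy())


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def icv_correct(table: pd.DataFrame) -> pd.DataFrame:
    """Divide every subject's regional volumes by that subject's ICV.

    ``table`` holds one row per subject with columns ``subject_id``,
    ``group``, ``icv`` and one column per region.  Returns the same layout
    with corrected region columns (icv column retained for provenance).
    """
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"volume table missing column(s): {missing}")
    bad = table.loc[table["icv"] <= 0, "subject_id"]
    if len(bad):
        raise ValueError(f"non-positive ICV for subject(s): {list(bad)}")
    out = table.copy()
    region_cols = [c for c in table.columns if c not in META_COLUMNS]
    out[region_cols] = table[region_cols].to_numpy(dtype=float) / \
        table["icv"].to_numpy(dtype=float)[:, None]
    return out


def group_tstat(patients: pd.DataFrame, controls: pd.DataFrame,
                welch: bool = False) -> np.ndarray:
    """Per-region two-sample t between control and patient corrected volumes,
    signed (mean_controls - mean_patients) so atrophy is positive.

    Pooled-variance (Student) t by default; ``welch=True`` for unequal
    variances.  Raises if a region has zero variance in both groups.
    """
    region_cols = [c for c in patients.columns if c not in META_COLUMNS]
    if region_cols != [c for c in controls.columns if c not in META_COLUMNS]:
        raise ValueError("patient and control tables list different regions")
    X = patients[region_cols].to_numpy(dtype=float)
    Y = controls[region_cols].to_numpy(dtype=float)
    n1, n2 = X.shape[0], Y.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 subjects per group")
    mean_p, mean_c = X.mean(axis=0), Y.mean(axis=0)
    var_p = X.var(axis=0, ddof=1)
    var_c = Y.var(axis=0, ddof=1)
    if welch:
        se = np.sqrt(var_p / n1 + var_c / n2)
    else:
        sp2 = ((n1 - 1) * var_p + (n2 - 1) * var_c) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    zero = np.flatnonzero(se == 0)
    if zero.size:
        names = [region_cols[i] for i in zero]
        raise ValueError(f"zero pooled variance in region(s): {names}")
    return (mean_c - mean_p) / se


def logistic_transform(t_raw: np.ndarray, slope: float = 1.0,
                       midpoint: float = 0.0) -> np.ndarray:
    """Map t-statistics onto (0, 1): v = 1 / (1 + exp(-slope*(t - midpoint))).

    Strictly increasing in t; t = midpoint maps to 0.5.
    """
    if slope <= 0:
        raise ValueError("logistic slope must be positive")
    t = np.asarray(t_raw, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t-statistics must be finite")
    return 1.0 / (1.0 + np.exp(-slope * (t - midpoint)))


def bilateral_average(v: np.ndarray, atlas: RegionAtlas) -> np.ndarray:
    """Average homotopic left/right values, returning one value per pair
    ordered by pair_id.  Requires a fully paired atlas."""
    if not atlas.fully_paired:
        raise ValueError("atlas has unpaired regions; cannot average bilaterally")
    v = np.asarray(v, dtype=float)
    if v.shape != (atlas.n_regions,):
        raise ValueError("vector length must equal atlas size")
    pairs = atlas.pairs()
    return np.array([(v[li] + v[ri]) / 2.0 for _, li, ri in pairs])


def compute_atrophy(volumes: pd.DataFrame, atlas: RegionAtlas,
                    slope: float = 1.0, midpoint: float = 0.0,
                    welch: bool = False, standardize: bool = True,
                    patient_label: str = "patient",
                    control_label: str = "control") -> AtrophyVector:
    """Full pipeline: ICV-correct, split by group, t-test, logistic transform.

    By default the t-vector is standardized (z-scored across regions) before
    the logistic, making the transform scale-free: t-statistic magnitudes
    grow with cohort size and shrink with measurement noise, and a fixed
    slope would saturate the transform for well-powered cohorts, flattening
    exactly the regional contrast the atrophy vector is meant to carry.
    Set ``standardize=False`` to apply slope/midpoint to the raw t directly.
    """
    region_cols = [c for c in volumes.columns if c not in META_COLUMNS]
    if region_cols != list(atlas.labels):
        raise ValueError("volume table regions do not match atlas order")
    corrected = icv_correct(volumes)
    patients = corrected[corrected["group"] == patient_label]
    controls = corrected[corrected["group"] == control_label]
    if patients.empty or controls.empty:
        raise ValueError("both patient and control groups are required")
    t = group_tstat(patients, controls, welch=welch)
    x = t
    if standardize:
        sd = t.std()
        if sd == 0:
            raise ValueError("t-statistics are constant across regions")
        x = (t - t.mean()) / sd
    values = logistic_transform(x, slope=slope, midpoint=midpoint)
    return AtrophyVector(atlas=atlas, t_raw=t, values=values)
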
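"""Region atlas: ordered brain-region labels with hemisphere, lobe and
bilateral (homotopic) pairing.

The atlas order is the canonical index for every matrix and vector in the
package; nothing downstream re-sorts regions.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HEMISPHERES = ("left", "right")
LOBES = ("frontal", "parietal", "occipital", "temporal", "subcortical")


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered set of brain regions.

    Parameters
    ----------
    labels : unique region names, in canonical order.
    hemisphere : ``"left"`` or ``"right"`` per region.
    lobe : lobe assignment per region (one of :data:`LOBES`).
    pair_id : homotopic-pair index per region; each id appears at most
        twice, once per hemisphere.  A fully paired atlas (every id exactly
        twice) is required for bilateral operations.
    """

    labels: tuple[str, ...]
    hemisphere: tuple[str, ...]
    lobe: tuple[str, ...]
    pair_id: tuple[int, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.labels)
        if not (len(self.hemisphere) == len(self.lobe) == len(self.pair_id) == n):
            raise ValueError("atlas fields must have equal length")
        if len(set(self.labels)) != n:
            raise ValueError("region labels must be unique")
        bad = set(self.hemisphere) - set(HEMISPHERES)
        if bad:
            raise ValueError(f"unknown hemisphere value(s): {sorted(bad)}")
        counts: dict[int, list[str]] = {}
        for pid, hemi in zip(self.pair_id, self.hemisphere):
            counts.setdefault(pid, []).append(hemi)
        for pid, hemis in counts.items():
            if len(hemis) > 2:
                raise ValueError(f"pair_id {pid} occurs more than twice")
            if len(hemis) == 2 and set(hemis) != set(HEMISPHERES):
                raise ValueError(f"pair_id {pid} is not a left/right pair")
        object.__setattr__(self, "_index", {lab: i for i, lab in enumerate(self.labels)})

    # -- basic introspection ------------------------------------------------
    @property
    def n_regions(self) -> int:
        return len(self.labels)

    @property
    def fully_paired(self) -> bool:
        pids = list(self.pair_id)
        return all(pids.count(p) == 2 for p in set(pids))

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown region label: {label!r}") from None

    def pairs(self) -> list[tuple[int, int, int]]:
        """Return ``(pair_id, left_index, right_index)`` for every complete
        homotopic pair, ordered by pair_id."""
        left: dict[int, int] = {}
        right: dict[int, int] = {}
        for i, (pid, hemi) in enumerate(zip(self.pair_id, self.hemisphere)):
            (left if hemi == "left" else right)[pid] = i
        out = []
        for pid in sorted(set(left) & set(right)):
            out.append((pid, left[pid], right[pid]))
        return out

    def pair_indices(self, label: str) -> tuple[int, int]:
        """Indices of a region and its homotopic partner, given either label."""
        i = self.index(label)
        pid = self.pair_id[i]
        for pid_, li, ri in self.pairs():
            if pid_ == pid:
                return li, ri
        raise ValueError(f"region {label!r} has no homotopic partner")

    def pair_label(self, pid: int) -> str:
        """Human-readable name of a bilateral pair (common label stem)."""
        members = [self.labels[i] for i, p in enumerate(self.pair_id) if p == pid]
        if len(members) == 2:
            a, b = members
            stem = _common_stem(a, b)
            if stem:
                return stem
            return f"{a}|{b}"
        return members[0]

    # -- derivation ---------------------------------------------------------
    def remove(self, labels) -> "RegionAtlas":
        """New atlas with the named regions dropped (order preserved)."""
        drop = set(labels)
        unknown = drop - set(self.labels)
        if unknown:
            raise KeyError(f"unknown region label(s): {sorted(unknown)}")
        keep = [i for i, lab in enumerate(self.labels) if lab not in drop]
        return RegionAtlas(
            labels=tuple(self.labels[i] for i in keep),
            hemisphere=tuple(self.hemisphere[i] for i in keep),
            lobe=tuple(self.lobe[i] for i in keep),
            pair_id=tuple(self.pair_id[i] for i in keep),
        )

    def keep_indices(self, labels) -> np.ndarray:
        drop = set(labels)
        return np.array([i for i, lab in enumerate(self.labels) if lab not in drop])

    # -- I/O ----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "hemisphere": self.hemisphere,
                "lobe": self.lobe,
                "pair_id": self.pair_id,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegionAtlas":
        return cls(
            labels=tuple(df["label"].astype(str)),
            hemisphere=tuple(df["hemisphere"].astype(str)),
            lobe=tuple(df["lobe"].astype(str)),
            pair_id=tuple(int(p) for p in df["pair_id"]),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RegionAtlas":
        return cls.from_frame(pd.read_csv(path))


def _common_stem(a: str, b: str) -> str | None:
    """Common pair name for labels like ``thalamus_left`` / ``thalamus_right``."""
    for suffixes in ((" left", " right"), ("_left", "_right"), ("_L", "_R")):
        sa, sb = suffixes
        if a.endswith(sa) and b.endswith(sb):
            stem_a, stem_b = a[: -len(sa)], b[: -len(sb)]
            if stem_a == stem_b:
                return stem_a
        if a.endswith(sb) and b.endswith(sa):
            stem_a, stem_b = a[: -len(sb)], b[: -len(sa)]
            if stem_a == stem_b:
                return stem_a
    return None
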
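"""Minimal plots: R-t curves and seed-ranking bars."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .evaluation import RTCurve, SeedRanking  # noqa: E402


def plot_rt_curves(curves: dict[str, RTCurve], highlight: str | None = None,
                   ax=None):
    """All R-t curves on a common axis; one seed optionally highlighted."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        if label == highlight:
            continue
        ax.plot(curve.times, curve.r_values, color="0.7", lw=0.8)
    if highlight is not None and highlight in curves:
        c = curves[highlight]
        ax.plot(c.times, c.r_values, color="crimson", lw=2, label=highlight)
        ax.legend(frameon=False)
    ax.set_xlabel("model time t (arbitrary units)")
    ax.set_ylabel("Pearson R (model vs atrophy)")
    return ax


def plot_ranking(ranking: SeedRanking, top: int = 20, ax=None):
    """Horizontal bars of the top seeds by peak correlation."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 0.3 * top + 1))
    sub = ranking.table.head(top).iloc[::-1]
    ax.barh(sub["seed"], sub["r_max"], color="steelblue")
    ax.set_xlabel("R_max")
    return ax
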
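"""Static plot export: index radar charts and the accuracy-vs-count curve."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")  # headless export only
import matplotlib.pyplot as plt
import numpy as np

from .indices import INDEX_NAMES

__all__ = ["radar_chart", "accuracy_curve_plot"]


def radar_chart(values: np.ndarray, names: Sequence[str] = INDEX_NAMES, *,
                title: str = "", path=None):
    """Radar chart of (canonicalized) index values, one axis per index."""
    values = np.asarray(values, dtype=np.float64)
    n = len(values)
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(7, 7))
    ax.plot(np.r_[angles, angles[0]], np.r_[values, values[0]], lw=1.5)
    ax.fill(np.r_[angles, angles[0]], np.r_[values, values[0]], alpha=0.2)
    ax.set_xticks(angles)
    ax.set_xticklabels(names, fontsize=7)
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig


def accuracy_curve_plot(curve: Mapping[int, float], *, path=None):
    """Classification accuracy as indices are removed one by one."""
    counts = sorted(curve, reverse=True)
    acc = [100.0 * curve[c] for c in counts]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(counts, acc, marker="o")
    ax.set_xlabel("number of input indices")
    ax.set_ylabel("classification accuracy [%]")
    ax.set_ylim(0, 105)
    ax.invert_xaxis()
    ax.grid(True, alpha=0.3)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
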
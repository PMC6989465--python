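"""Per-frame feature time series: posture P, movement M, body centre G.

For every analysis area ``A_k`` the silhouette pixel count ``P_l`` (posture)
and the normalized movement magnitude ``M_l`` are extracted per frame, and
the body-centre trajectory yields the normalized velocity ``G^v`` and
fluctuation ``G^d``:

.. math::

    M_l = \\frac{\\#\\{(x,y) \\in A_k : O_l(x,y) \\ne O_{l-1}(x,y)\\}}{P^{ave}},
    \\qquad
    G^v_l = \\frac{G_l - G_{l-1}}{\\sqrt{P^{ave}}},
    \\qquad
    G^d_l = \\frac{G_l - G^{ave}}{\\sqrt{P^{ave}}},

with :math:`P^{ave}` a reference whole-body area estimated from the first
``E`` frames and :math:`G^{ave}` the mean centre over the analysis interval.
``M_1 = 0`` and ``G^v_1 = (0, 0)`` by contract (no predecessor frame).

Movement pixels are counted on the *background-difference* masks of adjacent
frames (their symmetric difference); the interframe-difference image stream
is kept for display only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, lfilter

from .segmentation import AreaSet, Rect

__all__ = [
    "FeatureSeries",
    "posture_change",
    "reference_area",
    "movement_change",
    "body_centre",
    "centre_velocity",
    "centre_fluctuation",
    "smooth",
    "compute_features",
]

logger = logging.getLogger(__name__)

AREA_KEYS = tuple(range(1, 10))


def posture_change(bg_mask: np.ndarray, area: Rect) -> int:
    """Posture ``P_l``: silhouette pixel count inside one analysis area."""
    return area.count(bg_mask)


def reference_area(p9: np.ndarray, e: int, mode: str = "mean") -> float:
    """Reference whole-body area ``P_ave`` from the first ``E`` frames.

    ``mode="mean"`` (default) averages ``P_9`` over frames ``1..E``;
    ``mode="max"`` takes the maximum instead (alternative reading of the
    reference definition, exposed for comparison).
    """
    p9 = np.asarray(p9, dtype=np.float64)
    if e < 1 or e > len(p9):
        raise ValueError(f"E={e} out of range for {len(p9)} frames")
    head = p9[:e]
    if not np.any(head > 0):
        raise ValueError("no body detected in the first E frames (P9 all zero)")
    if mode == "mean":
        return float(head.mean())
    if mode == "max":
        return float(head.max())
    raise ValueError(f"unknown reference-area mode {mode!r}")


def movement_change(
    bg_mask: np.ndarray, prev_bg_mask: np.ndarray | None, area: Rect, p_ave: float
) -> float:
    """Movement ``M_l``: changed silhouette pixels in ``A_k``, normalized.

    ``M_1 = 0`` by contract (``prev_bg_mask=None``).
    """
    if p_ave <= 0:
        raise ValueError(f"P_ave must be positive, got {p_ave}")
    if prev_bg_mask is None:
        return 0.0
    ys, xs = area.slice()
    changed = bg_mask[ys, xs] != prev_bg_mask[ys, xs]
    return float(changed.sum()) / p_ave


def body_centre(bg_mask: np.ndarray, area: Rect) -> tuple[float, float]:
    """Centroid (x, y) of the silhouette pixels inside ``area``.

    Raises ``ValueError`` on an empty silhouette (callers flag the frame as
    missing and carry the last valid centre forward).
    """
    ys, xs = area.slice()
    sub = np.asarray(bg_mask[ys, xs]) > 0
    total = sub.sum()
    if total == 0:
        raise ValueError("empty silhouette: centroid undefined")
    rows, cols = np.nonzero(sub)
    return float(cols.mean() + area.x0), float(rows.mean() + area.y0)


def centre_velocity(g: np.ndarray, p_ave: float) -> np.ndarray:
    """Normalized body-centre velocity; first frame is (0, 0) by contract."""
    g = np.asarray(g, dtype=np.float64)
    gv = np.zeros_like(g)
    if len(g) > 1:
        gv[1:] = np.diff(g, axis=0) / np.sqrt(p_ave)
    return gv


def centre_fluctuation(g: np.ndarray, p_ave: float) -> np.ndarray:
    """Normalized deviation of the body centre from its interval mean."""
    g = np.asarray(g, dtype=np.float64)
    return (g - g.mean(axis=0)) / np.sqrt(p_ave)


def smooth(
    series: np.ndarray, cutoff: float, f_s: float, *, zero_phase: bool = True
) -> np.ndarray:
    """Second-order low-pass Butterworth smoothing (DC gain 1).

    Applied zero-phase (forward-backward) by default so per-frame indices do
    not lag; ``zero_phase=False`` gives a single causal pass.
    """
    if cutoff >= f_s / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({f_s / 2} Hz)")
    series = np.asarray(series, dtype=np.float64)
    b, a = butter(2, cutoff / (f_s / 2))
    if zero_phase:
        return filtfilt(b, a, series, axis=0)
    return lfilter(b, a, series, axis=0)


@dataclass
class FeatureSeries:
    """Whole-recording feature series for one segmented video.

    ``P[k]`` and ``M[k]`` are per-area arrays of length ``n_frames``;
    ``G``/``Gv`` are ``(n_frames, 2)`` arrays in (x, y) order.  ``Gd`` is
    interval-dependent and computed later via :func:`centre_fluctuation`.
    """

    P: Dict[int, np.ndarray]
    M: Dict[int, np.ndarray]
    G: np.ndarray
    Gv: np.ndarray
    p_ave: float
    f_s: float
    missing_centre_frames: list[int]

    @property
    def n_frames(self) -> int:
        return len(self.P[9])

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"frame": np.arange(self.n_frames)}
        for k in AREA_KEYS:
            cols[f"P{k}"] = self.P[k]
        for k in AREA_KEYS:
            cols[f"M{k}"] = self.M[k]
        cols["Gx"] = self.G[:, 0]
        cols["Gy"] = self.G[:, 1]
        cols["Gvx"] = self.Gv[:, 0]
        cols["Gvy"] = self.Gv[:, 1]
        return pd.DataFrame(cols)


def compute_features(
    bg_masks: np.ndarray,
    area_set: AreaSet,
    *,
    f_s: float,
    e: int = 10,
    p_ave_mode: str = "mean",
) -> FeatureSeries:
    """Compute P, M, G and G^v for a whole mask stream.

    Movement counts are additive over the quadrants: the counts in
    ``A_1..A_4`` sum to the ``A_9`` count on every frame.  Frames with an
    empty silhouette carry the last valid centre forward (logged).
    """
    n = bg_masks.shape[0]
    p: Dict[int, np.ndarray] = {k: np.empty(n) for k in AREA_KEYS}
    for k, rect in area_set.areas.items():
        ys, xs = rect.slice()
        p[k] = bg_masks[:, ys, xs].sum(axis=(1, 2)).astype(np.float64)

    p_ave = reference_area(p[9], e, mode=p_ave_mode)

    m: Dict[int, np.ndarray] = {}
    changed = np.zeros_like(bg_masks)
    if n > 1:
        changed[1:] = bg_masks[1:] != bg_masks[:-1]
    for k, rect in area_set.areas.items():
        ys, xs = rect.slice()
        m[k] = changed[:, ys, xs].sum(axis=(1, 2)).astype(np.float64) / p_ave

    g = np.zeros((n, 2))
    missing: list[int] = []
    last_valid: tuple[float, float] | None = None
    for l in range(n):
        try:
            last_valid = body_centre(bg_masks[l], area_set.areas[9])
        except ValueError:
            missing.append(l)
        if last_valid is not None:
            g[l] = last_valid
    if last_valid is None:
        raise ValueError("empty silhouette on every frame: no body centre")
    # Frames before the first valid centre inherit it (avoids NaN propagation).
    first_valid = next(i for i in range(n) if i not in set(missing))
    g[:first_valid] = g[first_valid]
    if missing:
        logger.warning("body centre missing on %d frame(s); carried forward", len(missing))

    gv = centre_velocity(g, p_ave)
    return FeatureSeries(P=p, M=m, G=g, Gv=gv, p_ave=p_ave, f_s=f_s,
                         missing_centre_frames=missing)
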
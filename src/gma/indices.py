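"""The 25 per-interval evaluation indices.

Each analysis interval of ``L`` frames is summarized by a 25-entry index
vector covering four aspects of the movement:

* **magnitude** — movement frequency ``I1`` (percentage of frames with
  supra-threshold movement), strength ``I2`` (mean supra-threshold ``M``),
  and count ``I3`` (number of movement episodes per frame), computed for the
  upper (``A_5``) and lower (``A_6``) body;
* **balance** — upper/lower ratios ``I4`` (of ``I1``) and ``I5`` (of ``I2``),
  and the symmetry ``I6`` (windowed zero-lag cross-correlation of the two
  ``M`` series);
* **rhythm** — spectral centre frequency and a spread companion for the
  ``M`` series (``I7``, ``I8``), the centre velocity ``G^v`` (``I9``,
  ``I10``) and the centre fluctuation ``G^d`` (``I11``, ``I12``), per axis;
* **body centre** — mean magnitudes of ``G^v`` (``I13``) and ``G^d``
  (``I14``), per axis.

Rhythm indices cut the interval into ``L / L_f`` subintervals; the centre
index is the mean of per-subinterval centre frequencies and the companion
index is, by default, the mean of the reciprocals of the per-subinterval
second moments (``spread_mode="reciprocal"``); the across-subinterval
standard deviation of the centre frequency is available as
``spread_mode="sd"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import welch

from .features import FeatureSeries, centre_fluctuation, centre_velocity, smooth

__all__ = [
    "SpectralConfig",
    "IndexVector",
    "INDEX_NAMES",
    "movement_frequency",
    "movement_strength",
    "movement_count",
    "balance_ratio",
    "symmetry",
    "power_spectrum",
    "spectral_centre",
    "spectral_spread",
    "rhythm_indices",
    "centre_magnitude",
    "compute_index_vector",
    "compute_indices",
    "indices_to_dataframe",
]

logger = logging.getLogger(__name__)

#: Canonical ordering of the 25 indices (positionally stable, so the
#: canonicalization parameters mu_j / sigma_j line up across runs).
INDEX_NAMES: tuple[str, ...] = (
    "I1_A5", "I2_A5", "I3_A5", "I7_A5", "I8_A5",
    "I1_A6", "I2_A6", "I3_A6", "I7_A6", "I8_A6",
    "I4_56", "I5_56", "I6_56",
    "I9_x", "I9_y", "I10_x", "I10_y",
    "I11_x", "I11_y", "I12_x", "I12_y",
    "I13_x", "I13_y", "I14_x", "I14_y",
)


@dataclass
class SpectralConfig:
    """Spectral-analysis parameters for the rhythm and symmetry indices."""

    f_max: float = 5.0           # Hz; upper analysis band edge
    fft_window: int = 128        # samples per FFT segment
    fft_overlap: int = 127       # segment overlap (step 1)
    corr_window: int = 300       # symmetry correlation window
    corr_overlap: int = 299
    subinterval: int = 300       # L_f, frames per rhythm subinterval
    spread_mode: str = "reciprocal"  # or "sd"

    def validate(self, interval_length: int) -> None:
        if self.subinterval > interval_length or interval_length % self.subinterval:
            raise ValueError(
                f"interval length {interval_length} must be a multiple of "
                f"L_f={self.subinterval}"
            )


@dataclass
class IndexVector:
    """One analysis interval's 25 evaluation indices, canonically ordered."""

    values: np.ndarray
    start_frame: int
    length: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(INDEX_NAMES),):
            raise ValueError(f"expected {len(INDEX_NAMES)} indices, got {self.values.shape}")

    def __getitem__(self, name: str) -> float:
        return float(self.values[INDEX_NAMES.index(name)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(INDEX_NAMES, map(float, self.values)))


# ---------------------------------------------------------------------------
# movement magnitude


def movement_frequency(m: np.ndarray, m_th: float) -> float:
    """``I1``: percentage of frames with ``M >= M_th`` (0..100)."""
    m = np.asarray(m)
    return 100.0 * float(np.count_nonzero(m >= m_th)) / len(m)


def movement_strength(m: np.ndarray, m_th: float) -> float:
    """``I2``: mean of ``M`` over supra-threshold frames; 0 if none."""
    m = np.asarray(m)
    supra = m[m >= m_th]
    if supra.size == 0:
        return 0.0
    return float(supra.mean())


def movement_count(m: np.ndarray, m_th: float) -> float:
    """``I3``: number of maximal supra-threshold episodes divided by ``L``.

    An episode still active at the last frame is counted once (its end is
    clipped to ``L``).
    """
    m = np.asarray(m)
    above = m >= m_th
    starts = np.count_nonzero(above[1:] & ~above[:-1]) + int(above[0])
    return float(starts) / len(m)


# ---------------------------------------------------------------------------
# movement balance


def balance_ratio(numerator: float, denominator: float) -> float:
    """``I4``/``I5``: ratio between areas; 0 when the denominator is 0."""
    if denominator == 0:
        return 0.0
    return numerator / denominator


def symmetry(
    m1: np.ndarray, m2: np.ndarray, window: int = 300, overlap: int = 299
) -> float:
    """``I6``: windowed zero-lag normalized cross-correlation, averaged.

    Pearson correlation is computed in sliding windows (default width 300,
    step 1) and averaged; windows where either series has zero variance are
    skipped (logged).  Bounded in [-1, 1].
    """
    x = np.asarray(m1, dtype=np.float64)
    y = np.asarray(m2, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    n = len(x)
    w = min(window, n)
    step = max(w - overlap, 1)

    def rolling(v: np.ndarray) -> np.ndarray:
        c = np.concatenate([[0.0], np.cumsum(v)])
        return c[w:] - c[:-w]

    sx, sy = rolling(x), rolling(y)
    sxx, syy, sxy = rolling(x * x), rolling(y * y), rolling(x * y)
    vx = w * sxx - sx**2
    vy = w * syy - sy**2
    cov = w * sxy - sx * sy
    idx = np.arange(0, n - w + 1, step)
    vx, vy, cov = vx[idx], vy[idx], cov[idx]
    tol = 1e-12 * w * max(float(np.max(np.abs(x)) ** 2), float(np.max(np.abs(y)) ** 2), 1.0)
    valid = (vx > tol) & (vy > tol)
    if not np.any(valid):
        logger.info("symmetry: all %d windows have zero variance; returning 0", len(idx))
        return 0.0
    if not np.all(valid):
        logger.info("symmetry: skipped %d zero-variance window(s)", int(np.sum(~valid)))
    r = cov[valid] / np.sqrt(vx[valid] * vy[valid])
    return float(np.clip(r, -1.0, 1.0).mean())


# ---------------------------------------------------------------------------
# movement rhythm


def power_spectrum(
    x: np.ndarray, f_s: float, window: int = 128, overlap: int = 127
) -> tuple[np.ndarray, np.ndarray]:
    """Averaged-periodogram PSD (Hann taper, constant detrend), normalized
    by its maximum.  Returns ``(frequencies, normalized PSD)``."""
    x = np.asarray(x, dtype=np.float64)
    nperseg = min(window, len(x))
    if nperseg < window:
        logger.info("power_spectrum: window clipped to series length %d", nperseg)
    noverlap = min(overlap, nperseg - 1)
    f, p = welch(x, fs=f_s, window="hann", nperseg=nperseg, noverlap=noverlap,
                 detrend="constant")
    peak = p.max()
    if peak > 0:
        p = p / peak
    return f, p


def spectral_centre(f: np.ndarray, p: np.ndarray, f_max: float) -> float:
    """Power-weighted mean frequency over ``[0, f_max]`` (``F_cntr``)."""
    f = np.asarray(f, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    band = f <= f_max
    total = p[band].sum()
    if total <= 0:
        raise ValueError("all-zero power spectrum: centre frequency undefined")
    return float((f[band] * p[band]).sum() / total)


def spectral_spread(
    f: np.ndarray, p: np.ndarray, f_max: float, centre: float | None = None
) -> float:
    """Power-weighted SD of frequency around ``F_cntr`` (``D_cntr``)."""
    f = np.asarray(f, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if centre is None:
        centre = spectral_centre(f, p, f_max)
    band = f <= f_max
    total = p[band].sum()
    if total <= 0:
        raise ValueError("all-zero power spectrum: spread undefined")
    return float(np.sqrt((p[band] * (f[band] - centre) ** 2).sum() / total))


def rhythm_indices(
    x: np.ndarray, f_s: float, cfg: SpectralConfig
) -> tuple[float, float]:
    """Centre-frequency index and its spread companion for one signal.

    The interval is cut into ``L / L_f`` subintervals.  The centre index is
    the mean of per-subinterval ``F_cntr``; the companion is the mean of
    ``1 / D_cntr`` (default) or the SD of the centre frequencies
    (``spread_mode="sd"``).  Subintervals with a degenerate (all-zero)
    spectrum are skipped; ``D_cntr = 0`` subintervals are excluded from the
    reciprocal mean.  Returns ``(0.0, 0.0)`` when every subinterval is
    degenerate (flagged in the log).
    """
    x = np.asarray(x, dtype=np.float64)
    cfg.validate(len(x))
    centres: list[float] = []
    spreads: list[float] = []
    for start in range(0, len(x), cfg.subinterval):
        seg = x[start : start + cfg.subinterval]
        f, p = power_spectrum(seg, f_s, cfg.fft_window, cfg.fft_overlap)
        try:
            c = spectral_centre(f, p, cfg.f_max)
        except ValueError:
            logger.info("rhythm: degenerate spectrum in subinterval at %d; skipped", start)
            continue
        centres.append(c)
        spreads.append(spectral_spread(f, p, cfg.f_max, c))
    if not centres:
        logger.info("rhythm: all subintervals degenerate; indices set to 0")
        return 0.0, 0.0
    centre_idx = float(np.mean(centres))
    if cfg.spread_mode == "sd":
        spread_idx = float(np.std(centres))
    else:
        recip = [1.0 / d for d in spreads if d > 0]
        spread_idx = float(np.mean(recip)) if recip else 0.0
    return centre_idx, spread_idx


# ---------------------------------------------------------------------------
# body centre


def centre_magnitude(series: np.ndarray, *, signed: bool = False) -> float:
    """``I13``/``I14``: mean magnitude of a centre signal over the interval.

    The mean absolute value is the default ("total magnitude" semantics);
    ``signed=True`` gives the plain mean instead.
    """
    series = np.asarray(series, dtype=np.float64)
    if signed:
        return float(series.mean())
    return float(np.abs(series).mean())


# ---------------------------------------------------------------------------
# assembly


def compute_index_vector(
    m_upper: np.ndarray,
    m_lower: np.ndarray,
    gv: np.ndarray,
    gd: np.ndarray,
    f_s: float,
    cfg: SpectralConfig | None = None,
    m_th: float = 0.05,
    start_frame: int = 0,
    *,
    signed_magnitude: bool = False,
) -> IndexVector:
    """Assemble the full 25-entry index vector for one analysis interval.

    ``m_upper``/``m_lower`` are the (smoothed) movement series of ``A_5`` and
    ``A_6``; ``gv``/``gd`` the ``(L, 2)`` centre velocity and fluctuation.
    """
    cfg = cfg or SpectralConfig()
    L = len(m_upper)
    if not (len(m_lower) == len(gv) == len(gd) == L):
        raise ValueError("interval series must share one length")

    vals: dict[str, float] = {}
    for name, m in (("A5", np.asarray(m_upper)), ("A6", np.asarray(m_lower))):
        vals[f"I1_{name}"] = movement_frequency(m, m_th)
        vals[f"I2_{name}"] = movement_strength(m, m_th)
        vals[f"I3_{name}"] = movement_count(m, m_th)
        i7, i8 = rhythm_indices(m, f_s, cfg)
        vals[f"I7_{name}"] = i7
        vals[f"I8_{name}"] = i8

    vals["I4_56"] = balance_ratio(vals["I1_A5"], vals["I1_A6"])
    vals["I5_56"] = balance_ratio(vals["I2_A5"], vals["I2_A6"])
    vals["I6_56"] = symmetry(m_upper, m_lower, cfg.corr_window, cfg.corr_overlap)

    for label, sig in (("9", gv), ("11", gd)):
        for ax, col in (("x", 0), ("y", 1)):
            c, s = rhythm_indices(sig[:, col], f_s, cfg)
            vals[f"I{label}_{ax}"] = c
            vals[f"I{int(label) + 1}_{ax}"] = s

    for label, sig in (("13", gv), ("14", gd)):
        for ax, col in (("x", 0), ("y", 1)):
            vals[f"I{label}_{ax}"] = centre_magnitude(sig[:, col], signed=signed_magnitude)

    values = np.array([vals[name] for name in INDEX_NAMES])
    return IndexVector(values, start_frame, L)


def compute_indices(
    features: FeatureSeries,
    *,
    interval_length: int = 900,
    step: int | None = None,
    cfg: SpectralConfig | None = None,
    m_th: float = 0.05,
    f_cut_m: float = 10.0,
    f_cut_g: float = 5.0,
    smoothing: bool = True,
    zero_phase: bool = True,
) -> list[IndexVector]:
    """Compute index vectors on every analysis interval of a recording.

    Intervals start every ``step`` frames (default: non-overlapping,
    ``step = interval_length``; ``step=1`` gives the sliding mode).  The
    movement series are low-pass filtered at ``f_cut_m`` and the centre
    trajectory at ``f_cut_g`` before analysis; velocity and fluctuation are
    derived from the smoothed trajectory.  A trailing fragment shorter than
    ``interval_length`` is skipped (logged).
    """
    cfg = cfg or SpectralConfig()
    step = step or interval_length
    n = features.n_frames
    if n < interval_length:
        logger.warning("recording (%d frames) shorter than one interval (%d); no indices",
                       n, interval_length)
        return []

    if smoothing:
        m5 = smooth(features.M[5], f_cut_m, features.f_s, zero_phase=zero_phase)
        m6 = smooth(features.M[6], f_cut_m, features.f_s, zero_phase=zero_phase)
        g = smooth(features.G, f_cut_g, features.f_s, zero_phase=zero_phase)
    else:
        m5, m6, g = features.M[5], features.M[6], features.G
    gv = centre_velocity(g, features.p_ave)

    out: list[IndexVector] = []
    for start in range(0, n - interval_length + 1, step):
        sl = slice(start, start + interval_length)
        gd = centre_fluctuation(g[sl], features.p_ave)
        out.append(
            compute_index_vector(
                m5[sl], m6[sl], gv[sl], gd, features.f_s, cfg, m_th, start_frame=start
            )
        )
    leftover = (n - interval_length) % step if step else 0
    if n % step and n - interval_length >= 0 and leftover:
        logger.info("trailing %d frame(s) shorter than an interval; skipped", leftover)
    return out


def indices_to_dataframe(vectors: Sequence[IndexVector]) -> pd.DataFrame:
    """Tabulate index vectors: one row per interval, canonical column order."""
    rows = []
    for v in vectors:
        row = {"start_frame": v.start_frame, "length": v.length}
        row.update(v.as_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=["start_frame", "length", *INDEX_NAMES])
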
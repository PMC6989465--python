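"""Independent brute-force reference implementations.

Every function here recomputes a pipeline quantity with plain Python loops
straight from its definition, deliberately sharing no code with the package.
They are slow and only meant for small fixtures.
"""

from __future__ import annotations

import numpy as np


def luma_loop(rgb: np.ndarray) -> np.ndarray:
    h, w, _ = rgb.shape
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            r, g, b = (float(v) for v in rgb[y, x, :3])
            out[y, x] = 0.299 * r + 0.587 * g + 0.114 * b
    return out


def binarize_loop(frame: np.ndarray, reference: np.ndarray, threshold: float) -> np.ndarray:
    h, w = frame.shape
    out = np.zeros((h, w), dtype=np.uint8)
    for y in range(h):
        for x in range(w):
            if abs(float(frame[y, x]) - float(reference[y, x])) >= threshold:
                out[y, x] = 1
    return out


def posture_loop(mask: np.ndarray, rect) -> int:
    total = 0
    for y in range(rect.y0, rect.y1):
        for x in range(rect.x0, rect.x1):
            if mask[y, x]:
                total += 1
    return total


def movement_loop(mask: np.ndarray, prev: np.ndarray | None, rect, p_ave: float) -> float:
    if prev is None:
        return 0.0
    changed = 0
    for y in range(rect.y0, rect.y1):
        for x in range(rect.x0, rect.x1):
            if bool(mask[y, x]) != bool(prev[y, x]):
                changed += 1
    return changed / p_ave


def centroid_loop(mask: np.ndarray, rect) -> tuple[float, float]:
    sx = sy = n = 0
    for y in range(rect.y0, rect.y1):
        for x in range(rect.x0, rect.x1):
            if mask[y, x]:
                sx += x
                sy += y
                n += 1
    if n == 0:
        raise ValueError("empty")
    return sx / n, sy / n


def velocity_loop(g: np.ndarray, p_ave: float) -> np.ndarray:
    out = np.zeros_like(np.asarray(g, dtype=float))
    for l in range(1, len(g)):
        for ax in range(2):
            out[l, ax] = (g[l, ax] - g[l - 1, ax]) / np.sqrt(p_ave)
    return out


def fluctuation_loop(g: np.ndarray, p_ave: float) -> np.ndarray:
    g = np.asarray(g, dtype=float)
    mean = [sum(g[:, ax]) / len(g) for ax in range(2)]
    out = np.zeros_like(g)
    for l in range(len(g)):
        for ax in range(2):
            out[l, ax] = (g[l, ax] - mean[ax]) / np.sqrt(p_ave)
    return out


# -- indices ----------------------------------------------------------------


def i1_loop(m, m_th) -> float:
    hits = sum(1 for v in m if v >= m_th)
    return 100.0 * hits / len(m)


def i2_loop(m, m_th) -> float:
    vals = [v for v in m if v >= m_th]
    return sum(vals) / len(vals) if vals else 0.0


def i3_loop(m, m_th) -> float:
    q = 0
    inside = False
    for v in m:
        if v >= m_th and not inside:
            q += 1
            inside = True
        elif v < m_th:
            inside = False
    return q / len(m)


def i6_loop(m1, m2, window, overlap) -> float:
    n = len(m1)
    w = min(window, n)
    step = max(w - overlap, 1)
    rs = []
    for start in range(0, n - w + 1, step):
        a = np.asarray(m1[start : start + w], dtype=float)
        b = np.asarray(m2[start : start + w], dtype=float)
        va = ((a - a.mean()) ** 2).sum()
        vb = ((b - b.mean()) ** 2).sum()
        if va <= 1e-12 * w or vb <= 1e-12 * w:
            continue
        rs.append(((a - a.mean()) * (b - b.mean())).sum() / np.sqrt(va * vb))
    return float(np.mean(rs)) if rs else 0.0


def magnitude_loop(series, signed=False) -> float:
    if signed:
        return sum(series) / len(series)
    return sum(abs(v) for v in series) / len(series)


# -- spectra ----------------------------------------------------------------


def welch_loop(x: np.ndarray, f_s: float, window: int, overlap: int):
    """Averaged modified periodogram: periodic Hann taper, per-segment mean
    removal, one-sided with doubling of interior bins.  Absolute scale
    arbitrary (centre/spread are scale-invariant)."""
    x = np.asarray(x, dtype=float)
    nperseg = min(window, len(x))
    noverlap = min(overlap, nperseg - 1)
    step = nperseg - noverlap
    taper = np.array(
        [0.5 - 0.5 * np.cos(2 * np.pi * i / nperseg) for i in range(nperseg)]
    )
    n_bins = nperseg // 2 + 1
    acc = np.zeros(n_bins)
    count = 0
    for start in range(0, len(x) - nperseg + 1, step):
        seg = x[start : start + nperseg]
        seg = seg - seg.mean()
        spec = np.fft.rfft(seg * taper)
        p = np.abs(spec) ** 2
        p[1:] *= 2.0
        if nperseg % 2 == 0:
            p[-1] /= 2.0
        acc += p
        count += 1
    freqs = np.array([i * f_s / nperseg for i in range(n_bins)])
    return freqs, acc / count


def centre_loop(f, p, f_max) -> float:
    num = den = 0.0
    for fi, pi in zip(f, p):
        if fi <= f_max:
            num += fi * pi
            den += pi
    return num / den


def spread_loop(f, p, f_max, centre) -> float:
    num = den = 0.0
    for fi, pi in zip(f, p):
        if fi <= f_max:
            num += pi * (fi - centre) ** 2
            den += pi
    return float(np.sqrt(num / den))


def rhythm_loop(x, f_s, subinterval, f_max, window, overlap, spread_mode="reciprocal"):
    """Per-subinterval centre frequency / reciprocal spread, averaged."""
    centres, spreads = [], []
    for start in range(0, len(x), subinterval):
        seg = np.asarray(x[start : start + subinterval], dtype=float)
        f, p = welch_loop(seg, f_s, window, overlap)
        if p.max() > 0:
            p = p / p.max()
        band_power = sum(pi for fi, pi in zip(f, p) if fi <= f_max)
        if band_power <= 0:
            continue
        c = centre_loop(f, p, f_max)
        centres.append(c)
        spreads.append(spread_loop(f, p, f_max, c))
    if not centres:
        return 0.0, 0.0
    if spread_mode == "sd":
        return float(np.mean(centres)), float(np.std(centres))
    recip = [1.0 / d for d in spreads if d > 0]
    return float(np.mean(centres)), (float(np.mean(recip)) if recip else 0.0)
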
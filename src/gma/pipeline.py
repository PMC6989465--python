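"""End-to-end orchestration: video -> masks -> areas -> features -> indices
-> classification, plus file import/export used by the CLI.

All result files are deterministic given the configuration and seeds: no
timestamps or environment data are written, so repeated runs are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .classification import (
    LLGMN,
    CanonicalizationParams,
    canonicalize,
    classify_interval,
    fit_canonicalization,
)
from .config import ConfigError, PipelineConfig
from .features import FeatureSeries, compute_features
from .indices import (
    INDEX_NAMES,
    IndexVector,
    SpectralConfig,
    compute_indices,
    indices_to_dataframe,
)
from .preprocessing import FrameSequence, compute_masks, temporal_median_background, to_grayscale
from .segmentation import AreaSet, analysis_area, divide_areas, fit_ellipse

__all__ = [
    "DataError",
    "load_frames",
    "save_frames",
    "AnalysisResult",
    "analyze",
    "train",
    "classify_indices",
]

logger = logging.getLogger(__name__)


class DataError(RuntimeError):
    """Unreadable or unusable input data."""


# ---------------------------------------------------------------------------
# frame I/O


def load_frames(path, frame_rate: float) -> FrameSequence:
    """Read a video container or a directory of image frames.

    Directories are read as sorted image files (PNG/JPEG); anything else is
    handed to imageio as a container.
    """
    p = Path(path)
    if not p.exists():
        raise DataError(f"input not found: {p}")
    try:
        if p.is_dir():
            files = sorted(
                f for f in p.iterdir() if f.suffix.lower() in (".png", ".jpg", ".jpeg", ".tif")
            )
            if not files:
                raise DataError(f"no image frames found in directory {p}")
            frames = [iio.imread(f) for f in files]
        else:
            frames = list(iio.imiter(p))
    except DataError:
        raise
    except Exception as exc:  # imageio raises various backend errors
        raise DataError(f"cannot read frames from {p}: {exc}") from exc
    return to_grayscale(frames, frame_rate)


def save_frames(seq: FrameSequence, directory) -> list[Path]:
    """Write frames as zero-padded PNGs; returns the file paths."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    width = max(len(str(seq.n_frames - 1)), 5)
    paths = []
    for i, frame in enumerate(seq.frames):
        f = d / f"frame_{i:0{width}d}.png"
        iio.imwrite(f, np.clip(frame, 0, 255).astype(np.uint8))
        paths.append(f)
    return paths


# ---------------------------------------------------------------------------
# analysis


@dataclass
class AnalysisResult:
    features: FeatureSeries
    index_vectors: list[IndexVector]
    area_set: AreaSet

    @property
    def index_table(self) -> pd.DataFrame:
        return indices_to_dataframe(self.index_vectors)

    def save(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "features": out / "features.csv",
            "indices": out / "indices.csv",
            "areas": out / "areas.json",
        }
        self.features.to_dataframe().to_csv(paths["features"], index=False)
        self.index_table.to_csv(paths["indices"], index=False)
        paths["areas"].write_text(json.dumps(self.area_set.to_dict(), indent=1))
        return paths


def _resolve_background(seq: FrameSequence, cfg: PipelineConfig) -> np.ndarray:
    bg = cfg.background
    if isinstance(bg, (int, float)):
        return np.full((seq.height, seq.width), float(bg))
    if bg == "median":
        return temporal_median_background(seq)
    p = Path(str(bg))
    if not p.exists():
        raise ConfigError(f"background frame not found: {p}")
    img = iio.imread(p)
    if img.ndim == 3:
        img = to_grayscale([img], seq.frame_rate).frames[0]
    return np.asarray(img, dtype=np.float64)


def analyze(
    seq: FrameSequence,
    cfg: PipelineConfig,
    *,
    exclude_intervals: list[tuple[int, int]] | None = None,
) -> AnalysisResult:
    """Run preprocessing, segmentation, features and indices on a recording.

    ``exclude_intervals`` are frame ranges (e.g. crying/sleeping periods,
    supplied by the user) whose analysis intervals are dropped.
    """
    cfg.validate(require_threshold=True)
    background = _resolve_background(seq, cfg)
    bg_masks, _ = compute_masks(
        seq, background, cfg.threshold, morphological_opening=cfg.morphological_opening
    )
    if not bg_masks.any():
        raise DataError("empty silhouette on every frame (threshold too high?)")

    # Ellipse fitted once on the first usable frame; areas stay fixed.
    fit = None
    for l in range(seq.n_frames):
        try:
            fit = fit_ellipse(bg_masks[l])
            break
        except Exception:
            continue
    if fit is None:
        raise DataError("no frame with a fittable silhouette")
    rect_b, rect_a = analysis_area(
        fit, (seq.height, seq.width), cfg.t_a1, cfg.t_a2, cfg.t_a3, cfg.head_end
    )
    area_set = divide_areas(rect_a, cfg.gamma, cfg.delta, cfg.head_end, rect_b=rect_b)

    features = compute_features(
        bg_masks, area_set, f_s=seq.frame_rate, e=cfg.e, p_ave_mode=cfg.p_ave_mode
    )
    spectral = SpectralConfig(
        f_max=cfg.f_max,
        fft_window=cfg.fft_window,
        fft_overlap=cfg.fft_overlap,
        corr_window=cfg.corr_window,
        corr_overlap=cfg.corr_overlap,
        subinterval=cfg.subinterval,
        spread_mode=cfg.spread_mode,
    )
    vectors = compute_indices(
        features,
        interval_length=cfg.interval_length,
        step=cfg.effective_step,
        cfg=spectral,
        m_th=cfg.m_th,
        f_cut_m=cfg.f_cut_m,
        f_cut_g=cfg.f_cut_g,
    )
    if exclude_intervals:
        def excluded(v: IndexVector) -> bool:
            end = v.start_frame + v.length
            return any(s < end and v.start_frame < e for s, e in exclude_intervals)

        kept = [v for v in vectors if not excluded(v)]
        logger.info("excluded %d interval(s) via mask file", len(vectors) - len(kept))
        vectors = kept
    return AnalysisResult(features, vectors, area_set)


# ---------------------------------------------------------------------------
# training / classification on index tables


def _index_matrix(df: pd.DataFrame) -> np.ndarray:
    missing = [c for c in INDEX_NAMES if c not in df.columns]
    if missing:
        raise DataError(f"index table lacks columns: {missing}")
    return df.loc[:, list(INDEX_NAMES)].to_numpy(dtype=np.float64)


def train(
    index_df: pd.DataFrame,
    labels: np.ndarray,
    cfg: PipelineConfig,
    *,
    reference_labels: tuple[int, ...] = (1, 2),
) -> tuple[CanonicalizationParams, LLGMN]:
    """Fit canonicalization on the normal-GM reference rows and train the LLGMN.

    ``labels`` are GM types 1..4; rows with a label in ``reference_labels``
    (default: the normal types WM and FM) define the canonicalization.
    """
    x = _index_matrix(index_df)
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(x):
        raise DataError("label count does not match index rows")
    ref = x[np.isin(labels, reference_labels)]
    if len(ref) < 2:
        raise DataError("need at least 2 normal-GM reference samples for canonicalization")
    params = fit_canonicalization(ref)
    z = canonicalize(x, params)
    model = LLGMN(
        n_classes=4,
        n_components=cfg.n_components,
        l2=cfg.l2,
        max_iter=cfg.max_iter,
        seed=cfg.seed,
    )
    model.fit(z, labels - 1)
    return params, model


def classify_indices(
    index_df: pd.DataFrame,
    params: CanonicalizationParams,
    model: LLGMN,
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """Classify each analysis interval of an index table.

    Returns one row per interval: start frame, posteriors ``Y1..Y4``,
    entropy ``S``, assigned type and rejection reason.
    """
    x = _index_matrix(index_df)
    z = canonicalize(x, params)
    posteriors = model.predict_proba(z)
    rows = []
    for i in range(len(x)):
        res = classify_interval(
            posteriors[i : i + 1],
            s_th=cfg.s_th,
            i1_upper=float(index_df.iloc[i]["I1_A5"]),
            i1_lower=float(index_df.iloc[i]["I1_A6"]),
            entropy_base=cfg.entropy_base,
        )
        row = {
            "start_frame": int(index_df.iloc[i].get("start_frame", i)),
            **{f"Y{c + 1}": res.posterior[c] for c in range(4)},
            "S": res.entropy,
            "type": res.gm_type,
            "label": res.label,
            "reason": res.reason,
        }
        rows.append(row)
    return pd.DataFrame(rows)
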
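"""Synthetic overhead videos and labelled index samples with ground truth.

No clinical recordings ship with this package, so every downstream stage is
exercised on synthetic data whose ground truth is known by construction:

* :func:`generate_video` renders an elliptical trunk with four limb blobs on
  a unicolor background, one blob per body quadrant, each sweeping back and
  forth at a controllable frequency and stroke length, plus optional
  body-centre drift and i.i.d. Gaussian pixel noise.
* :func:`generate_index_samples` draws labelled 25-dimensional index vectors
  from per-class Gaussian distributions — a stand-in for clinically labelled
  index samples when training and evaluating the classifier.

Limb kinematics are *strokes*, not sinusoidal positions: within each period
the blob sweeps one way with speed envelope ``(1 - cos(2 pi f t)) / 2`` and
reverses direction at the zero-speed instants.  The speed magnitude — and
hence the movement-magnitude signal ``M`` extracted downstream — is then a
pure sinusoid at the nominal limb frequency ``f``, so the rhythm indices
have an exact ground truth.  (A sinusoidal *position* would concentrate the
power of ``|v|`` at ``2f`` instead.)

Quadrant labels (``UL``/``UR``/``LL``/``LR``) are in image coordinates with
the head at the top of the frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Sequence

import numpy as np

from .preprocessing import FrameSequence

__all__ = [
    "LimbSpec",
    "MotionScenario",
    "GroundTruth",
    "ScenarioError",
    "generate_video",
    "generate_index_samples",
    "gaussian_class_specs",
    "informative_noise_specs",
    "bayes_accuracy",
]

LIMB_REGIONS = ("UL", "UR", "LL", "LR")


class ScenarioError(ValueError):
    """Raised when a scenario violates its invariants (e.g. body leaves frame)."""


@dataclass
class LimbSpec:
    """One oscillating limb blob.

    ``frequency`` is the stroke repetition rate in Hz, ``amplitude`` the
    stroke length in pixels, ``duty`` the active fraction of each period
    (1.0 = continuous strokes).
    """

    region: str
    frequency: float
    amplitude: float
    duty: float = 1.0

    def __post_init__(self) -> None:
        if self.region not in LIMB_REGIONS:
            raise ScenarioError(f"region must be one of {LIMB_REGIONS}, got {self.region!r}")
        if self.amplitude < 0:
            raise ScenarioError("amplitude must be non-negative")
        if not 0 < self.duty <= 1:
            raise ScenarioError("duty must lie in (0, 1]")


def _default_limbs() -> list[LimbSpec]:
    # Typical writhing-range stroke rates, one distinct frequency per limb.
    return [
        LimbSpec("UL", 1.0, 30.0),
        LimbSpec("UR", 1.3, 30.0),
        LimbSpec("LL", 1.7, 35.0),
        LimbSpec("LR", 2.1, 35.0),
    ]


@dataclass
class MotionScenario:
    """Full description of one synthetic recording.

    Defaults emulate the recording setup: a 720x480 overhead view at 30 Hz
    with the infant's trunk rendered as a vertical ellipse (head at the top),
    a 30-second take (900 frames), bright body on a dark unicolor sheet, and
    mild sensor noise.
    """

    frame_size: tuple[int, int] = (480, 720)  # (H, W)
    body_axes: tuple[float, float] = (300.0, 150.0)  # (alpha_true, beta_true) px
    body_centre: tuple[float, float] | None = None  # defaults to frame centre
    drift_amplitude: tuple[float, float] = (0.0, 0.0)  # px, sinusoidal drift
    drift_frequency: float = 0.05  # Hz
    limbs: list[LimbSpec] = field(default_factory=_default_limbs)
    limb_radius: float | None = None  # px; default beta_true / 6
    noise_sd: float = 2.0  # brightness units
    background_level: float = 60.0
    body_level: float = 200.0
    n_frames: int = 900
    frame_rate: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.body_centre is None:
            h, w = self.frame_size
            self.body_centre = (w / 2.0, h / 2.0)
        if self.limb_radius is None:
            self.limb_radius = self.body_axes[1] / 6.0
        self.validate()

    def validate(self) -> None:
        if self.n_frames < 1 or self.frame_rate <= 0:
            raise ScenarioError("need n_frames >= 1 and frame_rate > 0")
        for limb in self.limbs:
            if not 0 < limb.frequency < self.frame_rate / 2:
                raise ScenarioError(
                    f"limb {limb.region}: frequency {limb.frequency} Hz outside "
                    f"(0, {self.frame_rate / 2}) Hz"
                )
        h, w = self.frame_size
        alpha, beta = self.body_axes
        dx, dy = self.drift_amplitude
        r = self.limb_radius
        cx, cy = self.body_centre
        # exact silhouette extents: trunk plus each limb's full stroke sweep
        x_lo, x_hi = cx - beta / 2, cx + beta / 2
        y_lo, y_hi = cy - alpha / 2, cy + alpha / 2
        for limb in self.limbs:
            bx, by = _limb_base(limb.region, (cx, cy), alpha, beta, r)
            ux, uy = _LIMB_DIRECTIONS[limb.region]
            for s in (0.0, limb.amplitude):
                x_lo = min(x_lo, bx + ux * s - r)
                x_hi = max(x_hi, bx + ux * s + r)
                y_lo = min(y_lo, by + uy * s - r)
                y_hi = max(y_hi, by + uy * s + r)
        if x_lo - dx < 1 or x_hi + dx > w - 2 or y_lo - dy < 1 or y_hi + dy > h - 2:
            raise ScenarioError(
                "body silhouette can leave the frame under this scenario; "
                "shrink the body, strokes, or drift, or enlarge the frame"
            )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["limbs"] = [asdict(l) for l in self.limbs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MotionScenario":
        d = dict(d)
        if "limbs" in d:
            d["limbs"] = [LimbSpec(**l) for l in d["limbs"]]
        for key in ("frame_size", "body_axes", "body_centre", "drift_amplitude"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-frame truths of a rendered scenario, known by construction."""

    limb_frequencies: Dict[str, float]
    centroid: np.ndarray          # (n, 2) silhouette centroid (x, y), noiseless
    silhouette_area: np.ndarray   # (n,) pixel counts
    body_centre_path: np.ndarray  # (n, 2) nominal trunk centre

    def to_json(self, path) -> None:
        payload = {
            "limb_frequencies": self.limb_frequencies,
            "centroid": self.centroid.tolist(),
            "silhouette_area": self.silhouette_area.tolist(),
            "body_centre_path": self.body_centre_path.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            d["limb_frequencies"],
            np.array(d["centroid"]),
            np.array(d["silhouette_area"]),
            np.array(d["body_centre_path"]),
        )


def _stroke_position(t: np.ndarray, frequency: float, amplitude: float, duty: float) -> np.ndarray:
    """Back-and-forth stroke displacement in [0, amplitude].

    Within each period the blob travels ``amplitude`` with speed envelope
    ``(1 - cos(2 pi tau / duty)) / 2`` during the active fraction, then rests;
    direction alternates each period, so reversals happen at zero speed.
    """
    phase = t * frequency
    k = np.floor(phase).astype(int)
    tau = phase - k
    u = np.where(
        tau < duty,
        (tau / duty) - np.sin(2 * np.pi * tau / duty) / (2 * np.pi),
        1.0,
    )
    return amplitude * np.where(k % 2 == 0, u, 1.0 - u)


# outward stroke directions per quadrant (image coords, head at top)
_LIMB_DIRECTIONS = {"UL": (-1.0, 0.0), "UR": (1.0, 0.0), "LL": (0.0, 1.0), "LR": (0.0, 1.0)}


def _limb_base(region: str, centre: tuple[float, float], alpha: float, beta: float,
               radius: float) -> tuple[float, float]:
    cx, cy = centre
    a, b = alpha / 2.0, beta / 2.0
    if region == "UL":
        return cx - (b + radius), cy - 0.45 * a
    if region == "UR":
        return cx + (b + radius), cy - 0.45 * a
    if region == "LL":
        return cx - 0.55 * b, cy + a + 0.4 * radius
    return cx + 0.55 * b, cy + a + 0.4 * radius


def generate_video(scenario: MotionScenario) -> tuple[FrameSequence, GroundTruth]:
    """Render a scenario into frames plus its ground truth.

    The same seed always yields bit-identical pixel arrays.
    """
    scenario.validate()
    h, w = scenario.frame_size
    alpha, beta = scenario.body_axes
    a, b = alpha / 2.0, beta / 2.0
    r = scenario.limb_radius
    n = scenario.n_frames
    rng = np.random.default_rng(scenario.seed)
    t = np.arange(n) / scenario.frame_rate

    dx, dy = scenario.drift_amplitude
    path = np.column_stack([
        scenario.body_centre[0] + dx * np.sin(2 * np.pi * scenario.drift_frequency * t),
        scenario.body_centre[1] + dy * np.sin(2 * np.pi * scenario.drift_frequency * t),
    ])

    strokes = {
        limb.region: _stroke_position(t, limb.frequency, limb.amplitude, limb.duty)
        for limb in scenario.limbs
    }

    yy, xx = np.mgrid[0:h, 0:w]
    frames = np.empty((n, h, w), dtype=np.uint8)
    centroid = np.empty((n, 2))
    area = np.empty(n, dtype=np.int64)

    for i in range(n):
        cx, cy = path[i]
        mask = ((xx - cx) / b) ** 2 + ((yy - cy) / a) ** 2 <= 1.0
        for limb in scenario.limbs:
            bx, by = _limb_base(limb.region, (cx, cy), alpha, beta, r)
            ux, uy = _LIMB_DIRECTIONS[limb.region]
            s = strokes[limb.region][i]
            lx, ly = bx + ux * s, by + uy * s
            mask |= (xx - lx) ** 2 + (yy - ly) ** 2 <= r**2
        ys, xs = np.nonzero(mask)
        if len(ys) == 0:
            raise ScenarioError(f"empty silhouette at frame {i}")
        if xs.min() == 0 or ys.min() == 0 or xs.max() == w - 1 or ys.max() == h - 1:
            raise ScenarioError(f"silhouette touches the frame edge at frame {i}")
        centroid[i] = (xs.mean(), ys.mean())
        area[i] = len(ys)

        img = np.where(mask, scenario.body_level, scenario.background_level).astype(np.float64)
        if scenario.noise_sd > 0:
            img += rng.normal(0.0, scenario.noise_sd, size=img.shape)
        frames[i] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    seq = FrameSequence(frames, scenario.frame_rate)
    truth = GroundTruth(
        limb_frequencies={limb.region: limb.frequency for limb in scenario.limbs},
        centroid=centroid,
        silhouette_area=area,
        body_centre_path=path,
    )
    return seq, truth


# ---------------------------------------------------------------------------
# labelled index samples


def generate_index_samples(
    class_specs: Dict[str, tuple[np.ndarray, np.ndarray]],
    n_per_class: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Draw labelled index vectors from per-class Gaussian distributions.

    ``class_specs`` maps class name -> ``(mean, covariance)``.  Returns
    ``(Z, y, class_names)`` with integer labels in class-name order.
    Reproducible under ``seed``; covariances must be positive definite
    (the error names the offending class).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    names = list(class_specs)
    zs, ys = [], []
    for label, name in enumerate(names):
        mean, cov = class_specs[name]
        mean = np.asarray(mean, dtype=np.float64)
        cov = np.asarray(cov, dtype=np.float64)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"covariance of class {name!r} is not positive definite") from exc
        draws = mean + rng.standard_normal((n_per_class, len(mean))) @ chol.T
        zs.append(draws)
        ys.append(np.full(n_per_class, label))
    return np.vstack(zs), np.concatenate(ys), names


def gaussian_class_specs(
    n_classes: int = 4,
    dim: int = 25,
    separation: float = 3.5,
    informative: Sequence[int] | None = None,
) -> Dict[str, tuple[np.ndarray, np.ndarray]]:
    """Convenience spherical-Gaussian class layout for classifier tests.

    Class ``c`` has unit covariance and mean ``separation`` along dimension
    ``informative[c]`` (default: the first ``n_classes`` dimensions).
    """
    informative = list(informative) if informative is not None else list(range(n_classes))
    specs: Dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in range(n_classes):
        mean = np.zeros(dim)
        mean[informative[c % len(informative)]] = separation
        specs[f"class{c}"] = (mean, np.eye(dim))
    return specs


def informative_noise_specs(
    n_informative: int = 6,
    n_noise: int = 19,
    amplitude: float = 2.0,
    n_classes: int = 4,
) -> Dict[str, tuple[np.ndarray, np.ndarray]]:
    """Class layout with a known informative/noise split of the indices.

    The first ``n_informative`` dimensions carry class information: class
    means are ``+-amplitude`` sign patterns taken from mutually orthogonal
    rows (equal pairwise distances), so *every* informative dimension
    separates the classes.  The remaining ``n_noise`` dimensions are pure
    standard noise, identical across classes.  Unit covariance throughout.
    """
    if n_classes > 4:
        raise ValueError("sign patterns defined for up to 4 classes")
    base = np.array([
        [1, 1, 1],
        [1, -1, -1],
        [-1, 1, -1],
        [-1, -1, 1],
    ], dtype=np.float64)[:n_classes]
    patterns = np.tile(base, (1, (n_informative + 2) // 3))[:, :n_informative]
    dim = n_informative + n_noise
    specs: Dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in range(n_classes):
        mean = np.zeros(dim)
        mean[:n_informative] = amplitude * patterns[c]
        specs[f"class{c}"] = (mean, np.eye(dim))
    return specs


def bayes_accuracy(
    class_specs: Dict[str, tuple[np.ndarray, np.ndarray]],
    n_mc: int = 200_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo Bayes accuracy of the optimal (true-density) classifier.

    Independent oracle for classifier-recovery checks: draws from the true
    equal-prior Gaussian mixture and classifies with the exact class
    log-densities.
    """
    rng = np.random.default_rng(seed)
    names = list(class_specs)
    c = len(names)
    per = n_mc // c
    means = [np.asarray(class_specs[n][0], dtype=np.float64) for n in names]
    covs = [np.asarray(class_specs[n][1], dtype=np.float64) for n in names]
    chols = [np.linalg.cholesky(cv) for cv in covs]
    inv_covs = [np.linalg.inv(cv) for cv in covs]
    log_dets = [float(np.linalg.slogdet(cv)[1]) for cv in covs]
    hits = 0
    total = 0
    for true_c in range(c):
        x = means[true_c] + rng.standard_normal((per, len(means[true_c]))) @ chols[true_c].T
        scores = np.empty((per, c))
        for j in range(c):
            d = x - means[j]
            scores[:, j] = -0.5 * np.einsum("ni,ij,nj->n", d, inv_covs[j], d) - 0.5 * log_dets[j]
        hits += int(np.sum(scores.argmax(axis=1) == true_c))
        total += per
    return hits / total
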
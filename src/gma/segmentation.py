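"""Body segmentation: ellipse fit, analysis area, and the nine sub-areas.

The silhouette from the background-difference mask is approximated by a
least-squares ellipse.  The circumscribed rectangle ``B`` of that ellipse,
expanded by configurable margins, gives the analysis area ``A``, which two
split lines divide into the nine analysis areas:

====  =======================
k     region
====  =======================
1     infant's left, upper body
2     infant's right, upper body
3     infant's left, lower body
4     infant's right, lower body
5     upper body (1 u 2)
6     lower body (3 u 4)
7     left body (1 u 3)
8     right body (2 u 4)
9     whole analysis area
====  =======================

The long-axis split line sits at fraction ``gamma`` from the head end; the
cross split at fraction ``delta`` measured from the infant's left side.
"Left"/"right" are in the infant's own frame: a supine infant faces the
overhead camera, so with the head at the top of the image the infant's left
is the image's right.

Split lines are realized axis-aligned in image coordinates (the recording
protocol aligns the infant with the frame); the row/column at a split belongs
to the head-/left-side region (half-open convention), which makes
``A_1..A_4`` an exact partition of ``A_9``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np
from skimage.measure import EllipseModel, label

__all__ = [
    "EllipseFit",
    "Rect",
    "AreaSet",
    "SegmentationError",
    "fit_ellipse",
    "analysis_area",
    "divide_areas",
]

HEAD_ENDS = ("top", "bottom", "left", "right")


class SegmentationError(ValueError):
    """Raised when a frame cannot be segmented (unusable silhouette)."""


@dataclass
class EllipseFit:
    """Least-squares ellipse over the body silhouette.

    ``alpha``/``beta`` are the *full* long/short axis lengths in pixels
    (``alpha >= beta > 0``); ``orientation`` is the angle of the long axis
    with respect to the image x axis, in radians, normalized to
    ``[-pi/2, pi/2)``.
    """

    centre: tuple[float, float]
    alpha: float
    beta: float
    orientation: float

    def __post_init__(self) -> None:
        if not (self.alpha >= self.beta > 0):
            raise ValueError(f"invalid axes alpha={self.alpha}, beta={self.beta}")

    @property
    def long_axis_vertical(self) -> bool:
        """True when the body's long axis is closer to the image y axis."""
        return abs(np.sin(self.orientation)) > abs(np.cos(self.orientation))

    def render(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterize the fitted ellipse as a binary mask (for audit/refit)."""
        h, w = shape
        yy, xx = np.mgrid[0:h, 0:w]
        ct, st = np.cos(self.orientation), np.sin(self.orientation)
        dx = xx - self.centre[0]
        dy = yy - self.centre[1]
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        return (
            (u / (self.alpha / 2)) ** 2 + (v / (self.beta / 2)) ** 2 <= 1.0
        ).astype(np.uint8)


@dataclass(frozen=True)
class Rect:
    """Half-open pixel rectangle: rows ``[y0, y1)``, columns ``[x0, x1)``."""

    x0: int
    x1: int
    y0: int
    y1: int

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def n_pixels(self) -> int:
        return max(self.width, 0) * max(self.height, 0)

    def slice(self) -> tuple[slice, slice]:
        return slice(self.y0, self.y1), slice(self.x0, self.x1)

    def count(self, mask: np.ndarray) -> int:
        """Number of 1-pixels of ``mask`` inside this rectangle."""
        return int(mask[self.y0 : self.y1, self.x0 : self.x1].sum())


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    """Outer boundary pixels (x, y) of the largest connected component."""
    mask = np.asarray(mask) > 0
    labels = label(mask, connectivity=2)
    if labels.max() == 0:
        return np.empty((0, 2))
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    comp = labels == counts.argmax()
    # Boundary = component pixels with at least one 4-neighbour outside.
    interior = np.zeros_like(comp)
    interior[1:-1, 1:-1] = (
        comp[1:-1, 1:-1]
        & comp[:-2, 1:-1]
        & comp[2:, 1:-1]
        & comp[1:-1, :-2]
        & comp[1:-1, 2:]
    )
    ys, xs = np.nonzero(comp & ~interior)
    return np.column_stack([xs, ys]).astype(np.float64)


def fit_ellipse(bg_mask: np.ndarray) -> EllipseFit:
    """Fit a least-squares ellipse to the silhouette in ``bg_mask``.

    The conic is fitted to the outer boundary pixels of the largest
    connected foreground component (robust to speckle).

    Raises
    ------
    SegmentationError
        Fewer than 6 boundary points, or the least-squares conic is not a
        usable ellipse.
    """
    pts = _boundary_points(bg_mask)
    if len(pts) < 6:
        raise SegmentationError(
            f"silhouette has only {len(pts)} boundary pixels; need >= 6 for a conic fit"
        )
    model = EllipseModel.from_estimate(pts)
    if not model:
        raise SegmentationError("ellipse fit failed (degenerate conic)")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if not np.all(np.isfinite([xc, yc, a, b, theta])) or a <= 0 or b <= 0:
        raise SegmentationError("ellipse fit produced a degenerate conic")
    if a >= b:
        alpha, beta = 2 * a, 2 * b
    else:
        alpha, beta = 2 * b, 2 * a
        theta += np.pi / 2
    theta = (theta + np.pi / 2) % np.pi - np.pi / 2  # normalize to [-pi/2, pi/2)
    return EllipseFit((float(xc), float(yc)), float(alpha), float(beta), float(theta))


def analysis_area(
    fit: EllipseFit,
    frame_shape: tuple[int, int],
    t_a1: float = 0.02,
    t_a2: float = 0.02,
    t_a3: float = 0.03,
    head_end: str = "top",
) -> tuple[Rect, Rect]:
    """Build the analysis area ``A`` around the circumscribed rectangle ``B``.

    Margins ``a_1 = t_a1 * alpha`` (head end of the long axis),
    ``a_2 = t_a2 * alpha`` (foot end) and ``a_3 = t_a3 * beta`` (both ends of
    the short axis) expand ``B``; the result is clipped to the frame.

    Returns ``(rect_B, rect_A)``.
    """
    if min(t_a1, t_a2, t_a3) < 0:
        raise ValueError("margin factors must be non-negative")
    if head_end not in HEAD_ENDS:
        raise ValueError(f"head_end must be one of {HEAD_ENDS}, got {head_end!r}")
    h, w = frame_shape
    xc, yc = fit.centre
    a1 = t_a1 * fit.alpha
    a2 = t_a2 * fit.alpha
    a3 = t_a3 * fit.beta

    vertical = head_end in ("top", "bottom")
    if vertical:
        half_long, half_short = fit.alpha / 2, fit.beta / 2
        b = Rect(
            int(round(xc - half_short)),
            int(round(xc + half_short)),
            int(round(yc - half_long)),
            int(round(yc + half_long)),
        )
        head_first = head_end == "top"  # head at min-y end
        y0 = b.y0 - (a1 if head_first else a2)
        y1 = b.y1 + (a2 if head_first else a1)
        x0, x1 = b.x0 - a3, b.x1 + a3
    else:
        half_long, half_short = fit.alpha / 2, fit.beta / 2
        b = Rect(
            int(round(xc - half_long)),
            int(round(xc + half_long)),
            int(round(yc - half_short)),
            int(round(yc + half_short)),
        )
        head_first = head_end == "left"  # head at min-x end
        x0 = b.x0 - (a1 if head_first else a2)
        x1 = b.x1 + (a2 if head_first else a1)
        y0, y1 = b.y0 - a3, b.y1 + a3

    a = Rect(
        max(int(round(x0)), 0),
        min(int(round(x1)), w),
        max(int(round(y0)), 0),
        min(int(round(y1)), h),
    )
    if a.n_pixels <= 0:
        raise SegmentationError("analysis area collapsed to zero size")
    return b, a


@dataclass
class AreaSet:
    """The nine analysis areas ``A_1..A_9`` plus their construction inputs."""

    rect_b: Rect
    rect_a: Rect
    gamma: float
    delta: float
    head_end: str
    areas: Dict[int, Rect]

    def counts(self, mask: np.ndarray) -> Dict[int, int]:
        """Pixel counts of ``mask`` inside every area."""
        return {k: r.count(mask) for k, r in self.areas.items()}

    def to_dict(self) -> dict:
        return {
            "rect_B": vars(self.rect_b),
            "rect_A": vars(self.rect_a),
            "gamma": self.gamma,
            "delta": self.delta,
            "head_end": self.head_end,
            "areas": {k: vars(r) for k, r in self.areas.items()},
        }


def divide_areas(
    rect_a: Rect,
    gamma: float,
    delta: float,
    head_end: str = "top",
    rect_b: Rect | None = None,
) -> AreaSet:
    """Divide the analysis area into the nine analysis areas.

    ``gamma`` is the upper-body fraction measured from the head end along the
    body's long axis; ``delta`` the fraction on the infant's left side across
    the body.  Deterministic and independent of mask content.
    """
    if not (0 < gamma < 1) or not (0 < delta < 1):
        raise ValueError(f"gamma and delta must lie in (0, 1); got {gamma}, {delta}")
    if head_end not in HEAD_ENDS:
        raise ValueError(f"head_end must be one of {HEAD_ENDS}, got {head_end!r}")

    vertical = head_end in ("top", "bottom")
    if vertical:
        span = rect_a.height
        split_long = int(round(gamma * span))
        if head_end == "top":
            upper = (rect_a.y0, rect_a.y0 + split_long)
            lower = (rect_a.y0 + split_long, rect_a.y1)
            left_at_min_x = False  # head top: infant's left is image right
        else:
            upper = (rect_a.y1 - split_long, rect_a.y1)
            lower = (rect_a.y0, rect_a.y1 - split_long)
            left_at_min_x = True
        split_cross = int(round(delta * rect_a.width))
        if left_at_min_x:
            left_cols = (rect_a.x0, rect_a.x0 + split_cross)
            right_cols = (rect_a.x0 + split_cross, rect_a.x1)
        else:
            left_cols = (rect_a.x1 - split_cross, rect_a.x1)
            right_cols = (rect_a.x0, rect_a.x1 - split_cross)

        def make(cols, rows):
            return Rect(cols[0], cols[1], min(rows), max(rows))

        a1 = make(left_cols, upper)
        a2 = make(right_cols, upper)
        a3 = make(left_cols, lower)
        a4 = make(right_cols, lower)
        a5 = Rect(rect_a.x0, rect_a.x1, min(upper), max(upper))
        a6 = Rect(rect_a.x0, rect_a.x1, min(lower), max(lower))
        a7 = Rect(left_cols[0], left_cols[1], rect_a.y0, rect_a.y1)
        a8 = Rect(right_cols[0], right_cols[1], rect_a.y0, rect_a.y1)
    else:
        span = rect_a.width
        split_long = int(round(gamma * span))
        if head_end == "left":
            upper = (rect_a.x0, rect_a.x0 + split_long)
            lower = (rect_a.x0 + split_long, rect_a.x1)
            left_at_min_y = True  # head left: infant's left is image top
        else:
            upper = (rect_a.x1 - split_long, rect_a.x1)
            lower = (rect_a.x0, rect_a.x1 - split_long)
            left_at_min_y = False
        split_cross = int(round(delta * rect_a.height))
        if left_at_min_y:
            left_rows = (rect_a.y0, rect_a.y0 + split_cross)
            right_rows = (rect_a.y0 + split_cross, rect_a.y1)
        else:
            left_rows = (rect_a.y1 - split_cross, rect_a.y1)
            right_rows = (rect_a.y0, rect_a.y1 - split_cross)

        def make(cols, rows):
            return Rect(min(cols), max(cols), rows[0], rows[1])

        a1 = make(upper, left_rows)
        a2 = make(upper, right_rows)
        a3 = make(lower, left_rows)
        a4 = make(lower, right_rows)
        a5 = Rect(min(upper), max(upper), rect_a.y0, rect_a.y1)
        a6 = Rect(min(lower), max(lower), rect_a.y0, rect_a.y1)
        a7 = Rect(rect_a.x0, rect_a.x1, left_rows[0], left_rows[1])
        a8 = Rect(rect_a.x0, rect_a.x1, right_rows[0], right_rows[1])

    areas = {1: a1, 2: a2, 3: a3, 4: a4, 5: a5, 6: a6, 7: a7, 8: a8, 9: rect_a}
    return AreaSet(
        rect_b=rect_b if rect_b is not None else rect_a,
        rect_a=rect_a,
        gamma=gamma,
        delta=delta,
        head_end=head_end,
        areas=areas,
    )
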
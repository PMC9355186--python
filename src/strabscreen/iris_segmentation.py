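"""Iris segmentation and pupil-centre estimation from an eye-region crop.

The estimation chain: grayscale conversion, two dark-foreground masks
(Otsu's threshold and an HSV value-channel gate whose upper bound adapts to
the crop's mean gray), their pixel-wise AND, small-component cleanup,
per-column bottom-to-top sampling of the lower limbus arc, and an algebraic
(Kasa) least-squares circle fit giving the pupil centre and iris radius.

The lower limbus is sampled because the upper limbus is routinely hidden by
the eyelid; a circle fitted to the lower arc alone still pins down centre
and radius.

Otsu's threshold is computed by an explicit vectorized search over all 255
split points of the 256-bin gray histogram (maximizing between-class
variance), so it coincides exactly with a brute-force scan by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from skimage import measure

#: ITU-R BT.601 luma weights; the standard RGB-to-gray convention.
GRAY_WEIGHTS = (0.299, 0.587, 0.114)
#: connected components below this fraction of the crop area are removed
#: before limbus sampling (eyelash / noise suppression)
MIN_COMPONENT_FRACTION = 0.01


class SegmentationError(RuntimeError):
    pass


class ThresholdError(SegmentationError):
    """No valid threshold exists (e.g. a constant image)."""


class CircleFitError(SegmentationError):
    pass


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luma grayscale of an RGB raster, rounded to uint8."""
    image = np.asarray(image)
    if image.ndim == 2:
        return image.astype(np.uint8)
    gray = image[..., :3].astype(float) @ np.array(GRAY_WEIGHTS)
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def otsu_threshold(gray: np.ndarray) -> int:
    """Gray level t maximizing between-class variance for the split
    (values <= t) vs (values > t); smallest t on ties.

    Raises :class:`ThresholdError` for a constant image.
    """
    gray = np.asarray(gray)
    if gray.size == 0:
        raise ThresholdError("empty image")
    hist = np.bincount(gray.ravel().astype(np.uint8), minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise ThresholdError("constant image has no valid Otsu threshold")
    p = hist / hist.sum()
    levels = np.arange(256, dtype=float)
    omega0 = np.cumsum(p)[:-1]          # P(class <= t), t = 0..254
    mu_cum = np.cumsum(p * levels)
    mu_total = mu_cum[-1]
    mu0_sum = mu_cum[:-1]
    omega1 = 1.0 - omega0
    valid = (omega0 > 0) & (omega1 > 0)
    sigma_b = np.full(255, -np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (mu_total * omega0 - mu0_sum) ** 2
        sigma_b[valid] = num[valid] / (omega0[valid] * omega1[valid])
    return int(np.argmax(sigma_b))


@dataclass(frozen=True)
class BinaryMask:
    """Boolean foreground raster aligned to its source crop."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        if px.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def count(self) -> int:
        return int(self.pixels.sum())


def otsu_mask(crop: np.ndarray) -> BinaryMask:
    """Dark-foreground Otsu mask: pixels at or below the optimal threshold."""
    gray = to_grayscale(crop)
    t = otsu_threshold(gray)
    return BinaryMask(gray <= t)


def hsv_mask(crop: np.ndarray) -> BinaryMask:
    """HSV gate with bounds [0,0,0]..[180,255,v], v = rounded mean gray.

    H in [0,180] and S in [0,255] admit every pixel, so the gate reduces to
    the value channel (max of R,G,B) being at most the crop's mean gray
    level; the upper bound is inclusive.
    """
    crop = np.asarray(crop)
    gray = to_grayscale(crop)
    v = int(np.rint(gray.astype(float).mean()))
    if crop.ndim == 3:
        value = crop[..., :3].max(axis=2)
    else:
        value = crop
    return BinaryMask(value <= v)


def combine_masks(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Pixel-wise AND (the masks' common part)."""
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return BinaryMask(a.pixels & b.pixels)


def remove_small_components(mask: BinaryMask,
                            min_fraction: float = MIN_COMPONENT_FRACTION) -> BinaryMask:
    min_size = max(1, int(min_fraction * mask.pixels.size))
    labels = measure.label(mask.pixels, connectivity=2)
    if labels.max() == 0:
        return BinaryMask(np.zeros_like(mask.pixels))
    areas = np.bincount(labels.ravel())
    keep = np.nonzero(areas >= min_size)[0]
    keep = keep[keep != 0]
    return BinaryMask(np.isin(labels, keep))


def sample_limbus_points(mask: BinaryMask) -> np.ndarray:
    """Per-column bottom-to-top first-hit sampling of the lower limbus arc.

    For every column that intersects the foreground, the lowest foreground
    pixel is recorded as an (x, y) point; columns without foreground
    contribute nothing.  Fewer than 3 points leave a circle underdetermined
    and raise :class:`SegmentationError`.
    """
    px = mask.pixels
    cols = np.nonzero(px.any(axis=0))[0]
    if cols.size < 3:
        raise SegmentationError(
            f"only {cols.size} limbus point(s) sampled; need at least 3")
    # lowest row per column = last True scanning top-down
    last_rows = px.shape[0] - 1 - np.argmax(px[::-1, :][:, cols], axis=0)
    return np.stack([cols.astype(float), last_rows.astype(float)], axis=1)


@dataclass(frozen=True)
class IrisCircle:
    center: tuple[float, float]
    radius: float
    rms_residual: float
    n_points: int

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise CircleFitError(f"non-positive fitted radius {self.radius}")
        if self.n_points < 3:
            raise CircleFitError("a circle needs at least 3 points")


def fit_circle_lsm(points: Sequence[Sequence[float]] | np.ndarray) -> IrisCircle:
    """Kasa algebraic least-squares circle fit.

    Minimizes sum((x^2 + y^2 + D x + E y + F)^2) — linear in (D, E, F) — and
    reports the root-mean-square radial deviation of the points from the
    fitted circle.  Collinear points make the normal system singular.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise CircleFitError("need an (n, 2) array with n >= 3")
    if not np.all(np.isfinite(pts)):
        raise CircleFitError("non-finite point coordinates")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    if np.linalg.matrix_rank(A) < 3:
        raise CircleFitError("points are collinear; circle fit is singular")
    (cx, cy, c), *_ = np.linalg.lstsq(A, b, rcond=None)
    r2 = c + cx**2 + cy**2
    if r2 <= 0:
        raise CircleFitError("degenerate circle fit (non-positive radius)")
    r = float(np.sqrt(r2))
    resid = np.hypot(x - cx, y - cy) - r
    return IrisCircle(center=(float(cx), float(cy)), radius=r,
                      rms_residual=float(np.sqrt(np.mean(resid**2))),
                      n_points=pts.shape[0])


def refine_circle_geometric(points: np.ndarray, init: IrisCircle) -> IrisCircle:
    """Optional nonlinear refinement minimizing true radial distances.

    Gauss-Newton on residuals |p - c| - r starting from an algebraic fit;
    not the default path (the algebraic fit is closed-form and sufficient
    for rasterized limbus arcs).
    """
    pts = np.asarray(points, dtype=float)

    def resid(params: np.ndarray) -> np.ndarray:
        cx, cy, r = params
        return np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) - r

    x0 = np.array([*init.center, init.radius])
    sol = least_squares(resid, x0, method="lm")
    cx, cy, r = sol.x
    res = resid(sol.x)
    return IrisCircle(center=(float(cx), float(cy)), radius=float(r),
                      rms_residual=float(np.sqrt(np.mean(res**2))),
                      n_points=pts.shape[0])


def estimate_pupil_center(crop: np.ndarray, *, geometric_refine: bool = False,
                          min_component_fraction: float = MIN_COMPONENT_FRACTION
                          ) -> IrisCircle:
    """Full per-eye chain: Otsu AND HSV masks, cleanup, lower-limbus
    sampling, least-squares circle fit.

    The fitted centre doubles as the pupil-centre estimate (the iris and
    pupil are treated as concentric).
    """
    combined = combine_masks(otsu_mask(crop), hsv_mask(crop))
    cleaned = remove_small_components(combined, min_component_fraction)
    points = sample_limbus_points(cleaned)
    circle = fit_circle_lsm(points)
    if geometric_refine:
        circle = refine_circle_geometric(points, circle)
    return circle
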
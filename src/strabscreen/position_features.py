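"""Position-similarity ratio S and corneal-light-reflex (CLR) ratio.

Two scalar features describe ocular alignment in a frontal photograph:

* **Position similarity** ``S = max(R1/R2, L1/L2) / min(R1/R2, L1/L2)``,
  where R1, L1 are each pupil centre's Euclidean distance to the medial
  canthus and R2, L2 to the lateral canthus.  Symmetric fixation gives
  S = 1; deviation of either eye pushes S above 1.  S is scale- and
  rotation-invariant, so no physical calibration is needed.

* **CLR ratio** ``(D1 + D3) / (D2 + D4)`` (Hirschberg principle): D1, D3
  are the distances from each eye's specular reflex centre to the medial
  corneal limbus (the point one iris radius nasally from the pupil centre,
  on the horizontal through it) and D2, D4 are the iris diameters.  With
  both reflexes centred the ratio is exactly 0.5; the published reference
  range for orthotropic eyes is 0.448-0.488 (abnormal below 0.440 or above
  0.497), whose midpoint 0.468 doubles as the imputation constant.

Photographs taken without a pen torch have no reflex, so the ratio is
imputed: for training images the class label chooses 0.468 (normal) or 0
(strabismus); for test images, whose labels are unknown, a similarity-ratio
criterion — the midpoint between the largest normal S and the smallest
strabismic S in the training set — decides which constant to assign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .iris_segmentation import IrisCircle, otsu_threshold, to_grayscale
from .synthetic_eye import NORMAL, STRABISMUS

MEASURED = "measured"
IMPUTED_NORMAL = "imputed_normal"
IMPUTED_STRABISMUS = "imputed_strabismus"

#: maximum fraction of the iris disc a plausible reflex may occupy
MAX_REFLEX_AREA_FRACTION = 0.10
#: minimum reflex area in pixels
MIN_REFLEX_AREA_PX = 2


@dataclass(frozen=True)
class CLRReferenceRange:
    """Published normal / abnormal bands of the CLR ratio."""

    normal_low: float = 0.448
    normal_high: float = 0.488
    abnormal_below: float = 0.440
    abnormal_above: float = 0.497

    def __post_init__(self) -> None:
        if not (self.abnormal_below < self.normal_low < self.normal_high
                < self.abnormal_above):
            raise ValueError("reference bands out of order")

    @property
    def normal_midpoint(self) -> float:
        return 0.5 * (self.normal_low + self.normal_high)


CLR_REFERENCE = CLRReferenceRange()
#: imputation constant for presumed-normal images without a reflex: the
#: midpoint of the normal reference band (0.448 + 0.488) / 2
CLR_IMPUTE_NORMAL = 0.468
CLR_IMPUTE_STRABISMUS = 0.0


class FeatureError(ValueError):
    pass


@dataclass(frozen=True)
class PositionFeatures:
    R1: float  # right pupil -> medial canthus
    R2: float  # right pupil -> lateral canthus
    L1: float  # left pupil -> medial canthus
    L2: float  # left pupil -> lateral canthus
    S: float

    def __post_init__(self) -> None:
        if min(self.R1, self.R2, self.L1, self.L2) <= 0:
            raise FeatureError("pupil-to-canthus distances must be positive")
        if self.S < 1.0 - 1e-12:
            raise FeatureError(f"similarity ratio S={self.S} below 1")


def _dist(p: tuple[float, float], q: tuple[float, float]) -> float:
    return math.hypot(p[0] - q[0], p[1] - q[1])


def position_similarity(
    pupil_right: tuple[float, float],
    pupil_left: tuple[float, float],
    canthus_medial_right: tuple[float, float],
    canthus_lateral_right: tuple[float, float],
    canthus_medial_left: tuple[float, float],
    canthus_lateral_left: tuple[float, float],
) -> PositionFeatures:
    """Euclidean pupil-to-canthus distances and the similarity ratio S."""
    for pt in (pupil_right, pupil_left, canthus_medial_right,
               canthus_lateral_right, canthus_medial_left, canthus_lateral_left):
        if not all(math.isfinite(c) for c in pt):
            raise FeatureError("non-finite coordinate")
    R1 = _dist(pupil_right, canthus_medial_right)
    R2 = _dist(pupil_right, canthus_lateral_right)
    L1 = _dist(pupil_left, canthus_medial_left)
    L2 = _dist(pupil_left, canthus_lateral_left)
    if min(R1, R2, L1, L2) == 0:
        raise FeatureError("pupil centre coincides with a canthus landmark")
    r_ratio, l_ratio = R1 / R2, L1 / L2
    S = max(r_ratio, l_ratio) / min(r_ratio, l_ratio)
    return PositionFeatures(R1=R1, R2=R2, L1=L1, L2=L2, S=S)


def detect_clr_center(crop: np.ndarray, iris: IrisCircle) -> tuple[float, float] | None:
    """Centroid of the bright reflex pixels inside the iris disc, or None.

    A specular reflex punches a bright hole in the otherwise dark iris, so
    the search region is the hole-filled dark iris mask intersected with
    the fitted disc: sclera included by a slightly-too-large fitted circle
    and eyelid skin overhanging the upper limbus are connected to the
    outside, not enclosed by the iris, and therefore never enter the
    search.  Within that region, Otsu's threshold with bright polarity
    (foreground above the threshold) isolates candidate reflex pixels.
    The bright class is accepted as a reflex only if it covers at least
    2 px and at most 10% of the disc — otherwise (uniform iris, or a split
    that merely halves iris noise) no reflex is reported.  Absence is a
    value, not an error.
    """
    from scipy.ndimage import binary_fill_holes

    from .iris_segmentation import (combine_masks, hsv_mask, otsu_mask,
                                    remove_small_components)

    gray = to_grayscale(crop)
    h, w = gray.shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = iris.center
    dark = remove_small_components(combine_masks(otsu_mask(crop), hsv_mask(crop)))
    iris_region = binary_fill_holes(dark.pixels)
    disc = iris_region & ((xx - cx) ** 2 + (yy - cy) ** 2 <= iris.radius**2)
    vals = gray[disc]
    if vals.size == 0 or vals.min() == vals.max():
        return None
    t = otsu_threshold(vals)
    fg = disc & (gray > t)
    area = int(fg.sum())
    if area < MIN_REFLEX_AREA_PX or area > MAX_REFLEX_AREA_FRACTION * disc.sum():
        return None
    ys, xs = np.nonzero(fg)
    return (float(xs.mean()), float(ys.mean()))


@dataclass(frozen=True)
class CLRFeatures:
    D1: float | None  # right reflex -> right medial limbus
    D2: float         # right iris diameter
    D3: float | None  # left reflex -> left medial limbus
    D4: float         # left iris diameter
    ratio: float
    provenance: str

    def __post_init__(self) -> None:
        if self.D2 <= 0 or self.D4 <= 0:
            raise FeatureError("iris diameters must be positive")
        if self.provenance == MEASURED and not 0.0 <= self.ratio <= 1.0:
            raise FeatureError(f"measured CLR ratio {self.ratio} outside [0, 1]")


def clr_ratio(
    reflex_right: tuple[float, float],
    reflex_left: tuple[float, float],
    iris_right: IrisCircle,
    iris_left: IrisCircle,
    medial_sign_right: float = 1.0,
    medial_sign_left: float = -1.0,
) -> CLRFeatures:
    """Measured CLR ratio (D1 + D3) / (D2 + D4) from both reflexes.

    The medial limbus of each eye is one iris radius from the pupil centre
    along the horizontal axis toward the nose; the sign arguments encode
    that direction (+x for the subject's right eye, -x for the left, in the
    standard frontal frame where the right eye has smaller x).  All points
    must share one coordinate frame.
    """
    if iris_right.radius <= 0 or iris_left.radius <= 0:
        raise FeatureError("degenerate iris radius")
    limbus_r = (iris_right.center[0] + medial_sign_right * iris_right.radius,
                iris_right.center[1])
    limbus_l = (iris_left.center[0] + medial_sign_left * iris_left.radius,
                iris_left.center[1])
    D1 = _dist(reflex_right, limbus_r)
    D3 = _dist(reflex_left, limbus_l)
    D2 = 2.0 * iris_right.radius
    D4 = 2.0 * iris_left.radius
    return CLRFeatures(D1=D1, D2=D2, D3=D3, D4=D4,
                       ratio=(D1 + D3) / (D2 + D4), provenance=MEASURED)


def impute_clr_train(label: str) -> float:
    """Training-phase imputation for an image without a detected reflex."""
    if label == NORMAL:
        return CLR_IMPUTE_NORMAL
    if label == STRABISMUS:
        return CLR_IMPUTE_STRABISMUS
    raise FeatureError(f"unknown label {label!r}")


def clr_criterion(train_S_normal, train_S_strab) -> float:
    """Imputation criterion: midpoint between the largest training-normal S
    and the smallest training-strabismic S."""
    normal = list(train_S_normal)
    strab = list(train_S_strab)
    if not normal or not strab:
        raise FeatureError("both training S lists must be non-empty")
    return 0.5 * (max(normal) + min(strab))


def impute_clr_test(S: float, criterion: float) -> float:
    """Test-phase imputation: S at or below the criterion is presumed
    normal (0.468), above it strabismic (0)."""
    if not math.isfinite(S) or not math.isfinite(criterion):
        raise FeatureError("non-finite S or criterion")
    return CLR_IMPUTE_NORMAL if S <= criterion else CLR_IMPUTE_STRABISMUS
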
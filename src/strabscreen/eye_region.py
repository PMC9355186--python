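"""Eye-region extraction: locate each eye and crop it with six landmarks.

The screening pipeline's front end finds six landmarks per eye (including
the medial and lateral canthus), crops an expanded bounding box around
them, and resizes crops to the 84x84 input the embedding network expects.
Landmark detection sits behind a provider interface so the rest of the
pipeline never depends on the detector:

* :class:`GroundTruthProvider` replays the exact geometry of a synthetic
  scene (fixtures and oracles);
* :class:`HeuristicLandmarkProvider` detects eyes on synthetic-style images
  by intensity: a dark-iris threshold followed by a sclera/skin split, with
  canthi at the horizontal extremes of each eye opening.

Coordinates are 0-based, origin at the top-left, x rightward, y downward.
Sides are anatomical (the subject's right eye is on the image's left).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Protocol

import numpy as np
from PIL import Image
from skimage import measure
from skimage.transform import resize as _sk_resize

from .synthetic_eye import GroundTruth

EMBEDDING_INPUT_SIZE = (84, 84)
#: fractional expansion of the landmark bounding box on each side
CROP_MARGIN_FRACTION = 0.25


class FaceDetectionError(RuntimeError):
    """Base class for face/landmark detection failures."""


class NoFaceError(FaceDetectionError):
    pass


class MultipleFacesError(FaceDetectionError):
    def __init__(self, n_faces: int):
        super().__init__(f"expected exactly one face, detected {n_faces}")
        self.n_faces = n_faces


def load_face_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG into an (H, W, 3) uint8 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def _as_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.shape[0] == 0 or image.shape[1] == 0:
        raise ValueError(f"expected a non-empty (H, W, 3) RGB array, got shape {image.shape}")
    return image


@dataclass(frozen=True)
class EyeLandmarks:
    """Six landmarks for one eye, face-frame coordinates.

    ``landmarks`` rows are [lateral canthus, medial canthus, upper lid x2,
    lower lid x2]; the two canthi are also exposed directly.
    """

    landmarks: np.ndarray  # (6, 2)
    canthus_medial: tuple[float, float]
    canthus_lateral: tuple[float, float]

    def __post_init__(self) -> None:
        lm = np.asarray(self.landmarks, dtype=float)
        if lm.shape != (6, 2):
            raise ValueError(f"expected six (x, y) landmarks, got shape {lm.shape}")
        object.__setattr__(self, "landmarks", lm)
        for name in ("canthus_medial", "canthus_lateral"):
            pt = np.asarray(getattr(self, name), dtype=float)
            if not np.any(np.all(np.isclose(lm, pt, atol=1e-9), axis=1)):
                raise ValueError(f"{name} must be one of the six landmarks")


class LandmarkProvider(Protocol):
    def detect(self, image: np.ndarray) -> tuple[EyeLandmarks, EyeLandmarks]:
        """Return (right-eye, left-eye) landmarks or raise FaceDetectionError."""


class GroundTruthProvider:
    """Replays the exact landmarks of a rendered synthetic scene."""

    def __init__(self, truth: GroundTruth):
        self._truth = truth

    def detect(self, image: np.ndarray) -> tuple[EyeLandmarks, EyeLandmarks]:
        t = self._truth
        right = EyeLandmarks(t.landmarks_right, t.canthus_medial_right,
                             t.canthus_lateral_right)
        left = EyeLandmarks(t.landmarks_left, t.canthus_medial_left,
                            t.canthus_lateral_left)
        return right, left


class HeuristicLandmarkProvider:
    """Intensity-based eye finder for synthetic-style frontal images.

    Two-stage thresholding: an Otsu split of the grayscale image isolates
    the dark irises; a second Otsu split of the remaining (brighter) pixels
    separates sclera from skin.  The union (iris or sclera) components are
    candidate eye openings; exactly two are expected for one face.  Canthi
    are the horizontal extreme pixels of each opening; lid landmarks are
    the vertical extents at the quarter-width columns.
    """

    #: openings smaller than this fraction of the image are noise
    min_opening_fraction: float = 0.001

    def detect(self, image: np.ndarray) -> tuple[EyeLandmarks, EyeLandmarks]:
        from .iris_segmentation import ThresholdError, otsu_threshold, to_grayscale

        image = _as_rgb(image)
        gray = to_grayscale(image)
        try:
            t_dark = otsu_threshold(gray)
        except ThresholdError as exc:  # uniform image: nothing to find
            raise NoFaceError("no face found: image has no intensity structure") from exc
        dark = gray <= t_dark
        bright = gray[~dark]
        if bright.size == 0 or bright.min() == bright.max():
            raise NoFaceError("no face found: no sclera/skin contrast")
        t_sclera = otsu_threshold(bright)
        opening = dark | (gray <= t_sclera)

        labels = measure.label(opening, connectivity=2)
        min_area = self.min_opening_fraction * gray.size
        comps = [r for r in measure.regionprops(labels) if r.area >= min_area]
        if len(comps) < 2:
            raise NoFaceError(f"no face found: {len(comps)} eye opening(s) detected")
        if len(comps) > 2:
            if len(comps) % 2 == 0:
                raise MultipleFacesError(len(comps) // 2)
            raise NoFaceError(f"no face found: {len(comps)} eye opening(s) detected")

        comps.sort(key=lambda r: r.centroid[1])  # left-of-image first = subject right
        eyes = [self._landmarks_from_component(labels == r.label, medial_sign=s)
                for r, s in zip(comps, (1.0, -1.0))]
        return eyes[0], eyes[1]

    @staticmethod
    def _landmarks_from_component(mask: np.ndarray, medial_sign: float) -> EyeLandmarks:
        ys, xs = np.nonzero(mask)
        x_min, x_max = xs.min(), xs.max()

        def corner(x: int) -> tuple[float, float]:
            return (float(x), float(np.mean(ys[xs == x])))

        lateral = corner(x_min) if medial_sign > 0 else corner(x_max)
        medial = corner(x_max) if medial_sign > 0 else corner(x_min)
        lid_pts_upper, lid_pts_lower = [], []
        for frac in (0.25, 0.75):
            x = int(round(x_min + frac * (x_max - x_min)))
            col = ys[xs == x]
            lid_pts_upper.append((float(x), float(col.min())))
            lid_pts_lower.append((float(x), float(col.max())))
        lm = np.array([lateral, medial, *lid_pts_upper, *lid_pts_lower], dtype=float)
        return EyeLandmarks(lm, medial, lateral)


@dataclass(frozen=True)
class EyeRegion:
    """One eye's crop plus its landmarks in the shared face frame."""

    crop: np.ndarray
    origin: tuple[int, int]
    landmarks: np.ndarray  # (6, 2), face frame
    canthus_medial: tuple[float, float]
    canthus_lateral: tuple[float, float]
    side: str

    def to_local(self, point: tuple[float, float]) -> tuple[float, float]:
        return (point[0] - self.origin[0], point[1] - self.origin[1])

    def to_face(self, point: tuple[float, float]) -> tuple[float, float]:
        return (point[0] + self.origin[0], point[1] + self.origin[1])


def _crop_region(image: np.ndarray, eye: EyeLandmarks, side: str) -> EyeRegion:
    h, w = image.shape[:2]
    lm = eye.landmarks
    x0, y0 = lm.min(axis=0)
    x1, y1 = lm.max(axis=0)
    mx = CROP_MARGIN_FRACTION * (x1 - x0)
    my = CROP_MARGIN_FRACTION * (y1 - y0)
    xa = max(0, int(np.floor(x0 - mx)))
    ya = max(0, int(np.floor(y0 - my)))
    xb = min(w, int(np.ceil(x1 + mx)) + 1)
    yb = min(h, int(np.ceil(y1 + my)) + 1)
    return EyeRegion(
        crop=image[ya:yb, xa:xb].copy(),
        origin=(xa, ya),
        landmarks=lm,
        canthus_medial=tuple(eye.canthus_medial),
        canthus_lateral=tuple(eye.canthus_lateral),
        side=side,
    )


def detect_and_extract(
    image: np.ndarray, provider: LandmarkProvider
) -> tuple[EyeRegion, EyeRegion]:
    """Detect landmarks via ``provider`` and crop both eye regions.

    The crop box is the landmark bounding box expanded by 25% on each side
    (clipped to the image), so the full limbus is included.
    """
    image = _as_rgb(image)
    right, left = provider.detect(image)
    return _crop_region(image, right, "right"), _crop_region(image, left, "left")


def resize_for_embedding(
    region: EyeRegion | np.ndarray, size: tuple[int, int] = EMBEDDING_INPUT_SIZE
) -> np.ndarray:
    """Bilinearly resize a crop to ``size`` (height, width defaulting 84x84).

    Direct resize without aspect preservation; an already-conforming crop is
    returned unchanged.
    """
    crop = region.crop if isinstance(region, EyeRegion) else np.asarray(region)
    if crop.size == 0:
        raise ValueError("cannot resize an empty crop")
    if crop.shape[:2] == tuple(size):
        return crop.copy()
    out = _sk_resize(crop.astype(float), size, order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)
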
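"""Parametric eye-pair renderer with exact ground-truth geometry.

Renders a frontal eye strip: uniform skin, two palpebral (eye-opening)
ellipses of sclera, a dark iris disc per eye whose centre can be displaced
from its rest position (ocular deviation), an optional bright specular
reflex dot inside each iris (the corneal light reflex produced by a pen
torch in the Hirschberg test), optional eyelid occlusion of the upper
limbus, and optional additive Gaussian pixel noise.

Rendering is a pure function of the scene specification (the seed lives in
the spec), is not anti-aliased by default so segmentation oracles are exact,
and returns the exact geometry it drew.  Sides are anatomical: the subject's
right eye appears on the image's left.

Renderer geometry constants (fractions of the image size):

* eye rest centres at (0.25*W, 0.5*H) (right) and (0.75*W, 0.5*H) (left);
* palpebral half-axes a = 0.14*W (horizontal), b = 0.24*H (vertical);
* six landmarks per eye: medial and lateral canthus at the ellipse's
  horizontal extremes plus upper/lower lid points at x = centre ± a/2.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

NORMAL = "normal"
STRABISMUS = "strabismus"

#: fraction of image width/height giving each eye's rest centre
EYE_CENTER_X_FRACTIONS = (0.25, 0.75)  # (right eye, left eye) — subject sides
EYE_CENTER_Y_FRACTION = 0.5
#: palpebral ellipse half-axes as fractions of image width / height
PALPEBRAL_HALF_WIDTH_FRACTION = 0.14
PALPEBRAL_HALF_HEIGHT_FRACTION = 0.24
#: lid landmarks sit at x = centre ± a/2, i.e. at ±60° on the ellipse
_LID_X_FRACTION = 0.5
_LID_Y_FRACTION = math.sqrt(1.0 - _LID_X_FRACTION**2)


class SceneSpecError(ValueError):
    """Raised when an EyeSceneSpec violates its geometric or intensity invariants."""


@dataclass(frozen=True)
class EyeSceneSpec:
    """Full parametric description of one synthetic eye-pair scene.

    Offsets are (dx, dy) pixel displacements: iris offsets relative to each
    eye's rest position, reflex offsets relative to the (displaced) iris
    centre.  ``label_threshold_px`` is the declared deviation threshold that
    separates the two classes: a scene is labelled strabismic when the larger
    per-eye deviation magnitude exceeds it.
    """

    image_width: int = 360
    image_height: int = 140
    iris_radius: float = 18.0
    iris_center_offset_right: tuple[float, float] = (0.0, 0.0)
    iris_center_offset_left: tuple[float, float] = (0.0, 0.0)
    reflex_present_right: bool = True
    reflex_present_left: bool = True
    reflex_offset_right: tuple[float, float] = (0.0, 0.0)
    reflex_offset_left: tuple[float, float] = (0.0, 0.0)
    reflex_radius: float = 2.0
    eyelid_occlusion_fraction: float = 0.0
    intensity_skin: int = 200
    intensity_sclera: int = 180
    intensity_iris: int = 60
    intensity_reflex: int = 250
    noise_sd: float = 0.0
    label_threshold_px: float = 5.0
    antialias: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_width <= 0 or self.image_height <= 0:
            raise SceneSpecError("image dimensions must be positive")
        if self.iris_radius <= 0:
            raise SceneSpecError("iris_radius must be positive")
        if not (self.intensity_iris < self.intensity_sclera
                <= self.intensity_skin < self.intensity_reflex):
            raise SceneSpecError(
                "intensity ordering violated: need iris < sclera <= skin < reflex, got "
                f"iris={self.intensity_iris}, sclera={self.intensity_sclera}, "
                f"skin={self.intensity_skin}, reflex={self.intensity_reflex}")
        for name in ("intensity_skin", "intensity_sclera", "intensity_iris",
                     "intensity_reflex"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise SceneSpecError(f"{name}={v} outside gray range 0..255")
        if not 0.0 <= self.eyelid_occlusion_fraction <= 0.5:
            raise SceneSpecError(
                f"eyelid_occlusion_fraction={self.eyelid_occlusion_fraction} "
                "outside [0, 0.5]")
        if self.noise_sd < 0:
            raise SceneSpecError("noise_sd must be non-negative")
        for side in ("right", "left"):
            self._check_iris_inside_opening(side)
            self._check_reflex_inside_iris(side)

    # --- derived geometry -------------------------------------------------

    @property
    def palpebral_half_axes(self) -> tuple[float, float]:
        return (PALPEBRAL_HALF_WIDTH_FRACTION * self.image_width,
                PALPEBRAL_HALF_HEIGHT_FRACTION * self.image_height)

    def eye_rest_center(self, side: str) -> tuple[float, float]:
        i = {"right": 0, "left": 1}[side]
        return (EYE_CENTER_X_FRACTIONS[i] * self.image_width,
                EYE_CENTER_Y_FRACTION * self.image_height)

    def iris_center(self, side: str) -> tuple[float, float]:
        cx, cy = self.eye_rest_center(side)
        dx, dy = getattr(self, f"iris_center_offset_{side}")
        return (cx + dx, cy + dy)

    def reflex_center(self, side: str) -> tuple[float, float] | None:
        if not getattr(self, f"reflex_present_{side}"):
            return None
        ix, iy = self.iris_center(side)
        dx, dy = getattr(self, f"reflex_offset_{side}")
        return (ix + dx, iy + dy)

    def landmarks(self, side: str) -> np.ndarray:
        """Six (x, y) landmarks: [lateral canthus, medial canthus, two upper
        lid points, two lower lid points], in image coordinates."""
        a, b = self.palpebral_half_axes
        cx, cy = self.eye_rest_center(side)
        # medial = toward the nose = toward the image centre
        medial_sign = 1.0 if side == "right" else -1.0
        lateral = (cx - medial_sign * a, cy)
        medial = (cx + medial_sign * a, cy)
        xs = (cx - _LID_X_FRACTION * a, cx + _LID_X_FRACTION * a)
        upper = [(x, cy - _LID_Y_FRACTION * b) for x in xs]
        lower = [(x, cy + _LID_Y_FRACTION * b) for x in xs]
        return np.array([lateral, medial, *upper, *lower], dtype=float)

    def deviation_magnitude(self, side: str) -> float:
        return float(np.hypot(*getattr(self, f"iris_center_offset_{side}")))

    @property
    def label(self) -> str:
        dev = max(self.deviation_magnitude("right"),
                  self.deviation_magnitude("left"))
        return STRABISMUS if dev > self.label_threshold_px else NORMAL

    # --- invariant checks -------------------------------------------------

    def _check_iris_inside_opening(self, side: str) -> None:
        a, b = self.palpebral_half_axes
        cx, cy = self.eye_rest_center(side)
        ix, iy = self.iris_center(side)
        if ((ix - cx) / a) ** 2 + ((iy - cy) / b) ** 2 >= 1.0:
            raise SceneSpecError(f"{side} iris centre outside the eye opening")
        theta = np.linspace(0.0, 2.0 * np.pi, 1440, endpoint=False)
        boundary = np.stack([cx + a * np.cos(theta), cy + b * np.sin(theta)], axis=1)
        clearance = np.min(np.hypot(boundary[:, 0] - ix, boundary[:, 1] - iy))
        if clearance < self.iris_radius:
            raise SceneSpecError(
                f"{side} iris (radius {self.iris_radius}) extends outside its eye "
                f"opening (boundary clearance {clearance:.2f} px)")

    def _check_reflex_inside_iris(self, side: str) -> None:
        if not getattr(self, f"reflex_present_{side}"):
            return
        dx, dy = getattr(self, f"reflex_offset_{side}")
        if math.hypot(dx, dy) + self.reflex_radius > self.iris_radius:
            raise SceneSpecError(
                f"{side} reflex dot (offset ({dx}, {dy}), radius "
                f"{self.reflex_radius}) extends outside the iris disc")


@dataclass(frozen=True)
class GroundTruth:
    """Exact geometry of a rendered scene, in image coordinates."""

    canthus_medial_right: tuple[float, float]
    canthus_lateral_right: tuple[float, float]
    canthus_medial_left: tuple[float, float]
    canthus_lateral_left: tuple[float, float]
    pupil_center_right: tuple[float, float]
    pupil_center_left: tuple[float, float]
    iris_radius_right: float
    iris_radius_left: float
    reflex_center_right: tuple[float, float] | None
    reflex_center_left: tuple[float, float] | None
    label: str
    landmarks_right: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    landmarks_left: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def canthi(self) -> dict[str, tuple[float, float]]:
        return {
            "medial_right": self.canthus_medial_right,
            "lateral_right": self.canthus_lateral_right,
            "medial_left": self.canthus_medial_left,
            "lateral_left": self.canthus_lateral_left,
        }


def _disc_mask(xx: np.ndarray, yy: np.ndarray, center: tuple[float, float],
               radius: float) -> np.ndarray:
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2


def render_eye_pair(spec: EyeSceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render the scene; returns (H, W, 3) uint8 image and its ground truth.

    Pixel (x, y) membership tests use the pixel's integer centre, with no
    anti-aliasing unless ``spec.antialias`` — so for a noiseless, unoccluded
    scene the pixels strictly darker than the sclera inside an eye opening
    are exactly the iris disc (minus the reflex dot when present).
    """
    h, w = spec.image_height, spec.image_width
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    gray = np.full((h, w), float(spec.intensity_skin))

    a, b = spec.palpebral_half_axes
    for side in ("right", "left"):
        cx, cy = spec.eye_rest_center(side)
        opening = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
        gray[opening] = spec.intensity_sclera

        iris_c = spec.iris_center(side)
        iris = _disc_mask(xx, yy, iris_c, spec.iris_radius)
        gray[iris] = spec.intensity_iris

        reflex_c = spec.reflex_center(side)
        if reflex_c is not None:
            gray[_disc_mask(xx, yy, reflex_c, spec.reflex_radius)] = spec.intensity_reflex

        if spec.eyelid_occlusion_fraction > 0:
            # lid edge measured down from the iris top
            y_lid = (iris_c[1] - spec.iris_radius
                     + spec.eyelid_occlusion_fraction * 2.0 * spec.iris_radius)
            gray[opening & (yy < y_lid)] = spec.intensity_skin

    if spec.antialias:
        from scipy.ndimage import gaussian_filter

        gray = gaussian_filter(gray, sigma=0.7)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        gray = gray + rng.normal(0.0, spec.noise_sd, size=gray.shape)

    img = np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    image = np.repeat(img[:, :, None], 3, axis=2)

    lm_r, lm_l = spec.landmarks("right"), spec.landmarks("left")
    truth = GroundTruth(
        canthus_medial_right=tuple(lm_r[1]),
        canthus_lateral_right=tuple(lm_r[0]),
        canthus_medial_left=tuple(lm_l[1]),
        canthus_lateral_left=tuple(lm_l[0]),
        pupil_center_right=spec.iris_center("right"),
        pupil_center_left=spec.iris_center("left"),
        iris_radius_right=spec.iris_radius,
        iris_radius_left=spec.iris_radius,
        reflex_center_right=spec.reflex_center("right"),
        reflex_center_left=spec.reflex_center("left"),
        label=spec.label,
        landmarks_right=lm_r,
        landmarks_left=lm_l,
    )
    return image, truth


@dataclass(frozen=True)
class SyntheticScene:
    scene_id: str
    image: np.ndarray
    truth: GroundTruth
    spec: EyeSceneSpec


def _exact_missing_count(rate: float, n: int) -> int:
    return int(round(rate * n))


def make_dataset(
    n_normal: int,
    n_strab: int,
    seed: int = 0,
    deviation_range: tuple[float, float] = (7.0, 14.0),
    reflex_missing_rate: float | tuple[float, float] = 0.0,
    *,
    eyelid_occlusion_fraction: float = 0.15,
    noise_sd: float = 0.0,
    base_spec: EyeSceneSpec | None = None,
) -> list[SyntheticScene]:
    """Generate a labelled cohort of synthetic scenes.

    Normal scenes draw per-eye offsets with each component uniform in
    ±1.2 px (near-zero fixation jitter); strabismic scenes deviate one eye
    by a magnitude uniform in ``deviation_range`` along a direction within
    35° of horizontal (mostly eso-/exotropia with a small vertical
    component), keeping the iris inside the palpebral opening.  The
    deviated eye's reflex is displaced opposite the deviation (the reflex
    tracks the light source, not the rotated eye), clipped to stay inside
    the iris.

    ``reflex_missing_rate`` may be a scalar or a (normal, strabismic) pair;
    the expected share of missing-reflex subjects is realised exactly
    (rounded) per class, so rate 0 means every scene has both reflexes and
    rate 1 means none do.
    """
    if n_normal < 0 or n_strab < 0:
        raise ValueError("counts must be non-negative")
    if isinstance(reflex_missing_rate, (int, float)):
        rate_normal = rate_strab = float(reflex_missing_rate)
    else:
        rate_normal, rate_strab = map(float, reflex_missing_rate)
    for r in (rate_normal, rate_strab):
        if not 0.0 <= r <= 1.0:
            raise ValueError("reflex_missing_rate must lie in [0, 1]")
    lo, hi = deviation_range
    if not 0.0 < lo <= hi:
        raise ValueError("deviation_range must satisfy 0 < low <= high")

    template = base_spec if base_spec is not None else EyeSceneSpec()
    if lo <= template.label_threshold_px:
        raise ValueError(
            "deviation_range low end must exceed the label threshold "
            f"({template.label_threshold_px} px) for consistent labels")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    def jitter() -> tuple[float, float]:
        return tuple(rng.uniform(-1.2, 1.2, size=2))

    scenes: list[SyntheticScene] = []
    plans: list[tuple[str, int]] = [(NORMAL, i) for i in range(n_normal)]
    plans += [(STRABISMUS, i) for i in range(n_strab)]

    missing = {NORMAL: set(), STRABISMUS: set()}
    for cls, rate, n in ((NORMAL, rate_normal, n_normal),
                         (STRABISMUS, rate_strab, n_strab)):
        k = _exact_missing_count(rate, n)
        missing[cls] = set(rng.permutation(n)[:k].tolist())

    for cls, idx in plans:
        offsets = {"right": jitter(), "left": jitter()}
        reflex_off = {"right": (0.0, 0.0), "left": (0.0, 0.0)}
        if cls == STRABISMUS:
            deviated = "right" if rng.random() < 0.5 else "left"
            mag = rng.uniform(lo, hi)
            angle = rng.uniform(-math.radians(35), math.radians(35))
            if rng.random() < 0.5:
                angle += math.pi  # esotropia vs exotropia
            dev = (mag * math.cos(angle), mag * math.sin(angle))
            offsets[deviated] = dev
            # reflex lags the rotated eye; clip well inside the iris disc
            # (2.5 px limbus clearance keeps the dot detectable after a
            # sub-pixel circle-fit error)
            rx, ry = -0.4 * dev[0], -0.4 * dev[1]
            max_off = template.iris_radius - template.reflex_radius - 2.5
            norm = math.hypot(rx, ry)
            if norm > max_off:
                rx, ry = rx * max_off / norm, ry * max_off / norm
            reflex_off[deviated] = (rx, ry)

        present = idx not in missing[cls]
        spec = dataclasses.replace(
            template,
            iris_center_offset_right=offsets["right"],
            iris_center_offset_left=offsets["left"],
            reflex_present_right=present,
            reflex_present_left=present,
            reflex_offset_right=reflex_off["right"],
            reflex_offset_left=reflex_off["left"],
            eyelid_occlusion_fraction=eyelid_occlusion_fraction,
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        assert spec.label == cls, "deviation sampling inconsistent with label rule"
        image, truth = render_eye_pair(spec)
        scenes.append(SyntheticScene(f"{cls}_{idx:03d}", image, truth, spec))
    return scenes


def write_dataset(scenes: Sequence[SyntheticScene], out_dir: str | Path) -> Path:
    """Write scene PNGs plus a ground-truth sidecar CSV; returns the CSV path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sc in scenes:
        Image.fromarray(sc.image).save(out / f"{sc.scene_id}.png")
        t = sc.truth
        row: dict[str, object] = {"scene_id": sc.scene_id, "label": t.label}
        for name in ("canthus_medial_right", "canthus_lateral_right",
                     "canthus_medial_left", "canthus_lateral_left",
                     "pupil_center_right", "pupil_center_left"):
            x, y = getattr(t, name)
            row[f"{name}_x"], row[f"{name}_y"] = x, y
        row["iris_radius_right"] = t.iris_radius_right
        row["iris_radius_left"] = t.iris_radius_left
        for name in ("reflex_center_right", "reflex_center_left"):
            c = getattr(t, name)
            row[f"{name}_x"] = c[0] if c is not None else np.nan
            row[f"{name}_y"] = c[1] if c is not None else np.nan
        rows.append(row)
    csv_path = out / "ground_truth.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return csv_path
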
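"""End-to-end orchestration: face image -> processed subject record.

Chains the stages in method order: landmark detection and eye-region
extraction, per-eye iris segmentation and circle fitting, position
similarity, reflex detection and the measured CLR ratio (when both eyes
show a reflex), and the subject-level embedding.

The default embedding input is the eye strip spanning both eye regions
resized to 84x84 (``embed_mode="pair"``); ``embed_mode="concat"``
alternatively embeds each eye crop separately and concatenates the two
vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import position_features as pf
from .embedding_pca import EmbeddingProvider, embed
from .eye_region import (EyeRegion, LandmarkProvider, detect_and_extract,
                         resize_for_embedding)
from .iris_segmentation import IrisCircle, estimate_pupil_center
from .screening_classifier import SubjectRecord
from .synthetic_eye import SyntheticScene


@dataclass(frozen=True)
class SceneMeasurements:
    """Geometry measured from one image, in the face frame."""

    iris_right: IrisCircle
    iris_left: IrisCircle
    position: pf.PositionFeatures
    reflex_right: tuple[float, float] | None
    reflex_left: tuple[float, float] | None
    clr: pf.CLRFeatures | None


def _iris_in_face_frame(region: EyeRegion, circle: IrisCircle) -> IrisCircle:
    cx, cy = region.to_face(circle.center)
    return IrisCircle(center=(cx, cy), radius=circle.radius,
                      rms_residual=circle.rms_residual, n_points=circle.n_points)


def _medial_sign(region: EyeRegion) -> float:
    """+1 when the nose lies in +x from the pupil (subject's right eye in
    the standard frontal frame), -1 otherwise; derived from the canthi."""
    return 1.0 if region.canthus_medial[0] >= region.canthus_lateral[0] else -1.0


def measure_scene(image: np.ndarray, provider: LandmarkProvider) -> SceneMeasurements:
    """Measure iris circles, S, and the CLR features of one face image."""
    right, left = detect_and_extract(image, provider)
    circles: dict[str, IrisCircle] = {}
    reflexes: dict[str, tuple[float, float] | None] = {}
    for region in (right, left):
        local = estimate_pupil_center(region.crop)
        circles[region.side] = _iris_in_face_frame(region, local)
        reflex_local = pf.detect_clr_center(region.crop, local)
        reflexes[region.side] = (region.to_face(reflex_local)
                                 if reflex_local is not None else None)

    position = pf.position_similarity(
        circles["right"].center, circles["left"].center,
        right.canthus_medial, right.canthus_lateral,
        left.canthus_medial, left.canthus_lateral,
    )
    clr = None
    if reflexes["right"] is not None and reflexes["left"] is not None:
        clr = pf.clr_ratio(
            reflexes["right"], reflexes["left"],
            circles["right"], circles["left"],
            medial_sign_right=_medial_sign(right),
            medial_sign_left=_medial_sign(left),
        )
    return SceneMeasurements(
        iris_right=circles["right"], iris_left=circles["left"],
        position=position,
        reflex_right=reflexes["right"], reflex_left=reflexes["left"],
        clr=clr,
    )


def embedding_input(image: np.ndarray, right: EyeRegion, left: EyeRegion) -> np.ndarray:
    """Crop the strip spanning both eye regions and resize it to 84x84."""
    (rx, ry), (lx, ly) = right.origin, left.origin
    rh, rw = right.crop.shape[:2]
    lh, lw = left.crop.shape[:2]
    x0, y0 = min(rx, lx), min(ry, ly)
    x1 = max(rx + rw, lx + lw)
    y1 = max(ry + rh, ly + lh)
    return resize_for_embedding(image[y0:y1, x0:x1])


def embed_scene(image: np.ndarray, provider: LandmarkProvider,
                embedding_provider: EmbeddingProvider,
                embed_mode: str = "pair") -> np.ndarray:
    right, left = detect_and_extract(image, provider)
    if embed_mode == "pair":
        return embed(embedding_input(image, right, left), embedding_provider)
    if embed_mode == "concat":
        return np.concatenate([
            embed(resize_for_embedding(right), embedding_provider),
            embed(resize_for_embedding(left), embedding_provider),
        ])
    raise ValueError(f"unknown embed_mode {embed_mode!r}")


def process_scene(
    image: np.ndarray,
    provider: LandmarkProvider,
    embedding_provider: EmbeddingProvider,
    *,
    subject_id: str,
    label: str,
    embed_mode: str = "pair",
) -> SubjectRecord:
    """Measure one labelled face image into a protocol-ready record."""
    meas = measure_scene(image, provider)
    vector = embed_scene(image, provider, embedding_provider, embed_mode)
    return SubjectRecord(
        subject_id=subject_id,
        label=label,
        embedding=vector,
        S=meas.position.S,
        clr_ratio=meas.clr.ratio if meas.clr is not None else None,
        clr_provenance=(pf.MEASURED if meas.clr is not None else "missing"),
    )


def process_synthetic_cohort(
    scenes: list[SyntheticScene],
    embedding_provider: EmbeddingProvider,
    *,
    use_truth_landmarks: bool = True,
    embed_mode: str = "pair",
) -> list[SubjectRecord]:
    """Run the full pipeline over a synthetic cohort.

    With ``use_truth_landmarks`` the landmark stage replays each scene's
    ground truth (isolating the downstream stages); otherwise the heuristic
    detector runs.
    """
    from .eye_region import GroundTruthProvider, HeuristicLandmarkProvider

    records = []
    detector = HeuristicLandmarkProvider()
    for sc in scenes:
        provider = GroundTruthProvider(sc.truth) if use_truth_landmarks else detector
        records.append(process_scene(
            sc.image, provider, embedding_provider,
            subject_id=sc.scene_id, label=sc.truth.label, embed_mode=embed_mode,
        ))
    return records
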
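"""RULA scoring from two-plane 2D pose keypoints.

A posture is captured as two 17-keypoint stick figures (the standard COCO /
MoveNet layout) — one sagittal (side view) and one frontal snapshot — plus a
small set of manual annotations for transverse-plane items that planar
keypoints cannot measure (twists, forearm rotation, hand alignment, arm
support).  The extraction rules mirror how an ergonomist reads joint angles
off the two images:

* upper-arm flexion: sagittal angle between the shoulder-hip line and the
  shoulder-elbow axis (signed; extension negative);
* lower-arm flexion: sagittal angle between the shoulder-elbow line and the
  elbow-wrist axis;
* neck flexion: sagittal angle between the shoulder-hip line (extended
  upward) and the shoulder-ear axis;
* trunk flexion: sagittal inclination of the hip->shoulder line against the
  image vertical (the cameras are levelled, so image-vertical is taken as
  gravity-aligned);
* wrist deviation: sagittal angle between the elbow-wrist line and the
  annotated hand-direction vector (no hand keypoint exists in the layout);
* abduction / shoulder raise / midline crossing / eye-line tilt / trunk side
  lean: frontal-plane threshold rules.

Image coordinates are pixels with y increasing downward.  Only one body side
(default right) is scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

from .core import RulaInputs, RulaResult, score_posture
from .errors import DegenerateGeometryError, InputError, OcclusionError

__all__ = [
    "KEYPOINT_NAMES",
    "Skeleton2D",
    "ManualAnnotations",
    "PoseConfig",
    "line_angle",
    "signed_angle",
    "extract_rula_inputs",
    "score_pose_capture",
]

KEYPOINT_NAMES = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

Point = tuple[float, float]


@dataclass
class Skeleton2D:
    """All 17 named keypoints of one person in one anatomical plane."""

    plane: Literal["frontal", "sagittal"]
    keypoints: dict[str, Point]
    confidence: dict[str, float]

    def __post_init__(self) -> None:
        if self.plane not in ("frontal", "sagittal"):
            raise InputError(f"unknown plane {self.plane!r}")
        missing = set(KEYPOINT_NAMES) - set(self.keypoints)
        if missing:
            raise InputError(f"missing keypoints: {sorted(missing)}")
        unknown = set(self.keypoints) - set(KEYPOINT_NAMES)
        if unknown:
            raise InputError(f"unknown keypoints: {sorted(unknown)}")
        for name, (x, y) in self.keypoints.items():
            if not (math.isfinite(x) and math.isfinite(y)):
                raise InputError(f"non-finite coordinate for keypoint {name!r}")
            c = self.confidence.get(name, 1.0)
            if not (0.0 <= c <= 1.0):
                raise InputError(f"confidence for {name!r} must be in [0, 1], got {c}")

    def point(self, name: str, min_confidence: float) -> Point:
        if self.confidence.get(name, 1.0) < min_confidence:
            raise OcclusionError(name, self.plane)
        return self.keypoints[name]


@dataclass
class ManualAnnotations:
    """Ergonomist-supplied items that 2D keypoints cannot measure.

    ``hand_direction`` maps a plane name to a unit vector (image coordinates)
    along the hand, used to measure wrist deviation against the forearm line.
    """

    neck_twist: bool = False
    trunk_twist: bool = False
    wrist_twist_near_end_range: bool = False
    wrist_bent_from_midline: bool = False
    arm_supported: bool = False
    hand_direction: dict[str, Point] | None = None

    def __post_init__(self) -> None:
        if self.hand_direction is not None:
            for plane, (dx, dy) in self.hand_direction.items():
                norm = math.hypot(dx, dy)
                if not math.isclose(norm, 1.0, abs_tol=1e-6):
                    raise InputError(
                        f"hand_direction for plane {plane!r} must be a unit vector"
                    )


@dataclass
class PoseConfig:
    """Thresholds and conventions for keypoint-based extraction."""

    facing: Literal["left", "right"] = "right"  # profile direction in the sagittal image
    side: Literal["left", "right"] = "right"  # which arm/wrist is scored
    abduction_threshold_deg: float = 20.0
    shoulder_raise_threshold_deg: float = 5.0
    neck_side_tilt_tol_deg: float = 1.0
    trunk_side_tilt_threshold_deg: float = 5.0
    confidence_min: float = 0.3
    wrist_from_annotations_only: bool = False
    trunk_upright_tol_deg: float = 2.0


def _vec(p: Point, q: Point) -> Point:
    return (q[0] - p[0], q[1] - p[1])


def _check_nonzero(v: Point, what: str = "segment") -> None:
    if math.hypot(*v) < 1e-12:
        raise DegenerateGeometryError(f"{what} has coincident endpoints")


def signed_angle(u: Point, v: Point) -> float:
    """Signed angle in degrees from vector ``u`` to vector ``v`` in (-180, 180]."""
    _check_nonzero(u, "first vector")
    _check_nonzero(v, "second vector")
    cross = u[0] * v[1] - u[1] * v[0]
    dot = u[0] * v[0] + u[1] * v[1]
    return math.degrees(math.atan2(cross, dot))


def line_angle(p1: Point, p2: Point, q1: Point, q2: Point) -> float:
    """Unsigned angle in [0, 180] degrees between segments p1->p2 and q1->q2."""
    u = _vec(p1, p2)
    v = _vec(q1, q2)
    _check_nonzero(u, "segment p1->p2")
    _check_nonzero(v, "segment q1->q2")
    cross = abs(u[0] * v[1] - u[1] * v[0])
    dot = u[0] * v[0] + u[1] * v[1]
    return math.degrees(math.atan2(cross, dot))


def _inclination_from_horizontal(p: Point, q: Point) -> float:
    """Acute angle in degrees between line p-q and the image horizontal."""
    a = line_angle(p, q, (0.0, 0.0), (1.0, 0.0))
    return min(a, 180.0 - a)


def _inclination_from_vertical(p: Point, q: Point) -> float:
    a = line_angle(p, q, (0.0, 0.0), (0.0, 1.0))
    return min(a, 180.0 - a)


def extract_rula_inputs(
    sagittal: Skeleton2D,
    frontal: Skeleton2D,
    ann: ManualAnnotations,
    cfg: PoseConfig | None = None,
) -> RulaInputs:
    """Measure all RULA items from the two snapshots plus annotations.

    Raises :class:`OcclusionError` when a keypoint required by a rule falls
    below ``cfg.confidence_min``, and :class:`InputError` when the wrist must
    be measured but no hand direction was annotated.
    """
    cfg = cfg or PoseConfig()
    if sagittal.plane != "sagittal" or frontal.plane != "frontal":
        raise InputError("skeleton planes do not match the argument order")
    side = cfg.side
    other = "left" if side == "right" else "right"
    f = 1.0 if cfg.facing == "right" else -1.0

    def sag(name: str) -> Point:
        return sagittal.point(name, cfg.confidence_min)

    def fro(name: str) -> Point:
        return frontal.point(name, cfg.confidence_min)

    shoulder = sag(f"{side}_shoulder")
    hip = sag(f"{side}_hip")
    elbow = sag(f"{side}_elbow")
    wrist = sag(f"{side}_wrist")
    ear = sag(f"{side}_ear")

    trunk_down = _vec(shoulder, hip)  # shoulder -> hip

    # Upper arm: signed so that flexion toward the facing direction is positive.
    upper_arm_flexion = -f * signed_angle(trunk_down, _vec(shoulder, elbow))

    # Neck: shoulder->ear points opposite the trunk line; unfold to a signed
    # flexion where extension (ear behind the trunk line) is negative.
    s = signed_angle(trunk_down, _vec(shoulder, ear))
    neck_flexion = f * (-math.copysign(1.0, s)) * (180.0 - abs(s))

    lower_arm_flexion = line_angle(shoulder, elbow, elbow, wrist)

    trunk_signed = signed_angle((0.0, -1.0), _vec(hip, shoulder))
    trunk_flexion = f * trunk_signed

    # Wrist: forearm line against the annotated hand direction.
    if ann.hand_direction is not None and "sagittal" in ann.hand_direction:
        hand = ann.hand_direction["sagittal"]
        wrist_deviation = -f * signed_angle(_vec(elbow, wrist), hand)
    elif cfg.wrist_from_annotations_only:
        wrist_deviation = 0.0
    else:
        raise InputError(
            "wrist unmeasurable: no sagittal hand_direction annotation "
            "(set wrist_from_annotations_only to score from flags alone)"
        )

    # Frontal-plane threshold rules.
    r_sh = fro(f"{side}_shoulder")
    l_sh = fro(f"{other}_shoulder")
    r_hip_f = fro(f"{side}_hip")
    l_hip_f = fro(f"{other}_hip")
    elbow_f = fro(f"{side}_elbow")
    wrist_f = fro(f"{side}_wrist")
    eye_s = fro(f"{side}_eye")
    eye_o = fro(f"{other}_eye")

    shoulder_raised = (
        _inclination_from_horizontal(l_sh, r_sh) > cfg.shoulder_raise_threshold_deg
    )
    abduction_angle = 180.0 - line_angle(r_hip_f, r_sh, r_sh, elbow_f)
    upper_arm_abducted = abduction_angle > cfg.abduction_threshold_deg

    mid_hip_x = 0.5 * (r_hip_f[0] + l_hip_f[0])
    toward_other = l_hip_f[0] - mid_hip_x
    arm_across = (wrist_f[0] - mid_hip_x) * toward_other > 0.0

    neck_side_tilt = (
        _inclination_from_horizontal(eye_s, eye_o) > cfg.neck_side_tilt_tol_deg
    )

    mid_hip = (mid_hip_x, 0.5 * (r_hip_f[1] + l_hip_f[1]))
    mid_sh = (0.5 * (r_sh[0] + l_sh[0]), 0.5 * (r_sh[1] + l_sh[1]))
    trunk_side_tilt = (
        _inclination_from_vertical(mid_hip, mid_sh) > cfg.trunk_side_tilt_threshold_deg
    )

    return RulaInputs(
        upper_arm_flexion=upper_arm_flexion,
        shoulder_raised=shoulder_raised,
        upper_arm_abducted=upper_arm_abducted,
        arm_supported=ann.arm_supported,
        lower_arm_flexion=lower_arm_flexion,
        arm_across_midline_or_out=arm_across,
        wrist_deviation=wrist_deviation,
        wrist_bent_from_midline=ann.wrist_bent_from_midline,
        wrist_twist_near_end_range=ann.wrist_twist_near_end_range,
        neck_flexion=neck_flexion,
        neck_twist=ann.neck_twist,
        neck_side_tilt=neck_side_tilt,
        trunk_flexion=trunk_flexion,
        trunk_twist=ann.trunk_twist,
        trunk_side_tilt=trunk_side_tilt,
        legs_supported=True,  # seated task: legs/feet supported by design
    )


def score_pose_capture(
    sagittal: Skeleton2D,
    frontal: Skeleton2D,
    ann: ManualAnnotations,
    cfg: PoseConfig | None = None,
) -> RulaResult:
    """Extract RULA inputs from one two-plane capture and score them."""
    cfg = cfg or PoseConfig()
    inputs = extract_rula_inputs(sagittal, frontal, ann, cfg)
    return score_posture(inputs, trunk_upright_tol=cfg.trunk_upright_tol_deg)
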
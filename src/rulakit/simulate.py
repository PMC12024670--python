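"""Synthetic seated-posture cohorts for exercising both scoring branches.

The generator emulates the data-generating setting of a static-holding
ergonomic study: every participant adopts one "true" working posture
(shared joint angles and posture flags), which is then observed by two
technologies —

* an IMU-style branch producing a 30 s joint-angle stream at a fixed rate,
  with AR(1) jitter plus slow linear drift around the true angles, and
* a pose-estimation branch producing one frontal and one sagittal 17-keypoint
  stick-figure snapshot, built by 2D forward kinematics from the true angles
  perturbed by per-region bias and angle-equivalent noise, with pixel jitter
  on every keypoint.

True angles are drawn from truncated normal distributions and flags from
Bernoulli draws; anthropometry is resampled per participant from published
female-cohort summary statistics (mean/SD truncated at min/max).  All noise
magnitudes are explicit configuration so the downstream inter-method
agreement (weighted kappa) is tunable; :func:`calibrate_pose_noise` inverts
the monotone kappa-vs-noise relationship for a target kappa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal, stats

from .agreement import round_to_levels, weighted_kappa
from .core import ANGLE_FIELDS, RulaInputs, RulaResult, score_posture, score_posture_arrays
from .errors import ConfigError, UndefinedKappaError
from .pose import KEYPOINT_NAMES, ManualAnnotations, PoseConfig, Skeleton2D, extract_rula_inputs, score_pose_capture
from .stream import REGIONS, AngleStream

__all__ = [
    "Anthropometry",
    "AngleSpec",
    "ImuNoise",
    "PoseNoise",
    "CohortConfig",
    "CohortData",
    "sample_anthropometry",
    "sample_true_postures",
    "render_imu_stream",
    "skeleton_from_angles",
    "render_pose_capture",
    "simulate_cohort",
    "generate_cohort",
    "cohort_overall_kappa",
    "mean_overall_kappa",
    "calibrate_pose_noise",
]


# --------------------------------------------------------------------------
# Anthropometry (published female seated-work cohort summary statistics, cm).
# --------------------------------------------------------------------------

ANTHRO_STATS = {
    # field: (mean, sd, min, max)
    "height": (165.00, 6.35, 152.20, 178.40),
    "shoulder_height": (138.74, 5.42, 125.50, 150.00),
    "shoulder_width": (37.97, 2.75, 29.80, 44.40),
    "elbow_span": (81.42, 4.27, 72.80, 89.20),
    "wrist_span": (126.95, 11.38, 110.50, 187.20),
}


@dataclass(frozen=True)
class Anthropometry:
    """Body dimensions (cm) from which stick-figure segment lengths derive."""

    height: float = 165.00
    shoulder_height: float = 138.74
    shoulder_width: float = 37.97
    elbow_span: float = 81.42
    wrist_span: float = 126.95

    def __post_init__(self) -> None:
        for name in ("height", "shoulder_height", "shoulder_width", "elbow_span", "wrist_span"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"anthropometry field {name} must be positive")
        if self.upper_arm_len <= 0 or self.forearm_len <= 0:
            raise ConfigError("arm spans must increase: shoulder < elbow < wrist span")

    # Segment lengths.  Arm segments come from span differences (span = two
    # segments plus shoulder width); axial segments use standard proportions
    # of stature.
    @property
    def upper_arm_len(self) -> float:
        return (self.elbow_span - self.shoulder_width) / 2.0

    @property
    def forearm_len(self) -> float:
        return (self.wrist_span - self.elbow_span) / 2.0

    @property
    def trunk_len(self) -> float:
        return 0.288 * self.height

    @property
    def neck_len(self) -> float:  # shoulder to ear
        return 0.105 * self.height

    @property
    def hip_width(self) -> float:
        return 0.55 * self.shoulder_width

    @property
    def eye_span(self) -> float:
        return 0.17 * self.shoulder_width

    def scaled(self, factor: float) -> "Anthropometry":
        return Anthropometry(
            self.height * factor,
            self.shoulder_height * factor,
            self.shoulder_width * factor,
            self.elbow_span * factor,
            self.wrist_span * factor,
        )


def _truncnorm(mean, sd, lo, hi, size, rng):
    if sd == 0:
        return np.full(size, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_anthropometry(rng: np.random.Generator) -> Anthropometry:
    """Draw one participant's body dimensions from the cohort statistics."""
    values = {
        name: float(_truncnorm(*ANTHRO_STATS[name], size=1, rng=rng)[0])
        for name in ANTHRO_STATS
    }
    # Enforce span ordering; resampling is cheap and rarely needed.
    while not (values["shoulder_width"] < values["elbow_span"] < values["wrist_span"]):
        values = {
            name: float(_truncnorm(*ANTHRO_STATS[name], size=1, rng=rng)[0])
            for name in ANTHRO_STATS
        }
    return Anthropometry(**values)


# --------------------------------------------------------------------------
# Cohort configuration.
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AngleSpec:
    """Truncated-normal distribution for one true joint angle (degrees)."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigError("angle SD must be >= 0")
        if not self.lo <= self.mean <= self.hi:
            raise ConfigError("angle mean must lie within its truncation bounds")

    def sample(self, size, rng):
        return _truncnorm(self.mean, self.sd, self.lo, self.hi, size, rng)


def _default_angles() -> dict[str, AngleSpec]:
    # Calibrated once so the IMU-branch cohort mean overall RULA sits in the
    # moderate-risk range (~4.8); see docs/methods.md.
    return {
        "upper_arm_flexion": AngleSpec(40.0, 22.0, -10.0, 120.0),
        "lower_arm_flexion": AngleSpec(110.0, 25.0, 20.0, 160.0),
        "wrist_deviation": AngleSpec(12.0, 8.0, -30.0, 45.0),
        "neck_flexion": AngleSpec(15.0, 13.0, -15.0, 60.0),
        "trunk_flexion": AngleSpec(7.0, 6.0, -5.0, 40.0),
    }


def _default_flag_probs() -> dict[str, float]:
    return {
        "shoulder_raised": 0.15,
        "upper_arm_abducted": 0.30,
        "arm_supported": 0.10,
        "arm_across_midline_or_out": 0.40,
        "wrist_bent_from_midline": 0.35,
        "wrist_twist_near_end_range": 0.50,
        "neck_twist": 0.15,
        "neck_side_tilt": 0.15,
        "trunk_twist": 0.05,
        "trunk_side_tilt": 0.05,
    }


@dataclass(frozen=True)
class ImuNoise:
    """Measurement model of the motion-capture branch (degrees)."""

    white_sd_deg: float = 2.0
    ar1: float = 0.9
    drift_deg_per_s: float = 0.02

    def __post_init__(self) -> None:
        if self.white_sd_deg < 0:
            raise ConfigError("white noise SD must be >= 0")
        if not (0.0 <= self.ar1 < 1.0):
            raise ConfigError("AR(1) coefficient must lie in [0, 1)")


@dataclass(frozen=True)
class PoseNoise:
    """Measurement model of the pose-estimation branch."""

    keypoint_jitter_px: float = 1.0
    angle_sd_deg: float = 6.0

    def __post_init__(self) -> None:
        if self.keypoint_jitter_px < 0 or self.angle_sd_deg < 0:
            raise ConfigError("pose noise magnitudes must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate one synthetic cohort."""

    n_participants: int = 45
    angles: dict[str, AngleSpec] = field(default_factory=_default_angles)
    flag_probs: dict[str, float] = field(default_factory=_default_flag_probs)
    imu_noise: ImuNoise = field(default_factory=ImuNoise)
    pose_noise: PoseNoise = field(default_factory=PoseNoise)
    region_bias: Mapping[str, float] = field(
        default_factory=lambda: {"trunk_flexion": 4.0}
    )
    stream_rate: float = 60.0
    stream_duration: float = 30.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ConfigError("a cohort needs at least 2 participants")
        if self.stream_rate <= 0 or self.stream_duration <= 0:
            raise ConfigError("stream rate and duration must be positive")
        missing = set(ANGLE_FIELDS) - set(self.angles)
        if missing:
            raise ConfigError(f"angle specs missing for {sorted(missing)}")
        for name, p in self.flag_probs.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"flag probability {name} must be in [0, 1]")
        unknown = set(self.region_bias) - set(ANGLE_FIELDS)
        if unknown:
            raise ConfigError(f"region_bias for unknown angles: {sorted(unknown)}")

    def with_pose_angle_sd(self, angle_sd: float) -> "CohortConfig":
        return replace(self, pose_noise=replace(self.pose_noise, angle_sd_deg=angle_sd))

    @classmethod
    def zero_noise(cls, **kwargs) -> "CohortConfig":
        """Both branches observe the true posture exactly."""
        kwargs.setdefault("imu_noise", ImuNoise(0.0, 0.0, 0.0))
        kwargs.setdefault("pose_noise", PoseNoise(0.0, 0.0))
        kwargs.setdefault("region_bias", {})
        return cls(**kwargs)


# --------------------------------------------------------------------------
# True postures.
# --------------------------------------------------------------------------


def sample_true_postures(
    cfg: CohortConfig, rng: np.random.Generator | None = None
) -> list[RulaInputs]:
    """Draw each participant's true posture (angles plus flags)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = cfg.n_participants
    angles = {name: spec.sample(n, rng) for name, spec in cfg.angles.items()}
    flags = {name: rng.random(n) < p for name, p in cfg.flag_probs.items()}
    out = []
    for i in range(n):
        out.append(
            RulaInputs(
                **{name: float(col[i]) for name, col in angles.items()},
                **{name: bool(col[i]) for name, col in flags.items()},
                legs_supported=True,
            )
        )
    return out


# --------------------------------------------------------------------------
# IMU branch.
# --------------------------------------------------------------------------


def _imu_angle_matrix(
    true: RulaInputs, cfg: CohortConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-frame angle tracks: true value + linear drift + stationary AR(1)."""
    n = int(round(cfg.stream_rate * cfg.stream_duration))
    t = np.arange(n) / cfg.stream_rate
    noise_cfg = cfg.imu_noise
    tracks = {}
    for name in ANGLE_FIELDS:
        base = getattr(true, name) + noise_cfg.drift_deg_per_s * t
        sd = noise_cfg.white_sd_deg
        if sd > 0:
            phi = noise_cfg.ar1
            w = rng.normal(0.0, sd * math.sqrt(1.0 - phi**2), size=n)
            e = signal.lfilter([1.0], [1.0, -phi], w)
            # stationary start instead of a zero start
            e += rng.normal(0.0, sd) * phi ** np.arange(1, n + 1)
            base = base + e
        tracks[name] = base
    return tracks


def render_imu_stream(
    true: RulaInputs, cfg: CohortConfig, rng: np.random.Generator | None = None
) -> AngleStream:
    """Simulated motion-capture take for one participant's true posture."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    tracks = _imu_angle_matrix(true, cfg, rng)
    n = len(next(iter(tracks.values())))
    frames = [
        true.replace(**{name: float(tracks[name][i]) for name in ANGLE_FIELDS})
        for i in range(n)
    ]
    return AngleStream(rate=cfg.stream_rate, frames=frames)


def _imu_aggregates(
    true: RulaInputs, cfg: CohortConfig, rng: np.random.Generator
) -> dict[str, float]:
    """Time-weighted aggregate scores without materialising frame objects.

    Shares :func:`_imu_angle_matrix` with :func:`render_imu_stream`, so the
    two paths score identical angle tracks for a given generator state.
    """
    tracks = _imu_angle_matrix(true, cfg, rng)
    scored = score_posture_arrays(
        tracks["upper_arm_flexion"],
        true.shoulder_raised,
        true.upper_arm_abducted,
        true.arm_supported,
        tracks["lower_arm_flexion"],
        true.arm_across_midline_or_out,
        tracks["wrist_deviation"],
        true.wrist_bent_from_midline,
        true.wrist_twist_near_end_range,
        tracks["neck_flexion"],
        true.neck_twist,
        true.neck_side_tilt,
        tracks["trunk_flexion"],
        true.trunk_twist,
        true.trunk_side_tilt,
        true.legs_supported,
        true.muscle_use_arm,
        true.force_load_arm,
        true.muscle_use_trunk,
        true.force_load_trunk,
    )
    out = {"overall": float(scored["grand"].mean())}
    for region in REGIONS:
        out[region] = float(scored[region].mean())
    return out


# --------------------------------------------------------------------------
# Pose branch: 2D forward kinematics.
# --------------------------------------------------------------------------

PX_PER_CM = 4.0
SAGITTAL_ORIGIN = (320.0, 400.0)
FRONTAL_ORIGIN = (320.0, 400.0)
VISIBLE_CONF = 0.95
OCCLUDED_CONF = 0.1

# Frontal rendering angles used to express posture flags geometrically.
ABDUCTION_RENDER_DEG = {False: 5.0, True: 30.0}
SHOULDER_RAISE_RENDER_DEG = {False: 0.0, True: 10.0}
EYE_TILT_RENDER_DEG = {False: 0.0, True: 6.0}
TRUNK_LEAN_RENDER_DEG = {False: 0.0, True: 8.0}


def _rot(deg: float) -> tuple[float, float]:
    r = math.radians(deg)
    return math.sin(r), math.cos(r)


def _sagittal_points(
    inputs: RulaInputs, anthro: Anthropometry, f: float, scale: float, origin
) -> dict[str, tuple[float, float]]:
    ox, oy = origin
    t = inputs.trunk_flexion
    ua = inputs.upper_arm_flexion
    la = inputs.lower_arm_flexion
    nk = inputs.neck_flexion
    s = scale
    hip = (ox, oy)
    st, ct = _rot(t)
    shoulder = (hip[0] + anthro.trunk_len * st * f * s, hip[1] - anthro.trunk_len * ct * s)
    # The upper arm is flexed relative to the trunk line; from the shoulder
    # the trunk line continues downward at angle -t from the image vertical.
    s1, c1 = _rot(ua - t)
    elbow = (
        shoulder[0] + anthro.upper_arm_len * s1 * f * s,
        shoulder[1] + anthro.upper_arm_len * c1 * s,
    )
    s2, c2 = _rot(ua - t + la)
    wrist = (
        elbow[0] + anthro.forearm_len * s2 * f * s,
        elbow[1] + anthro.forearm_len * c2 * s,
    )
    sn, cn = _rot(t + nk)
    ear = (
        shoulder[0] + anthro.neck_len * sn * f * s,
        shoulder[1] - anthro.neck_len * cn * s,
    )
    eye = (ear[0] + 0.35 * anthro.neck_len * f * s, ear[1] - 0.05 * anthro.neck_len * s)
    nose = (ear[0] + 0.55 * anthro.neck_len * f * s, ear[1] + 0.15 * anthro.neck_len * s)
    thigh = 0.245 * anthro.height
    shank = 0.246 * anthro.height
    knee = (hip[0] + thigh * f * s, hip[1])
    ankle = (knee[0], knee[1] + shank * s)
    return {
        "hip": hip,
        "shoulder": shoulder,
        "elbow": elbow,
        "wrist": wrist,
        "ear": ear,
        "eye": eye,
        "nose": nose,
        "knee": knee,
        "ankle": ankle,
    }


def _frontal_points(
    inputs: RulaInputs, anthro: Anthropometry, side: str, scale: float, origin
) -> dict[str, tuple[float, float]]:
    # Person faces the camera; the scored side appears at negative x.
    ox, oy = origin
    s = scale
    lean = TRUNK_LEAN_RENDER_DEG[inputs.trunk_side_tilt]
    raise_deg = SHOULDER_RAISE_RENDER_DEG[inputs.shoulder_raised]
    eye_tilt = EYE_TILT_RENDER_DEG[inputs.neck_side_tilt]
    abd = ABDUCTION_RENDER_DEG[inputs.upper_arm_abducted]

    hw = anthro.hip_width * s
    sw = anthro.shoulder_width * s
    trunk = anthro.trunk_len * math.cos(math.radians(inputs.trunk_flexion)) * s

    hip_s = (ox - hw / 2.0, oy)  # scored side
    hip_o = (ox + hw / 2.0, oy)
    sl, cl = _rot(lean)
    mid_sh = (ox + trunk * sl, oy - trunk * cl)
    # Shoulder line kept level apart from the single-shoulder raise (the head
    # and shoulders are assumed to compensate a sideways trunk lean).
    sr, cr = _rot(raise_deg)
    sh_s = (mid_sh[0] - (sw / 2.0) * cr, mid_sh[1] - (sw / 2.0) * sr)
    sh_o = (mid_sh[0] + (sw / 2.0) * cr, mid_sh[1] + (sw / 2.0) * sr)

    ua_len = anthro.upper_arm_len * s
    fa_len = anthro.forearm_len * s
    # The upper arm hangs along the hip->shoulder line (the reference of the
    # frontal abduction rule), rotated outward by the abduction angle.
    ddx, ddy = hip_s[0] - sh_s[0], hip_s[1] - sh_s[1]
    dn = math.hypot(ddx, ddy)
    ddx, ddy = ddx / dn, ddy / dn
    sa, ca = _rot(abd)
    arm_dir = (ddx * ca - ddy * sa, ddx * sa + ddy * ca)  # outward = toward -x
    elbow_s = (sh_s[0] + ua_len * arm_dir[0], sh_s[1] + ua_len * arm_dir[1])
    elbow_o = (sh_o[0] + ua_len * math.sin(math.radians(5.0)), sh_o[1] + ua_len * math.cos(math.radians(5.0)))
    if inputs.arm_across_midline_or_out:
        wrist_s = (ox + 0.15 * sw, elbow_s[1] + 0.3 * fa_len)
    else:
        wrist_s = (elbow_s[0], elbow_s[1] + fa_len)
    wrist_o = (elbow_o[0], elbow_o[1] + fa_len)

    head_c = (mid_sh[0], mid_sh[1] - 0.11 * anthro.height * s)
    es = anthro.eye_span * s
    se_, ce_ = _rot(eye_tilt)
    eye_s = (head_c[0] - (es / 2.0) * ce_, head_c[1] - (es / 2.0) * se_)
    eye_o = (head_c[0] + (es / 2.0) * ce_, head_c[1] + (es / 2.0) * se_)
    ear_s = (head_c[0] - 1.3 * es, head_c[1] + 0.05 * es)
    ear_o = (head_c[0] + 1.3 * es, head_c[1] + 0.05 * es)
    nose = (head_c[0], head_c[1] + 0.4 * es)

    knee_s = (hip_s[0] - 0.1 * hw, oy + 0.15 * anthro.height * s)
    knee_o = (hip_o[0] + 0.1 * hw, oy + 0.15 * anthro.height * s)
    ankle_s = (knee_s[0], knee_s[1] + 0.2 * anthro.height * s)
    ankle_o = (knee_o[0], knee_o[1] + 0.2 * anthro.height * s)
    return {
        "hip_s": hip_s,
        "hip_o": hip_o,
        "shoulder_s": sh_s,
        "shoulder_o": sh_o,
        "elbow_s": elbow_s,
        "elbow_o": elbow_o,
        "wrist_s": wrist_s,
        "wrist_o": wrist_o,
        "eye_s": eye_s,
        "eye_o": eye_o,
        "ear_s": ear_s,
        "ear_o": ear_o,
        "nose": nose,
        "knee_s": knee_s,
        "knee_o": knee_o,
        "ankle_s": ankle_s,
        "ankle_o": ankle_o,
    }


def skeleton_from_angles(
    inputs: RulaInputs,
    anthro: Anthropometry | None = None,
    plane: str = "sagittal",
    *,
    jitter_px: float = 0.0,
    rng: np.random.Generator | None = None,
    facing: str = "right",
    side: str = "right",
    px_per_cm: float = PX_PER_CM,
    origin: tuple[float, float] | None = None,
) -> Skeleton2D:
    """Deterministic stick figure for one posture in one plane.

    The sagittal figure places the hip at the origin and positions shoulder,
    elbow, wrist and ear by the trunk, upper-arm, lower-arm and neck angles;
    the frontal figure expresses the threshold-based flags (abduction,
    shoulder raise, midline crossing, eye-line tilt, trunk side lean)
    geometrically.  Optional Gaussian pixel jitter is applied to every
    keypoint.
    """
    anthro = anthro or Anthropometry()
    f = 1.0 if facing == "right" else -1.0
    other = "left" if side == "right" else "right"
    if plane == "sagittal":
        origin = origin or SAGITTAL_ORIGIN
        pts = _sagittal_points(inputs, anthro, f, px_per_cm, origin)
        keypoints = {}
        confidence = {}
        near = {
            "hip": "hip",
            "shoulder": "shoulder",
            "elbow": "elbow",
            "wrist": "wrist",
            "ear": "ear",
            "eye": "eye",
            "knee": "knee",
            "ankle": "ankle",
        }
        for joint, key in near.items():
            keypoints[f"{side}_{joint}"] = pts[key]
            confidence[f"{side}_{joint}"] = VISIBLE_CONF
            # contralateral joints hidden behind the body in a profile view
            keypoints[f"{other}_{joint}"] = pts[key]
            confidence[f"{other}_{joint}"] = OCCLUDED_CONF
        keypoints["nose"] = pts["nose"]
        confidence["nose"] = VISIBLE_CONF
    elif plane == "frontal":
        origin = origin or FRONTAL_ORIGIN
        pts = _frontal_points(inputs, anthro, side, px_per_cm, origin)
        keypoints = {"nose": pts["nose"]}
        confidence = {"nose": VISIBLE_CONF}
        for joint in ("hip", "shoulder", "elbow", "wrist", "eye", "ear", "knee", "ankle"):
            keypoints[f"{side}_{joint}"] = pts[f"{joint}_s"]
            keypoints[f"{other}_{joint}"] = pts[f"{joint}_o"]
            confidence[f"{side}_{joint}"] = VISIBLE_CONF
            confidence[f"{other}_{joint}"] = VISIBLE_CONF
    else:
        raise ConfigError(f"unknown plane {plane!r}")

    if jitter_px > 0:
        if rng is None:
            raise ConfigError("keypoint jitter requires a random generator")
        keypoints = {
            name: (x + rng.normal(0.0, jitter_px), y + rng.normal(0.0, jitter_px))
            for name, (x, y) in keypoints.items()
        }
    return Skeleton2D(plane=plane, keypoints=keypoints, confidence=confidence)


def render_pose_capture(
    inputs: RulaInputs,
    anthro: Anthropometry | None = None,
    *,
    jitter_px: float = 0.0,
    rng: np.random.Generator | None = None,
    facing: str = "right",
    side: str = "right",
) -> tuple[Skeleton2D, Skeleton2D, ManualAnnotations]:
    """Both snapshot skeletons plus the matching manual annotations.

    The annotated hand-direction vector is the sagittal forearm direction
    rotated by the wrist deviation, exactly as an ergonomist would mark the
    hand axis on the image.
    """
    sag = skeleton_from_angles(
        inputs, anthro, "sagittal", jitter_px=jitter_px, rng=rng, facing=facing, side=side
    )
    fro = skeleton_from_angles(
        inputs, anthro, "frontal", jitter_px=jitter_px, rng=rng, facing=facing, side=side
    )
    f = 1.0 if facing == "right" else -1.0
    phi = inputs.upper_arm_flexion - inputs.trunk_flexion + inputs.lower_arm_flexion
    sh, ch = _rot(phi + inputs.wrist_deviation)
    ann = ManualAnnotations(
        neck_twist=inputs.neck_twist,
        trunk_twist=inputs.trunk_twist,
        wrist_twist_near_end_range=inputs.wrist_twist_near_end_range,
        wrist_bent_from_midline=inputs.wrist_bent_from_midline,
        arm_supported=inputs.arm_supported,
        hand_direction={"sagittal": (sh * f, ch)},
    )
    return sag, fro, ann


# --------------------------------------------------------------------------
# Whole cohorts.
# --------------------------------------------------------------------------


@dataclass
class CohortData:
    """In-memory synthetic cohort: truth plus both branches' scores."""

    config: CohortConfig
    true_inputs: list[RulaInputs]
    true_results: list[RulaResult]
    anthropometries: list[Anthropometry]
    imu: pd.DataFrame  # continuous aggregates: overall + region columns
    pose_results: list[RulaResult]

    def paired_scores(self) -> pd.DataFrame:
        """Long-format paired scores (overall + regions) for the agreement stats."""
        rows = []
        for i, pr in enumerate(self.pose_results):
            rows.append(("overall", i, self.imu.loc[i, "overall"], float(pr.grand)))
            for region in REGIONS:
                rows.append((region, i, self.imu.loc[i, region], float(getattr(pr, region))))
        return pd.DataFrame(rows, columns=["region", "participant", "imu_score", "pose_score"])[
            ["participant", "region", "imu_score", "pose_score"]
        ]


def _pose_observed_inputs(
    true: RulaInputs, cfg: CohortConfig, rng: np.random.Generator
) -> RulaInputs:
    """True angles perturbed by the pose branch's bias and angle noise."""
    changes = {}
    sd = cfg.pose_noise.angle_sd_deg
    for name in ANGLE_FIELDS:
        value = getattr(true, name) + cfg.region_bias.get(name, 0.0)
        if sd > 0:
            value += rng.normal(0.0, sd)
        changes[name] = float(value)
    return true.replace(**changes)


def simulate_cohort(
    cfg: CohortConfig,
    rng: np.random.Generator | None = None,
    pose_cfg: PoseConfig | None = None,
) -> CohortData:
    """Generate and score one complete cohort in memory."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    pose_cfg = pose_cfg or PoseConfig()
    true_inputs = sample_true_postures(cfg, rng)
    true_results = [score_posture(t) for t in true_inputs]
    anthros = [sample_anthropometry(rng) for _ in true_inputs]

    imu_rows = []
    pose_results = []
    for true, anthro in zip(true_inputs, anthros):
        imu_rows.append(_imu_aggregates(true, cfg, rng))
        observed = _pose_observed_inputs(true, cfg, rng)
        sag, fro, ann = render_pose_capture(
            observed,
            anthro,
            jitter_px=cfg.pose_noise.keypoint_jitter_px,
            rng=rng,
            facing=pose_cfg.facing,
            side=pose_cfg.side,
        )
        pose_results.append(score_pose_capture(sag, fro, ann, pose_cfg))
    imu = pd.DataFrame(imu_rows)
    return CohortData(cfg, true_inputs, true_results, anthros, imu, pose_results)


def generate_cohort(
    cfg: CohortConfig,
    out_dir,
    rng: np.random.Generator | None = None,
    pose_cfg: PoseConfig | None = None,
):
    """Write a complete self-describing cohort file tree.

    Per participant: two keypoint JSON files, an annotation JSON and an
    angle-stream CSV; plus one ``truth.csv`` with the true angles, flags and
    RULA scores.  Returns the output directory path.
    """
    from pathlib import Path

    from . import io as rio

    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    pose_cfg = pose_cfg or PoseConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    true_inputs = sample_true_postures(cfg, rng)
    truth_rows = []
    for i, true in enumerate(true_inputs):
        pid = f"p{i + 1:03d}"
        pdir = out / pid
        pdir.mkdir(exist_ok=True)
        anthro = sample_anthropometry(rng)
        stream = render_imu_stream(true, cfg, rng)
        rio.write_angle_stream(pdir / "imu_stream.csv", stream)
        observed = _pose_observed_inputs(true, cfg, rng)
        sag, fro, ann = render_pose_capture(
            observed,
            anthro,
            jitter_px=cfg.pose_noise.keypoint_jitter_px,
            rng=rng,
            facing=pose_cfg.facing,
            side=pose_cfg.side,
        )
        rio.write_keypoints(pdir / "pose_sagittal.json", sag)
        rio.write_keypoints(pdir / "pose_frontal.json", fro)
        rio.write_annotations(pdir / "annotations.json", ann)
        result = score_posture(true)
        row = {"participant": pid}
        row.update({name: getattr(true, name) for name in ANGLE_FIELDS})
        row.update(
            {name: getattr(true, name) for name in true.__dataclass_fields__ if name not in ANGLE_FIELDS}
        )
        row.update({f"true_{k}": v for k, v in result._asdict().items()})
        truth_rows.append(row)
    pd.DataFrame(truth_rows).to_csv(out / "truth.csv", index=False)
    return out


# --------------------------------------------------------------------------
# Kappa calibration.
# --------------------------------------------------------------------------


def cohort_overall_kappa(
    cfg: CohortConfig, rng: np.random.Generator, pose_cfg: PoseConfig | None = None
) -> float:
    """Weighted kappa between the two branches' overall scores for one cohort."""
    cohort = simulate_cohort(cfg, rng, pose_cfg)
    imu_lvl = round_to_levels(cohort.imu["overall"].to_numpy(), 7)
    pose_lvl = np.array([r.grand for r in cohort.pose_results])
    return weighted_kappa(imu_lvl, pose_lvl, 7).kappa


def mean_overall_kappa(
    cfg: CohortConfig, n_cohorts: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo mean kappa over replicate cohorts (degenerate ones skipped)."""
    kappas = []
    for _ in range(n_cohorts):
        try:
            kappas.append(cohort_overall_kappa(cfg, rng))
        except UndefinedKappaError:
            continue
    if not kappas:
        raise UndefinedKappaError("all replicate cohorts were degenerate")
    return float(np.mean(kappas))


def calibrate_pose_noise(
    target_kappa: float = 0.45,
    cfg: CohortConfig | None = None,
    n_cohorts: int = 40,
    grid: tuple[float, ...] = (0.5, 2.0, 4.0, 7.0, 11.0, 16.0, 24.0),
    seed: int = 0,
    refine: bool = True,
) -> float:
    """Pose angle-noise SD (degrees) whose expected overall kappa hits a target.

    Exploits the monotone decrease of expected kappa with the pose branch's
    angle-equivalent noise: evaluates mean kappa on a noise grid, inverts by
    interpolation, and optionally refines with a local linear fit.
    """
    cfg = cfg or CohortConfig()
    rng = np.random.default_rng(seed)
    kappas = np.array(
        [mean_overall_kappa(cfg.with_pose_angle_sd(sd), n_cohorts, rng) for sd in grid]
    )
    if not (kappas.min() <= target_kappa <= kappas.max()):
        raise ConfigError(
            f"target kappa {target_kappa} outside achievable range "
            f"[{kappas.min():.3f}, {kappas.max():.3f}] on the noise grid"
        )
    # kappa decreases with noise: invert on the reversed (increasing) axis.
    estimate = float(np.interp(target_kappa, kappas[::-1], np.asarray(grid)[::-1]))
    if refine:
        lo, hi = max(estimate - 2.0, 0.1), estimate + 2.0
        k_lo = mean_overall_kappa(cfg.with_pose_angle_sd(lo), n_cohorts, rng)
        k_hi = mean_overall_kappa(cfg.with_pose_angle_sd(hi), n_cohorts, rng)
        if abs(k_lo - k_hi) > 1e-9:
            frac = (target_kappa - k_lo) / (k_hi - k_lo)
            estimate = float(np.clip(lo + frac * (hi - lo), 0.1, max(grid)))
    return estimate
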
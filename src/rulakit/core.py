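"""Deterministic RULA scoring engine.

Rapid Upper Limb Assessment (RULA) turns a single working posture into a
musculoskeletal-risk grand score on a 1-7 scale.  Body-region sub-scores
(upper arm, lower arm, wrist, wrist twist, neck, trunk, legs) are read off
angle bands and posture flags, combined through the published lookup tables
A (arm/wrist) and B (neck/trunk/legs), augmented with muscle-use and
force/load increments into scores A and B, and finally mapped through the
grand-score table C.

The angle-band thresholds and the three tables follow the standard RULA
worksheet:

* upper arm: 1 within +/-20 deg of the trunk line, 2 for 20-45 deg flexion or
  any extension beyond 20 deg, 3 for 45-90 deg, 4 above 90 deg; +1 raised
  shoulder, +1 abducted arm, -1 when the arm is supported (floored at 1);
* lower arm: 1 within the 60-100 deg elbow-flexion band, 2 outside; +1 when
  the arm works across the midline or out to the side;
* wrist: 1 in neutral, 2 up to 15 deg of flexion/extension, 3 beyond; +1 when
  the wrist is bent from the midline; forearm rotation scores 1 (mid-range)
  or 2 (near end of range) on its own 2-point item;
* neck: 1 for 0-10 deg flexion, 2 for 10-20 deg, 3 beyond 20 deg, 4 for any
  extension; +1 twist, +1 side tilt;
* trunk: 1 when seated and well supported (upright within a small tolerance),
  2 up to 20 deg flexion, 3 up to 60 deg, 4 beyond; +1 twist, +1 side tilt;
* legs: 1 when legs and feet are supported and balanced, 2 otherwise.

Band boundaries belong to the lower-scoring band (``<=`` comparisons).

Both a scalar API (:func:`score_posture` and the per-region functions) and a
vectorised array path (:func:`score_posture_arrays`, used for frame-by-frame
scoring of motion-capture streams) are provided; the scalar functions are
thin wrappers over the array kernels so the two can never disagree.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import InputError

__all__ = [
    "RulaInputs",
    "RulaResult",
    "TABLE_A",
    "TABLE_B",
    "TABLE_C",
    "ANGLE_FIELDS",
    "FLAG_FIELDS",
    "score_upper_arm",
    "score_lower_arm",
    "score_wrist",
    "score_wrist_twist",
    "score_neck",
    "score_trunk",
    "score_legs",
    "lookup_posture_a",
    "lookup_posture_b",
    "grand_score",
    "score_posture",
    "score_posture_arrays",
]

# Default trunk tolerance: a seated trunk within +/-2 deg of upright counts as
# "well supported" (score 1).
TRUNK_UPRIGHT_TOL_DEG = 2.0
# Wrist deviations of exactly neutral score 1; any measurable deviation enters
# the 2-band.  The default tolerance is a pure numerical guard so angles
# reconstructed through floating-point geometry still count as neutral; a
# larger value can be supplied for pre-rounded instrument output.
WRIST_NEUTRAL_TOL_DEG = 1e-9


# --------------------------------------------------------------------------
# Lookup tables (standard RULA worksheet).
# TABLE_A[ua-1, la-1, wrist-1, twist-1]; TABLE_B[neck-1, trunk-1, legs-1];
# TABLE_C[min(score_a,8)-1, min(score_b,7)-1].
# --------------------------------------------------------------------------

TABLE_A = np.array(
    [
        [  # upper arm 1
            [[1, 2], [2, 2], [2, 3], [3, 3]],
            [[2, 2], [2, 2], [3, 3], [3, 3]],
            [[2, 3], [3, 3], [3, 3], [4, 4]],
        ],
        [  # upper arm 2
            [[2, 3], [3, 3], [3, 4], [4, 4]],
            [[3, 3], [3, 3], [3, 4], [4, 4]],
            [[3, 4], [4, 4], [4, 4], [5, 5]],
        ],
        [  # upper arm 3
            [[3, 3], [4, 4], [4, 4], [5, 5]],
            [[3, 4], [4, 4], [4, 4], [5, 5]],
            [[4, 4], [4, 4], [4, 5], [5, 5]],
        ],
        [  # upper arm 4
            [[4, 4], [4, 4], [4, 5], [5, 5]],
            [[4, 4], [4, 4], [4, 5], [5, 5]],
            [[4, 4], [4, 5], [5, 5], [6, 6]],
        ],
        [  # upper arm 5
            [[5, 5], [5, 5], [5, 6], [6, 7]],
            [[5, 6], [6, 6], [6, 7], [7, 7]],
            [[6, 6], [6, 7], [7, 7], [7, 8]],
        ],
        [  # upper arm 6
            [[7, 7], [7, 7], [7, 8], [8, 9]],
            [[8, 8], [8, 8], [8, 9], [9, 9]],
            [[9, 9], [9, 9], [9, 9], [9, 9]],
        ],
    ],
    dtype=np.int64,
)

TABLE_B = np.array(
    [
        [[1, 3], [2, 3], [3, 4], [5, 5], [6, 6], [7, 7]],  # neck 1
        [[2, 3], [2, 3], [4, 5], [5, 5], [6, 7], [7, 7]],  # neck 2
        [[3, 3], [3, 4], [4, 5], [5, 6], [6, 7], [7, 7]],  # neck 3
        [[5, 5], [5, 6], [6, 7], [7, 7], [7, 7], [8, 8]],  # neck 4
        [[7, 7], [7, 7], [7, 8], [8, 8], [8, 8], [8, 8]],  # neck 5
        [[8, 8], [8, 8], [8, 8], [8, 9], [9, 9], [9, 9]],  # neck 6
    ],
    dtype=np.int64,
)

TABLE_C = np.array(
    [
        [1, 2, 3, 3, 4, 5, 5],  # score A 1
        [2, 2, 3, 4, 4, 5, 5],
        [3, 3, 3, 4, 4, 5, 6],
        [3, 3, 3, 4, 5, 6, 6],
        [4, 4, 4, 5, 6, 7, 7],
        [4, 4, 5, 6, 6, 7, 7],
        [5, 5, 6, 6, 7, 7, 7],
        [5, 5, 6, 7, 7, 7, 7],  # score A 8+
    ],
    dtype=np.int64,
)


ANGLE_FIELDS = (
    "upper_arm_flexion",
    "lower_arm_flexion",
    "wrist_deviation",
    "neck_flexion",
    "trunk_flexion",
)

FLAG_FIELDS = (
    "shoulder_raised",
    "upper_arm_abducted",
    "arm_supported",
    "arm_across_midline_or_out",
    "wrist_bent_from_midline",
    "wrist_twist_near_end_range",
    "neck_twist",
    "neck_side_tilt",
    "trunk_twist",
    "trunk_side_tilt",
    "legs_supported",
)

MODIFIER_FIELDS = (
    "muscle_use_arm",
    "force_load_arm",
    "muscle_use_trunk",
    "force_load_trunk",
)


@dataclass(frozen=True)
class RulaInputs:
    """One posture's joint angles, posture flags and score increments.

    Angles are in degrees.  Flexion toward the front of the body is positive;
    extension is negative for the upper arm and neck.  The muscle-use and
    force/load increments default to the fixed values used for static seated
    work without load handling (muscle +1 for each group, force 0).
    """

    upper_arm_flexion: float = 0.0
    shoulder_raised: bool = False
    upper_arm_abducted: bool = False
    arm_supported: bool = False
    lower_arm_flexion: float = 90.0
    arm_across_midline_or_out: bool = False
    wrist_deviation: float = 0.0
    wrist_bent_from_midline: bool = False
    wrist_twist_near_end_range: bool = False
    neck_flexion: float = 0.0
    neck_twist: bool = False
    neck_side_tilt: bool = False
    trunk_flexion: float = 0.0
    trunk_twist: bool = False
    trunk_side_tilt: bool = False
    legs_supported: bool = True
    muscle_use_arm: int = 1
    force_load_arm: int = 0
    muscle_use_trunk: int = 1
    force_load_trunk: int = 0

    @classmethod
    def neutral(cls) -> "RulaInputs":
        """Reference seated working posture: upright trunk and neck, arm
        hanging, elbow at 90 deg, neutral wrist, legs supported."""
        return cls()

    def validate(self) -> None:
        for name in ANGLE_FIELDS:
            value = getattr(self, name)
            if not math.isfinite(float(value)):
                raise InputError(f"{name} must be finite, got {value!r}")

    def replace(self, **changes) -> "RulaInputs":
        return dataclasses.replace(self, **changes)


class RulaResult(NamedTuple):
    """All sub-scores plus intermediate and grand RULA scores."""

    upper_arm: int
    lower_arm: int
    wrist: int
    wrist_twist: int
    neck: int
    trunk: int
    legs: int
    posture_a: int
    posture_b: int
    score_a: int
    score_b: int
    grand: int


# --------------------------------------------------------------------------
# Vectorised kernels.
# --------------------------------------------------------------------------


def _check_finite(values: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(values)):
        raise InputError(f"{name} must be finite")


def _upper_arm_vec(flexion, raised, abducted, supported):
    f = np.asarray(flexion, dtype=float)
    _check_finite(f, "upper arm flexion")
    base = np.select(
        [
            (f >= -20.0) & (f <= 20.0),
            ((f > 20.0) & (f <= 45.0)) | (f < -20.0),
            (f > 45.0) & (f <= 90.0),
        ],
        [1, 2, 3],
        default=4,
    )
    score = base + np.asarray(raised, int) + np.asarray(abducted, int)
    score = score - np.asarray(supported, int)
    return np.maximum(score, 1)


def _lower_arm_vec(flexion, across_or_out):
    f = np.asarray(flexion, dtype=float)
    _check_finite(f, "lower arm flexion")
    base = np.where((f >= 60.0) & (f <= 100.0), 1, 2)
    return base + np.asarray(across_or_out, int)


def _wrist_vec(deviation, bent, neutral_tol=WRIST_NEUTRAL_TOL_DEG):
    d = np.abs(np.asarray(deviation, dtype=float))
    _check_finite(d, "wrist deviation")
    base = np.select([d <= neutral_tol, d <= 15.0], [1, 2], default=3)
    return base + np.asarray(bent, int)


def _wrist_twist_vec(near_end_range):
    return np.where(np.asarray(near_end_range, bool), 2, 1)


def _neck_vec(flexion, twist, side_tilt):
    f = np.asarray(flexion, dtype=float)
    _check_finite(f, "neck flexion")
    base = np.select(
        [f < 0.0, f <= 10.0, f <= 20.0],
        [4, 1, 2],
        default=3,
    )
    return base + np.asarray(twist, int) + np.asarray(side_tilt, int)


def _trunk_vec(flexion, twist, side_tilt, upright_tol=TRUNK_UPRIGHT_TOL_DEG):
    # The seated trunk is banded on the magnitude of its deviation from
    # upright; a small recline is treated like the equivalent small flexion.
    a = np.abs(np.asarray(flexion, dtype=float))
    _check_finite(a, "trunk flexion")
    base = np.select([a <= upright_tol, a <= 20.0, a <= 60.0], [1, 2, 3], default=4)
    return base + np.asarray(twist, int) + np.asarray(side_tilt, int)


def _legs_vec(supported):
    return np.where(np.asarray(supported, bool), 1, 2)


def score_posture_arrays(
    upper_arm_flexion,
    shoulder_raised,
    upper_arm_abducted,
    arm_supported,
    lower_arm_flexion,
    arm_across_midline_or_out,
    wrist_deviation,
    wrist_bent_from_midline,
    wrist_twist_near_end_range,
    neck_flexion,
    neck_twist,
    neck_side_tilt,
    trunk_flexion,
    trunk_twist,
    trunk_side_tilt,
    legs_supported,
    muscle_use_arm=1,
    force_load_arm=0,
    muscle_use_trunk=1,
    force_load_trunk=0,
    *,
    trunk_upright_tol=TRUNK_UPRIGHT_TOL_DEG,
    wrist_neutral_tol=WRIST_NEUTRAL_TOL_DEG,
) -> dict[str, np.ndarray]:
    """Score many postures at once; every argument broadcasts elementwise.

    Returns a dict with one integer array per :class:`RulaResult` field.
    """
    ua = _upper_arm_vec(upper_arm_flexion, shoulder_raised, upper_arm_abducted, arm_supported)
    la = _lower_arm_vec(lower_arm_flexion, arm_across_midline_or_out)
    wr = _wrist_vec(wrist_deviation, wrist_bent_from_midline, wrist_neutral_tol)
    wt = _wrist_twist_vec(wrist_twist_near_end_range)
    nk = _neck_vec(neck_flexion, neck_twist, neck_side_tilt)
    tr = _trunk_vec(trunk_flexion, trunk_twist, trunk_side_tilt, trunk_upright_tol)
    lg = _legs_vec(legs_supported)
    ua, la, wr, wt, nk, tr, lg = np.broadcast_arrays(ua, la, wr, wt, nk, tr, lg)

    pa = TABLE_A[
        np.minimum(ua, 6) - 1,
        np.minimum(la, 3) - 1,
        np.minimum(wr, 4) - 1,
        np.minimum(wt, 2) - 1,
    ]
    pb = TABLE_B[
        np.minimum(nk, 6) - 1,
        np.minimum(tr, 6) - 1,
        np.minimum(lg, 2) - 1,
    ]
    sa = pa + np.asarray(muscle_use_arm, int) + np.asarray(force_load_arm, int)
    sb = pb + np.asarray(muscle_use_trunk, int) + np.asarray(force_load_trunk, int)
    sa, sb = np.broadcast_arrays(sa, sb)
    grand = TABLE_C[np.minimum(sa, 8) - 1, np.minimum(sb, 7) - 1]
    return {
        "upper_arm": ua,
        "lower_arm": la,
        "wrist": wr,
        "wrist_twist": wt,
        "neck": nk,
        "trunk": tr,
        "legs": lg,
        "posture_a": pa,
        "posture_b": pb,
        "score_a": sa,
        "score_b": sb,
        "grand": grand,
    }


# --------------------------------------------------------------------------
# Scalar API.
# --------------------------------------------------------------------------


def _scalar(fn, *args, **kwargs) -> int:
    return int(fn(*args, **kwargs))


def score_upper_arm(
    flexion: float, raised: bool = False, abducted: bool = False, supported: bool = False
) -> int:
    """Upper-arm sub-score (1-6) from shoulder flexion/extension in degrees."""
    return _scalar(_upper_arm_vec, flexion, raised, abducted, supported)


def score_lower_arm(flexion: float, across_or_out: bool = False) -> int:
    """Lower-arm sub-score (1-3) from elbow flexion in degrees."""
    return _scalar(_lower_arm_vec, flexion, across_or_out)


def score_wrist(
    deviation: float,
    bent_from_midline: bool = False,
    neutral_tol: float = WRIST_NEUTRAL_TOL_DEG,
) -> int:
    """Wrist sub-score (1-4) from flexion/extension deviation in degrees."""
    return _scalar(_wrist_vec, deviation, bent_from_midline, neutral_tol)


def score_wrist_twist(near_end_range: bool) -> int:
    """Forearm-rotation item: 1 mid-range, 2 near end of range."""
    return _scalar(_wrist_twist_vec, near_end_range)


def score_neck(flexion: float, twist: bool = False, side_tilt: bool = False) -> int:
    """Neck sub-score (1-6); negative flexion means extension (band 4)."""
    return _scalar(_neck_vec, flexion, twist, side_tilt)


def score_trunk(
    flexion: float,
    twist: bool = False,
    side_tilt: bool = False,
    upright_tol: float = TRUNK_UPRIGHT_TOL_DEG,
) -> int:
    """Trunk sub-score (1-6); seated upright within ``upright_tol`` scores 1."""
    return _scalar(_trunk_vec, flexion, twist, side_tilt, upright_tol)


def score_legs(supported: bool) -> int:
    """Legs item: 1 when legs and feet are supported, 2 otherwise."""
    return _scalar(_legs_vec, supported)


def _check_range(name: str, value: int, lo: int, hi: int) -> None:
    if not (isinstance(value, (int, np.integer)) and lo <= value <= hi):
        raise InputError(f"{name} must be an integer in [{lo}, {hi}], got {value!r}")


def lookup_posture_a(ua: int, la: int, wrist: int, twist: int) -> int:
    """Posture score from table A for the arm/wrist group."""
    _check_range("upper arm score", ua, 1, 6)
    _check_range("lower arm score", la, 1, 3)
    _check_range("wrist score", wrist, 1, 4)
    _check_range("wrist twist score", twist, 1, 2)
    return int(TABLE_A[ua - 1, la - 1, wrist - 1, twist - 1])


def lookup_posture_b(neck: int, trunk: int, legs: int) -> int:
    """Posture score from table B for the neck/trunk/legs group."""
    _check_range("neck score", neck, 1, 6)
    _check_range("trunk score", trunk, 1, 6)
    _check_range("legs score", legs, 1, 2)
    return int(TABLE_B[neck - 1, trunk - 1, legs - 1])


def grand_score(score_a: int, score_b: int) -> int:
    """Grand RULA score (1-7) from table C; inputs of 8+ use the 8+ row/column."""
    if score_a < 1 or score_b < 1:
        raise InputError("scores A and B must be >= 1")
    return int(TABLE_C[min(int(score_a), 8) - 1, min(int(score_b), 7) - 1])


def score_posture(
    inputs: RulaInputs,
    *,
    trunk_upright_tol: float = TRUNK_UPRIGHT_TOL_DEG,
    wrist_neutral_tol: float = WRIST_NEUTRAL_TOL_DEG,
) -> RulaResult:
    """Score one complete posture through the full RULA chain."""
    inputs.validate()
    cols = score_posture_arrays(
        inputs.upper_arm_flexion,
        inputs.shoulder_raised,
        inputs.upper_arm_abducted,
        inputs.arm_supported,
        inputs.lower_arm_flexion,
        inputs.arm_across_midline_or_out,
        inputs.wrist_deviation,
        inputs.wrist_bent_from_midline,
        inputs.wrist_twist_near_end_range,
        inputs.neck_flexion,
        inputs.neck_twist,
        inputs.neck_side_tilt,
        inputs.trunk_flexion,
        inputs.trunk_twist,
        inputs.trunk_side_tilt,
        inputs.legs_supported,
        inputs.muscle_use_arm,
        inputs.force_load_arm,
        inputs.muscle_use_trunk,
        inputs.force_load_trunk,
        trunk_upright_tol=trunk_upright_tol,
        wrist_neutral_tol=wrist_neutral_tol,
    )
    return RulaResult(**{k: int(v) for k, v in cols.items()})
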
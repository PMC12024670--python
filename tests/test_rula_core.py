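"""Engine tests against an independently transcribed RULA worksheet."""

import itertools

import numpy as np
import pytest

from rulakit.core import (
    RulaInputs,
    grand_score,
    lookup_posture_a,
    lookup_posture_b,
    score_legs,
    score_lower_arm,
    score_neck,
    score_posture,
    score_posture_arrays,
    score_trunk,
    score_upper_arm,
    score_wrist,
    score_wrist_twist,
)
from rulakit.errors import InputError

from .conftest import random_inputs

# ---------------------------------------------------------------------------
# Independent second transcription of the RULA worksheet tables, written as
# flat dictionaries keyed by the sub-score tuples (not by array index), so a
# transcription slip in one copy cannot silently match the other.
# ---------------------------------------------------------------------------

ORACLE_A = {}
_ROWS_A = {
    # (ua, la): [wrist1(t1,t2), wrist2, wrist3, wrist4]
    (1, 1): [(1, 2), (2, 2), (2, 3), (3, 3)],
    (1, 2): [(2, 2), (2, 2), (3, 3), (3, 3)],
    (1, 3): [(2, 3), (3, 3), (3, 3), (4, 4)],
    (2, 1): [(2, 3), (3, 3), (3, 4), (4, 4)],
    (2, 2): [(3, 3), (3, 3), (3, 4), (4, 4)],
    (2, 3): [(3, 4), (4, 4), (4, 4), (5, 5)],
    (3, 1): [(3, 3), (4, 4), (4, 4), (5, 5)],
    (3, 2): [(3, 4), (4, 4), (4, 4), (5, 5)],
    (3, 3): [(4, 4), (4, 4), (4, 5), (5, 5)],
    (4, 1): [(4, 4), (4, 4), (4, 5), (5, 5)],
    (4, 2): [(4, 4), (4, 4), (4, 5), (5, 5)],
    (4, 3): [(4, 4), (4, 5), (5, 5), (6, 6)],
    (5, 1): [(5, 5), (5, 5), (5, 6), (6, 7)],
    (5, 2): [(5, 6), (6, 6), (6, 7), (7, 7)],
    (5, 3): [(6, 6), (6, 7), (7, 7), (7, 8)],
    (6, 1): [(7, 7), (7, 7), (7, 8), (8, 9)],
    (6, 2): [(8, 8), (8, 8), (8, 9), (9, 9)],
    (6, 3): [(9, 9), (9, 9), (9, 9), (9, 9)],
}
for (ua, la), cells in _ROWS_A.items():
    for w, pair in enumerate(cells, start=1):
        for t, val in enumerate(pair, start=1):
            ORACLE_A[(ua, la, w, t)] = val

ORACLE_B = {}
_ROWS_B = {
    # neck: [trunk1(l1,l2), ..., trunk6]
    1: [(1, 3), (2, 3), (3, 4), (5, 5), (6, 6), (7, 7)],
    2: [(2, 3), (2, 3), (4, 5), (5, 5), (6, 7), (7, 7)],
    3: [(3, 3), (3, 4), (4, 5), (5, 6), (6, 7), (7, 7)],
    4: [(5, 5), (5, 6), (6, 7), (7, 7), (7, 7), (8, 8)],
    5: [(7, 7), (7, 7), (7, 8), (8, 8), (8, 8), (8, 8)],
    6: [(8, 8), (8, 8), (8, 8), (8, 9), (9, 9), (9, 9)],
}
for neck, cells in _ROWS_B.items():
    for trunk, pair in enumerate(cells, start=1):
        for legs, val in enumerate(pair, start=1):
            ORACLE_B[(neck, trunk, legs)] = val

ORACLE_C = {
    1: [1, 2, 3, 3, 4, 5, 5],
    2: [2, 2, 3, 4, 4, 5, 5],
    3: [3, 3, 3, 4, 4, 5, 6],
    4: [3, 3, 3, 4, 5, 6, 6],
    5: [4, 4, 4, 5, 6, 7, 7],
    6: [4, 4, 5, 6, 6, 7, 7],
    7: [5, 5, 6, 6, 7, 7, 7],
    8: [5, 5, 6, 7, 7, 7, 7],
}


def oracle_upper_arm(flexion, raised, abducted, supported):
    if -20.0 <= flexion <= 20.0:
        base = 1
    elif flexion < -20.0 or flexion <= 45.0:
        base = 2
    elif flexion <= 90.0:
        base = 3
    else:
        base = 4
    return max(1, base + raised + abducted - supported)


def oracle_lower_arm(flexion, across):
    return (1 if 60.0 <= flexion <= 100.0 else 2) + across


def oracle_wrist(deviation, bent):
    d = abs(deviation)
    base = 1 if d == 0.0 else (2 if d <= 15.0 else 3)
    return base + bent


def oracle_neck(flexion, twist, tilt):
    if flexion < 0.0:
        base = 4
    elif flexion <= 10.0:
        base = 1
    elif flexion <= 20.0:
        base = 2
    else:
        base = 3
    return base + twist + tilt


def oracle_trunk(flexion, twist, tilt):
    a = abs(flexion)
    base = 1 if a <= 2.0 else (2 if a <= 20.0 else (3 if a <= 60.0 else 4))
    return base + twist + tilt


def oracle_chain(inp: RulaInputs) -> int:
    ua = oracle_upper_arm(
        inp.upper_arm_flexion,
        inp.shoulder_raised,
        inp.upper_arm_abducted,
        inp.arm_supported,
    )
    la = oracle_lower_arm(inp.lower_arm_flexion, inp.arm_across_midline_or_out)
    wr = oracle_wrist(inp.wrist_deviation, inp.wrist_bent_from_midline)
    wt = 2 if inp.wrist_twist_near_end_range else 1
    nk = oracle_neck(inp.neck_flexion, inp.neck_twist, inp.neck_side_tilt)
    tr = oracle_trunk(inp.trunk_flexion, inp.trunk_twist, inp.trunk_side_tilt)
    lg = 1 if inp.legs_supported else 2
    pa = ORACLE_A[(min(ua, 6), min(la, 3), min(wr, 4), wt)]
    pb = ORACLE_B[(min(nk, 6), min(tr, 6), lg)]
    sa = pa + inp.muscle_use_arm + inp.force_load_arm
    sb = pb + inp.muscle_use_trunk + inp.force_load_trunk
    return ORACLE_C[min(sa, 8)][min(sb, 7) - 1]


# ---------------------------------------------------------------------------
# Lookup tables: exhaustive cell-for-cell agreement with the second copy.
# ---------------------------------------------------------------------------


def test_table_a_matches_oracle_exhaustively():
    for (ua, la, w, t), expected in ORACLE_A.items():
        assert lookup_posture_a(ua, la, w, t) == expected


def test_table_b_matches_oracle_exhaustively():
    for (neck, trunk, legs), expected in ORACLE_B.items():
        assert lookup_posture_b(neck, trunk, legs) == expected


def test_table_c_matches_oracle_exhaustively():
    for a in range(1, 13):
        for b in range(1, 13):
            assert grand_score(a, b) == ORACLE_C[min(a, 8)][min(b, 7) - 1]


def test_lookup_range_errors():
    with pytest.raises(InputError):
        lookup_posture_a(0, 1, 1, 1)
    with pytest.raises(InputError):
        lookup_posture_a(7, 1, 1, 1)
    with pytest.raises(InputError):
        lookup_posture_b(1, 7, 1)
    with pytest.raises(InputError):
        lookup_posture_b(1, 1, 3)
    with pytest.raises(InputError):
        grand_score(0, 1)


# ---------------------------------------------------------------------------
# Sub-score bands (boundaries belong to the lower band).
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "flexion,expected",
    [
        (-25.0, 2),
        (-20.0, 1),
        (0.0, 1),
        (10.0, 1),
        (20.0, 1),
        (20.0001, 2),
        (45.0, 2),
        (45.0001, 3),
        (70.0, 3),
        (90.0, 3),
        (90.0001, 4),
        (140.0, 4),
    ],
)
def test_upper_arm_bands(flexion, expected):
    assert score_upper_arm(flexion) == expected


def test_upper_arm_modifiers_and_floor():
    assert score_upper_arm(10.0) == 1
    assert score_upper_arm(70.0, raised=True) == 4
    assert score_upper_arm(10.0, supported=True) == 1  # floored at 1
    assert score_upper_arm(30.0, supported=True) == 1
    assert score_upper_arm(70.0, raised=True, abducted=True, supported=True) == 4


@pytest.mark.parametrize(
    "flexion,expected",
    [(0.0, 2), (30.0, 2), (59.9, 2), (60.0, 1), (80.0, 1), (100.0, 1), (100.1, 2), (160.0, 2)],
)
def test_lower_arm_bands(flexion, expected):
    assert score_lower_arm(flexion) == expected


def test_lower_arm_flag():
    assert score_lower_arm(80.0, across_or_out=True) == 2
    assert score_lower_arm(30.0, across_or_out=True) == 3


@pytest.mark.parametrize(
    "deviation,expected",
    [(0.0, 1), (0.1, 2), (-10.0, 2), (10.0, 2), (15.0, 2), (15.1, 3), (-20.0, 3), (40.0, 3)],
)
def test_wrist_bands(deviation, expected):
    assert score_wrist(deviation) == expected


def test_wrist_flag_and_twist():
    assert score_wrist(20.0, bent_from_midline=True) == 4
    assert score_wrist_twist(False) == 1
    assert score_wrist_twist(True) == 2
    assert score_wrist_twist(True) == 2  # idempotent


@pytest.mark.parametrize(
    "flexion,expected",
    [(5.0, 1), (0.0, 1), (10.0, 1), (10.1, 2), (20.0, 2), (20.1, 3), (25.0, 3), (-0.1, 4), (-5.0, 4)],
)
def test_neck_bands(flexion, expected):
    assert score_neck(flexion) == expected


def test_neck_flags():
    assert score_neck(25.0, twist=True, side_tilt=True) == 5
    assert score_neck(-5.0, twist=True) == 5


@pytest.mark.parametrize(
    "flexion,expected",
    [(0.0, 1), (2.0, 1), (-2.0, 1), (2.1, 2), (10.0, 2), (20.0, 2), (20.1, 3), (30.0, 3), (60.0, 3), (60.1, 4), (-30.0, 3)],
)
def test_trunk_bands(flexion, expected):
    assert score_trunk(flexion) == expected


def test_trunk_flags_and_legs():
    assert score_trunk(30.0, twist=True) == 4
    assert score_legs(True) == 1
    assert score_legs(False) == 2


# ---------------------------------------------------------------------------
# Full chain.
# ---------------------------------------------------------------------------


def test_neutral_posture_scores_grand_2():
    result = score_posture(RulaInputs.neutral())
    assert result.posture_a == 1
    assert result.score_a == 2
    assert result.posture_b == 1
    assert result.score_b == 2
    assert result.grand == 2


def test_all_minimum_chain_without_modifiers():
    inp = RulaInputs.neutral().replace(muscle_use_arm=0, muscle_use_trunk=0)
    assert score_posture(inp).grand == 1


def test_high_risk_chain_scores_grand_7():
    inp = RulaInputs(
        upper_arm_flexion=70.0,
        shoulder_raised=True,
        lower_arm_flexion=30.0,
        wrist_deviation=20.0,
        wrist_bent_from_midline=True,
        wrist_twist_near_end_range=True,
        neck_flexion=25.0,
        neck_twist=True,
        trunk_flexion=30.0,
        trunk_twist=True,
        legs_supported=True,
    )
    assert score_posture(inp).grand == 7


def test_exhaustive_grid_matches_oracle_chain(rng):
    # Representative angle values in every band, all flag combinations for a
    # sampled subset, plus a dense random sweep.
    ua_angles = [-30.0, -20.0, 0.0, 20.0, 33.0, 45.0, 70.0, 90.0, 120.0]
    la_angles = [20.0, 60.0, 80.0, 100.0, 150.0]
    wr_angles = [0.0, 8.0, 15.0, 30.0]
    nk_angles = [-10.0, 0.0, 10.0, 15.0, 20.0, 40.0]
    tr_angles = [0.0, 2.0, 10.0, 20.0, 40.0, 60.0, 80.0]
    for ua, la, wr, nk, tr in itertools.product(
        ua_angles, la_angles, wr_angles, nk_angles, tr_angles
    ):
        inp = RulaInputs(
            upper_arm_flexion=ua,
            lower_arm_flexion=la,
            wrist_deviation=wr,
            neck_flexion=nk,
            trunk_flexion=tr,
        )
        assert score_posture(inp).grand == oracle_chain(inp)
    for inp in random_inputs(rng, 500):
        assert score_posture(inp).grand == oracle_chain(inp)


def test_monotonicity_flags_never_decrease_scores(rng):
    flag_names = (
        "shoulder_raised",
        "upper_arm_abducted",
        "arm_across_midline_or_out",
        "wrist_bent_from_midline",
        "wrist_twist_near_end_range",
        "neck_twist",
        "neck_side_tilt",
        "trunk_twist",
        "trunk_side_tilt",
    )
    for inp in random_inputs(rng, 200):
        base = score_posture(inp)
        for name in flag_names:
            if getattr(inp, name):
                continue
            bumped = score_posture(inp.replace(**{name: True}))
            assert bumped.grand >= base.grand
            assert bumped.score_a >= base.score_a
            assert bumped.score_b >= base.score_b
        if inp.legs_supported:
            assert score_posture(inp.replace(legs_supported=False)).grand >= base.grand


def test_tables_monotone_in_each_sub_score():
    for (ua, la, w, t), val in ORACLE_A.items():
        if ua < 6:
            assert ORACLE_A[(ua + 1, la, w, t)] >= val
        if la < 3:
            assert ORACLE_A[(ua, la + 1, w, t)] >= val
        if w < 4:
            assert ORACLE_A[(ua, la, w + 1, t)] >= val
        if t < 2:
            assert ORACLE_A[(ua, la, w, t + 1)] >= val
    for (nk, tr, lg), val in ORACLE_B.items():
        if nk < 6:
            assert ORACLE_B[(nk + 1, tr, lg)] >= val
        if tr < 6:
            assert ORACLE_B[(nk, tr + 1, lg)] >= val
        if lg < 2:
            assert ORACLE_B[(nk, tr, lg + 1)] >= val
    for a in range(1, 9):
        for b in range(1, 8):
            if a < 8:
                assert ORACLE_C[a + 1][b - 1] >= ORACLE_C[a][b - 1]
            if b < 7:
                assert ORACLE_C[a][b] >= ORACLE_C[a][b - 1]


def test_vectorized_path_equals_scalar(rng):
    postures = random_inputs(rng, 300)
    cols = {}
    fields = list(RulaInputs.__dataclass_fields__)
    for name in fields:
        cols[name] = np.array([getattr(p, name) for p in postures])
    arrays = score_posture_arrays(*(cols[name] for name in fields))
    for i, p in enumerate(postures):
        scalar = score_posture(p)
        for field_name in scalar._fields:
            assert arrays[field_name][i] == getattr(scalar, field_name)


def test_result_ranges(rng):
    for inp in random_inputs(rng, 300):
        r = score_posture(inp)
        assert 1 <= r.upper_arm <= 6
        assert 1 <= r.lower_arm <= 3
        assert 1 <= r.wrist <= 4
        assert r.wrist_twist in (1, 2)
        assert 1 <= r.neck <= 6
        assert 1 <= r.trunk <= 6
        assert r.legs in (1, 2)
        assert 1 <= r.grand <= 7


def test_non_finite_angles_rejected():
    with pytest.raises(InputError):
        score_posture(RulaInputs(upper_arm_flexion=float("nan")))
    with pytest.raises(InputError):
        score_posture(RulaInputs(trunk_flexion=float("inf")))
    with pytest.raises(InputError):
        score_upper_arm(float("nan"))


def test_determinism():
    inp = RulaInputs(upper_arm_flexion=47.3, neck_flexion=12.1, trunk_flexion=19.9)
    assert score_posture(inp) == score_posture(inp)
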
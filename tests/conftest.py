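"""Shared fixtures and helpers for the rulakit test suite."""

import numpy as np
import pytest

from rulakit.core import RulaInputs


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_inputs(rng, n):
    """Draw ``n`` random but valid postures spanning all score bands."""
    out = []
    for _ in range(n):
        out.append(
            RulaInputs(
                upper_arm_flexion=float(rng.uniform(-60, 150)),
                shoulder_raised=bool(rng.random() < 0.3),
                upper_arm_abducted=bool(rng.random() < 0.3),
                arm_supported=bool(rng.random() < 0.2),
                lower_arm_flexion=float(rng.uniform(0, 170)),
                arm_across_midline_or_out=bool(rng.random() < 0.3),
                wrist_deviation=float(rng.uniform(-45, 45)),
                wrist_bent_from_midline=bool(rng.random() < 0.3),
                wrist_twist_near_end_range=bool(rng.random() < 0.5),
                neck_flexion=float(rng.uniform(-30, 70)),
                neck_twist=bool(rng.random() < 0.3),
                neck_side_tilt=bool(rng.random() < 0.3),
                trunk_flexion=float(rng.uniform(-20, 80)),
                trunk_twist=bool(rng.random() < 0.3),
                trunk_side_tilt=bool(rng.random() < 0.3),
                legs_supported=bool(rng.random() < 0.8),
            )
        )
    return out
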
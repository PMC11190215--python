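import numpy as np
import pytest

from audiotype.core import AIR_FREQS, BONE_FREQS, Audiogram, AudiogramSet


def make_audiogram(air=10, bone=5, subject="t0", ear="left",
                   skip_air=(), skip_bone=(250,)):
    """Build an audiogram from scalars, dicts, or per-grid sequences.

    By default the optional 250 Hz bone point is omitted and all mandatory
    frequencies are present.
    """
    def expand(values, grid):
        if isinstance(values, dict):
            return dict(values)
        if np.isscalar(values):
            return {f: float(values) for f in grid}
        return {f: float(v) for f, v in zip(grid, values)}

    ac = {f: v for f, v in expand(air, AIR_FREQS).items() if f not in skip_air}
    bc = {f: v for f, v in expand(bone, BONE_FREQS).items() if f not in skip_bone}
    return Audiogram(subject_id=subject, ear=ear, ac=ac, bc=bc)


def six_record_qc_fixture():
    """Five records each violating exactly one screening rule, plus one clean.

    Keyed by the expected reason code string ('clean' for the valid record).
    """
    return {
        "clean": make_audiogram(air=10, bone=5, subject="ok"),
        "missing_frequency": make_audiogram(skip_air=(4000,), subject="m"),
        "air_out_of_range": make_audiogram(
            air=(-15, 0, 0, 0, 0, 0, 0), bone=-5, subject="r"),
        "air_step_violation": make_audiogram(
            air=(10, 10, 10, 45, 45, 45, 45),
            bone={500: 10, 1000: 40, 2000: 40, 4000: 40}, subject="s"),
        "bone_out_of_range": make_audiogram(
            air=60, bone={500: 55, 1000: 55, 2000: 65, 4000: 55}, subject="b"),
        "air_bone_relation": make_audiogram(
            air=20, bone={500: 35, 1000: 20, 2000: 20, 4000: 20}, subject="g"),
    }


@pytest.fixture
def complete_audiogram():
    return make_audiogram(air=10, bone=5)


@pytest.fixture
def small_set():
    records = [
        make_audiogram(air=10, bone=5, subject="a", ear="left"),
        make_audiogram(air=40, bone=5, subject="a", ear="right", skip_bone=()),
        make_audiogram(air=55, bone=50, subject="b", ear="left", skip_air=(125,)),
    ]
    return AudiogramSet(records)
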
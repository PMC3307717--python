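import numpy as np
import pytest

from hairpinhmm import simulator as sim
from hairpinhmm.patterns_io import CpGLocus, DoubleStrandPattern


@pytest.fixture
def toy_locus() -> CpGLocus:
    """Three CpGs at 1-, 6- and 13-bp offsets within a short region."""
    return CpGLocus("toy", "chrT", (101, 107, 114), 95, 120)


@pytest.fixture
def fmr1_locus() -> CpGLocus:
    return sim.fmr1_like_locus()


@pytest.fixture
def fmr1_params():
    return sim.fmr1_regime_params()


def make_pattern(a: str, b: str, pid: str = "p", mult: int = 1) -> DoubleStrandPattern:
    conv = {"0": 0, "1": 1, "?": -1}
    return DoubleStrandPattern(
        pid,
        np.array([conv[c] for c in a], dtype=np.int8),
        np.array([conv[c] for c in b], dtype=np.int8),
        mult,
    )


@pytest.fixture
def pattern_factory():
    return make_pattern
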
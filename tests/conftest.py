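"""Shared fixtures: curve libraries and synthetic systems built once."""

from __future__ import annotations

import pytest

from redorlab.powder import PowderScheme
from redorlab.spinsim import RedorSequenceParams, build_curve_library
from redorlab.synthetic import SyntheticConfig, gen_toy_complex


@pytest.fixture(scope="session")
def ideal_seq() -> RedorSequenceParams:
    """Ideal-pulse, zero-CSA sequence with a light powder set."""
    return RedorSequenceParams(
        powder=PowderScheme("spiral", 128, 8), csa_span_ppm=0.0
    )


@pytest.fixture(scope="session")
def ideal_library(ideal_seq):
    """Full 3.0-15.0 A distance->curve library on the ideal sequence."""
    return build_curve_library(ideal_seq)


@pytest.fixture(scope="session")
def toy_complex():
    return gen_toy_complex(SyntheticConfig(seed=11))
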
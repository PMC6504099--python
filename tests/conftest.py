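"""Shared fixtures: synthetic structures with known symmetry ground truth.

Generation is cheap but the heavier fixtures are session-scoped so the
pipeline fixtures are built once per run.
"""

import numpy as np
import pytest

from intsymm.structure_io import extract_ca_trace
from intsymm.synthetic import GeneratorSpec, make_decoy, make_symmetric


def build(arrangement="cyclic", n=3, motif="mixed", motif_len=24, seed=1, **kw):
    st, truth = make_symmetric(
        GeneratorSpec(
            motif=motif, motif_len=motif_len, n_repeats=n,
            arrangement=arrangement, seed=seed, **kw,
        )
    )
    return st, truth, extract_ca_trace(st)


@pytest.fixture(scope="session")
def c2_fixture():
    return build(n=2)


@pytest.fixture(scope="session")
def c3_fixture():
    return build(n=3)


@pytest.fixture(scope="session")
def c4_fixture():
    return build(n=4)


@pytest.fixture(scope="session")
def c6_fixture():
    return build(n=6)


@pytest.fixture(scope="session")
def c8_fixture():
    return build(n=8)


@pytest.fixture(scope="session")
def helical_fixture():
    return build(arrangement="helical", n=5, motif_len=20, theta=120.0, rise=5.0, seed=2)


@pytest.fixture(scope="session")
def translational_fixture():
    return build(arrangement="translational", n=4, motif="helix", motif_len=22,
                 shift=12.0, seed=3)


@pytest.fixture(scope="session")
def d2_fixture():
    return build(arrangement="dihedral", n=2, seed=4)


@pytest.fixture(scope="session")
def decoy_trace():
    return extract_ca_trace(make_decoy(150, seed=7))


def true_period(truth) -> int:
    """Chain period implied by the ground-truth repeat ranges."""
    (s0, _), (s1, _) = truth.repeat_ranges[0], truth.repeat_ranges[1]
    return s1 - s0


def truth_mapping(truth, n: int) -> dict:
    """Position map implied by the generator truth: each position of repeat r
    maps to the equivalent position of repeat r+1 (wrapping to repeat 0 for
    closed labels).  Linker positions without a symmetric image are omitted."""
    period = true_period(truth)
    k = len(truth.repeat_ranges)
    closed = truth.label.startswith(("C", "D"))
    out = {}
    for i in range(n):
        j = i + period
        if j < n:
            out[i] = j
        elif closed and i >= (k - 1) * period:
            out[i] = i - (k - 1) * period
    return out
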
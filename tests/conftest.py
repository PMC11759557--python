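"""Shared phantom fixtures.

Session-scoped so the noiseless reference phantom and its pipeline run
are built once; tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

from cdtikit.pipeline import run_pipeline
from cdtikit.synthetic_phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def noiseless_phantom(default_spec):
    """(stack, table, truth) for the consensus-normal noiseless phantom."""
    return make_phantom(default_spec)


@pytest.fixture(scope="session")
def noiseless_result(noiseless_phantom):
    """Full pipeline output on the noiseless phantom (no registration)."""
    stack, table, truth = noiseless_phantom
    return run_pipeline(stack, table, truth.contours, mask=truth.mask, register=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
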
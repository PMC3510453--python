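"""Shared fixtures: one default synthetic bundle per session plus its
smoothed track and nucleosome calls, so the expensive generation runs once."""

import numpy as np
import pytest

from tetramap import calling, smoothing
from tetramap.core import CoverageTrack, Replicon
from tetramap.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def bundle():
    """Default study-condition simulation (200 kb, depth 30x, seed 1)."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def smoothed(bundle):
    return smoothing.convolve(bundle.mnase, smoothing.gaussian_kernel(27))


@pytest.fixture(scope="session")
def calls(smoothed):
    return calling.call_nucleosomes(smoothed)


@pytest.fixture
def circular_replicon():
    return Replicon("chr", 100, circular=True)


def random_track(n=1000, seed=0, circular=True, name="chr"):
    rng = np.random.default_rng(seed)
    rep = Replicon(name, n, circular=circular)
    return CoverageTrack(rep, rng.poisson(10, n).astype(float))
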
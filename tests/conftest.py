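import numpy as np
import pytest
from hypothesis import settings

from bulbflow import synthetic as syn
from bulbflow.core import FlowWaveform, FluidProperties

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture(scope="session")
def tube_mesh():
    """Default-resolution straight tube (R = 0.3 cm, L = 3 cm)."""
    return syn.make_tube_mesh(syn.TubeSpec(radius=0.3, length=3.0))


@pytest.fixture(scope="session")
def small_tube_mesh():
    """Coarse tube for fast I/O and plumbing tests."""
    return syn.make_tube_mesh(
        syn.TubeSpec(radius=0.25, length=2.0, n_axial=8, n_radial=4,
                     n_circumferential=8)
    )


@pytest.fixture(scope="session")
def waveform():
    return syn.make_carotid_waveform(period=0.9, mean_flow=6.0, peak_flow=18.0,
                                     n_samples=40)


def steady_waveform(q, period=0.9, n=8):
    """Constant-flow waveform (useful for Poiseuille oracles)."""
    return FlowWaveform(
        times=np.arange(n) * period / n, flows=np.full(n, float(q)), period=period
    )


@pytest.fixture(scope="session")
def steady_field(tube_mesh):
    """Steady Poiseuille field with Q = 6 mL/s on the default tube."""
    return syn.sample_parabolic_field(tube_mesh, steady_waveform(6.0), n_frames=20)
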
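import numpy as np
import pytest

from nanodome.synthetic import (
    SurfaceSpec,
    make_surface,
    make_topology,
    sample_bilayer_frame,
)


@pytest.fixture(scope="session")
def spec():
    """Generator parameters at the study conditions (50 nm patch etc.)."""
    return SurfaceSpec()


@pytest.fixture(scope="session")
def topology(spec):
    return make_topology(spec)


@pytest.fixture(scope="session")
def surface_and_truth(spec):
    return make_surface(spec)


@pytest.fixture(scope="session")
def dome_frames(spec, surface_and_truth):
    """A small ensemble of dome frames with undulations, shared per session."""
    surf, _ = surface_and_truth
    out = []
    for s in range(8):
        fr, labels = sample_bilayer_frame(surf, spec, seed=1000 + s)
        out.append((fr, labels))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
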
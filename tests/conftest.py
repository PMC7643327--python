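import numpy as np
import pytest

from pvq.pulsatility import DiameterTrace
from pvq.synthetic import CorticalSliceSpec, make_cortical_slice, random_slice_spec, make_slice_image


def make_trace(D, dt_ms=1.0, d=None, window_ms=None):
    """Assemble a DiameterTrace directly from arrays (test helper)."""
    D = np.asarray(D, dtype=float)
    return DiameterTrace(
        t_ms=np.arange(D.size) * dt_ms,
        D_um=D,
        valid=np.ones(D.size, dtype=bool),
        line_period_ms=dt_ms,
        d_um=None if d is None else np.asarray(d, dtype=float),
        window_ms=window_ms,
    )


def random_smooth_trace(rng, n=4000, dt_ms=1.0):
    """Random band-limited diameter trace around a positive baseline."""
    t = np.arange(n) * dt_ms / 1000.0
    baseline = rng.uniform(6.0, 15.0)
    D = np.full(n, baseline)
    for _ in range(rng.integers(1, 4)):
        f = rng.uniform(3.0, 12.0)
        D += rng.uniform(0.1, 1.0) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    D += rng.uniform(-0.5, 0.5) * t  # slow drift
    return make_trace(D, dt_ms)


@pytest.fixture(scope="session")
def noise_free_slice():
    """One noise-free synthetic slice image with its ground truth."""
    spec = random_slice_spec(
        n_arteries=10, n_tracer_positive=7, mx04_fraction=0.25,
        collagen_density_fraction=0.12, plaque_fraction=0.03, seed=11,
    )
    image, vessel_truth, slice_truth = make_slice_image(spec)
    return spec, image, vessel_truth, slice_truth


@pytest.fixture(scope="session")
def cortical_slice_pair():
    """A noise-free cortical slice with penetrating vessels, plus its truth."""
    spec = CorticalSliceSpec(n_penetrating_vessels=12, seed=4)
    cslice, truth = make_cortical_slice(spec)
    return spec, cslice, truth
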
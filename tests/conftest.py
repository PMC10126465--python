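import numpy as np
import pytest

import sporekit as sk


@pytest.fixture(scope="session")
def small_rendered_stack():
    """A noise-free 3-spore stack with its truth, shared across tests."""
    img = sk.ImagingParams(width=300, height=300, duration=40.0, noise_sd=0.0)
    truth = sk.generate_truth(
        sk.PopulationParams(n_spores=3, frac_germinating=1.0, seed=42), img
    )
    frames, roster = sk.render_stack(truth, img, seed=42)
    stack = sk.ImageStack(frames, img.frame_interval, img.bit_depth)
    return stack, truth, roster, img


def make_synthetic_trace(rng, T=None, noise_sd=0.02):
    """A random normalized-scale trace with known breakpoints.

    Returns (trace, (b1, b2, b3)); the trace is marked as a germination
    candidate with `normalized` set directly.
    """
    if T is None:
        T = int(rng.integers(12, 61))
    b1 = int(rng.integers(1, T - 6))
    b2 = int(rng.integers(b1 + 2, T - 3))
    b3 = int(rng.integers(b2 + 2, T))
    v1 = float(rng.uniform(0.85, 1.0))
    v2 = float(rng.uniform(0.2, 0.6)) * v1
    t = np.arange(T, dtype=float)
    y = np.interp(t, [0, b1, b2, b3], [1.0, v1, v2, 0.0])
    y = y + rng.normal(0.0, noise_sd, size=T)
    trace = sk.IntensityTrace(
        spore_id="synthetic",
        times=t * 0.25,
        raw=y.copy(),
        normalized=y,
        germination_candidate=True,
    )
    return trace, (b1, b2, b3)
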
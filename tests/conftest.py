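import numpy as np
import pytest

from carpo.phantom import PhantomSpec, generate_sequence


@pytest.fixture(scope="session")
def small_phantom():
    """Short healthy phantom at native resolution (12 frames, 168 px)."""
    spec = PhantomSpec(duration_s=3.0, frame_interval_ms=250.0, noise_sigma=0.05,
                       seed=42)
    seq, truth = generate_sequence(spec)
    return spec, seq, truth


@pytest.fixture(scope="session")
def measured_phantom():
    """Noise-free healthy phantom at measurement resolution (0.5 mm/px)."""
    spec = PhantomSpec(duration_s=3.0, frame_interval_ms=250.0, noise_sigma=0.0,
                       seed=7)
    seq, truth = generate_sequence(spec, supersample=2)
    return spec, seq, truth


@pytest.fixture(scope="session")
def slow_phantom():
    """Phantom with realistic inter-frame motion (~0.5 deg/frame at 100 ms)."""
    spec = PhantomSpec(duration_s=1.2, frame_interval_ms=100.0,
                       angle_min_deg=-2.0, angle_max_deg=2.0,
                       noise_sigma=0.05, seed=3)
    seq, truth = generate_sequence(spec)
    return spec, seq, truth


@pytest.fixture(scope="session")
def desk_phantom():
    """Small-field phantom suited to CPU training (96 px, 96 mm field).

    The 15 s duration reproduces the reference movement rate: one full
    radial-ulnar cycle in ~15 s, i.e. about 1 deg per 100 ms frame at the
    fastest point of the sweep.
    """
    spec = PhantomSpec(duration_s=15.0, frame_interval_ms=100.0, native_size_px=96,
                       pixel_spacing_mm=1.0, noise_sigma=0.05, seed=7)
    seq, truth = generate_sequence(spec)
    return spec, seq, truth
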
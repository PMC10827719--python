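import numpy as np
import pytest

from dlrflight.synthetic import SynthSpec, generate_motif


@pytest.fixture(scope="session")
def orbit_traj():
    """Banked orbit at 0.5 m radius, 45 deg bank toward the central light."""
    return generate_motif(SynthSpec(motif="orbit", duration=2.0, rate=100.0,
                                    orbit_radius=0.5, bank_deg=45.0,
                                    speed=2.0, heading_deg=0.0, seed=1))


@pytest.fixture(scope="session")
def cruise_traj():
    """Straight level cruise, 2 s at 2 m/s and 100 Hz."""
    return generate_motif(SynthSpec(motif="cruise", duration=2.0, rate=100.0,
                                    speed=2.0, heading_deg=30.0,
                                    start_offset=(1.0, -2.0, 0.0), seed=1))


@pytest.fixture(scope="session")
def stall_traj():
    return generate_motif(SynthSpec(motif="stall", duration=2.0, rate=100.0,
                                    heading_deg=10.0, seed=1))


@pytest.fixture(scope="session")
def invert_traj():
    return generate_motif(SynthSpec(motif="invert", duration=2.0, rate=100.0,
                                    seed=1))


def random_rotation(rng) -> np.ndarray:
    """Uniformly random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] *= -1
    return q
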
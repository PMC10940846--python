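import numpy as np
import pytest

from aortaflow import JetSpec, MaskSeries, VelocityCine, make_velocity_cine


@pytest.fixture(scope="session")
def centred_bundle():
    """Noiseless centred symmetric jet, no reversal."""
    return make_velocity_cine(JetSpec())


@pytest.fixture(scope="session")
def eccentric_bundle():
    """Noiseless jet displaced 15% of the diameter toward 3 o'clock with a
    10% reversal target — every index well-defined and above the RA gate."""
    return make_velocity_cine(
        JetSpec(displacement_fraction=0.15, displacement_direction=90.0, reversal_target=0.10)
    )


def random_field(rng: np.random.Generator, n: int = 16, n_frames: int = 6):
    """Small random velocity cine + disk-ish random mask for oracle tests."""
    velocity = rng.normal(0.0, 40.0, size=(n, n, n_frames))
    mask = rng.random((n, n, n_frames)) < 0.6
    # guarantee foreground everywhere
    mask[n // 2, n // 2, :] = True
    cine = VelocityCine(velocity, (1.2, 0.8), 35.0)
    return cine, MaskSeries(mask)
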
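import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from llrpdff.fat_model import EchoTrain, FatSpectrum
from llrpdff.presets import get_preset


@pytest.fixture(scope="session")
def nine_peak():
    return FatSpectrum.nine_peak_liver()


@pytest.fixture(scope="session")
def protocol1():
    """Low-field protocol-1 echo train (six echoes, 0.55 T)."""
    return get_preset("protocol1_055T").echo_train()


@pytest.fixture(scope="session")
def protocol2_15():
    return get_preset("protocol2_15T").echo_train()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def small_study():
    """A small shared simulation: phantom, coils, caipi mask, k-space.

    Session-scoped because simulation and reconstruction dominate test time.
    """
    from llrpdff.phantom import (
        echo_images,
        make_coils,
        make_mask,
        make_phantom,
        pdff_series_config,
        simulate_kspace,
    )

    spectrum = FatSpectrum.nine_peak_liver()
    echoes = get_preset("protocol1_055T").echo_train()
    shape = (4, 32, 32)
    config = pdff_series_config(shape=shape, pdff_values=[0, 25, 50, 75, 100])
    phantom = make_phantom(config)
    reference = echo_images(phantom, spectrum, echoes)
    coils = make_coils(shape, 8, seed=3)
    mask = make_mask(shape[:2], 4, "caipi")
    kspace = simulate_kspace(
        phantom, spectrum, echoes, coils, mask, noise_sd=0.03, seed=42
    )
    return dict(
        spectrum=spectrum,
        echoes=echoes,
        shape=shape,
        phantom=phantom,
        reference=reference,
        coils=coils,
        mask=mask,
        kspace=kspace,
    )
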
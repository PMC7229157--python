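import numpy as np
import pytest

from paquant import (
    DualWavelengthVolume,
    Ellipsoid,
    ExtinctionTable,
    ForwardModelConfig,
    PhantomSpec,
    build_phantom,
    forward_project,
)

# Pinned coefficients so tests are bit-stable regardless of updates to the
# packaged compilation (cm^-1 M^-1).
PINNED = dict(
    wavelengths=(750.0, 830.0),
    eps_hb_oxy=(518.0, 974.0),
    eps_hb_deoxy=(1405.24, 693.04),
    version="pinned-test-table",
)


@pytest.fixture(scope="session")
def ext() -> ExtinctionTable:
    return ExtinctionTable(**PINNED)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_volume(pa750, pa830, voxel_size=(0.2, 0.2, 0.2), normalized=True, energies=None):
    """Assemble a DualWavelengthVolume from two stacks."""
    pa750 = np.asarray(pa750, dtype=float)
    n = pa750.shape[0]
    if energies is None:
        energies = {750.0: np.ones(n), 830.0: np.ones(n)}
    return DualWavelengthVolume(
        stacks={750.0: pa750, 830.0: np.asarray(pa830, dtype=float)},
        frame_energies=energies,
        voxel_size=voxel_size,
        meta={"energy_normalized": normalized},
    )


def simple_tumour_spec(**overrides) -> PhantomSpec:
    """A 32^3 phantom with a centred axis-aligned ellipsoidal tumour."""
    defaults = dict(
        grid_shape=(32, 32, 32),
        voxel_size=(0.25, 0.25, 0.25),
        tumour_ellipsoid=Ellipsoid(
            center=[3.875, 3.875, 3.875],
            semi_axes=[2.2, 1.8, 1.5],
            orientation=np.eye(3),
        ),
        tumour_so2=0.70,
        tumour_thb=100e-6,
        background_thb=20e-6,
        background_so2=0.75,
        seed=11,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture
def noise_free_case(ext):
    """Phantom + its noise-free unit-fluence forward projection."""
    spec = simple_tumour_spec()
    phantom = build_phantom(spec)
    volume = forward_project(phantom, ext, ForwardModelConfig())
    return phantom, volume
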
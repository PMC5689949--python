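import numpy as np
import pytest

import voxdose as vd


@pytest.fixture(scope="session")
def physics():
    return vd.PhysicsTable()


@pytest.fixture(scope="session")
def kernel(physics):
    """Y-90 mean-energy dose-point kernel in unit-density water."""
    return vd.build_kernel(physics, energy_mev=0.937, n_histories=200_000, seed=42)


@pytest.fixture(scope="session")
def female_phantom():
    """The lowest-BMI female study phantom."""
    return vd.build_phantom(vd.preset("female", 18.6))


@pytest.fixture(scope="session")
def all_phantoms():
    """All thirteen study phantoms, keyed by (sex, bmi)."""
    return {(s.sex, s.bmi): vd.build_phantom(s) for s in vd.all_presets()}


@pytest.fixture(scope="session")
def water_cube():
    """A 7.5 cm water cube labeled as a single organ: large against the
    ~0.4 cm CSDA range of the Y-90 mean beta energy."""
    return vd.water_block_phantom((24, 24, 24), density=1.0)


@pytest.fixture(scope="session")
def cube_run(water_cube):
    """A 2e5-history electron-only transport on the water cube."""
    batch = vd.sample_emissions(water_cube, "liver", 200_000, seed=5)
    dosemap, ledger = vd.transport_mc(
        water_cube, batch, options=vd.TransportOptions(radiative="off")
    )
    return dosemap, ledger


def equilibrium_dose_cgy(energy_mev: float, histories_per_voxel: float,
                         voxel_side: float = 0.3125, density: float = 1.0) -> float:
    """Closed-form equilibrium dose for a uniform source filling a
    uniform medium: every voxel absorbs what its own decays emit."""
    vox_mass_kg = density * voxel_side**3 * 1e-3
    return energy_mev * histories_per_voxel * 1.602176634e-13 / vox_mass_kg * 100.0


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
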
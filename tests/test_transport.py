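"""CSDA Monte Carlo and dose-point-kernel engines."""

import numpy as np
import pytest

import voxdose as vd
from voxdose.source import EmissionBatch, isotropic_directions
from tests.conftest import equilibrium_dose_cgy

ELECTRON_ONLY = vd.TransportOptions(radiative="off")


def _point_batch(n, position, energy=0.937, seed=0):
    rng = np.random.default_rng(seed)
    return EmissionBatch(
        positions=np.tile(position, (n, 1)).astype(float),
        directions=isotropic_directions(n, rng),
        energies=np.full(n, energy),
        seed=seed,
    )


class TestEnergyLedger:
    def test_balances_on_phantom_run(self, female_phantom):
        batch = vd.sample_emissions(female_phantom, "liver", 2000, seed=8)
        _, ledger = vd.transport_mc(female_phantom, batch)
        assert ledger.imbalance() < 1e-6
        assert ledger.radiative_mev > 0  # bremsstrahlung tallied, not deposited

    def test_single_electron_deep_in_water_fully_absorbed(self, water_cube):
        """A 0.937 MeV electron started far from every boundary deposits
        100% of its energy on the lattice: zero escape, zero radiative."""
        center = np.array([[3.75, 3.75, 3.75]])
        dosemap, ledger = vd.transport_mc(
            water_cube, _point_batch(10, center[0]), options=ELECTRON_ONLY
        )
        assert ledger.escaped_mev == 0.0
        assert ledger.radiative_mev == 0.0
        assert ledger.deposited_mev == pytest.approx(ledger.emitted_mev, rel=1e-12)
        assert np.all(dosemap.dose_cgy >= 0)

    def test_emission_outside_lattice_rejected(self, water_cube):
        batch = _point_batch(20, np.array([50.0, 50.0, 50.0]))
        _, ledger = vd.transport_mc(water_cube, batch, options=ELECTRON_ONLY)
        assert ledger.n_rejected == 20
        assert ledger.emitted_mev == 0.0


class TestEquilibrium:
    def test_uniform_source_matches_closed_form(self):
        """Uniform activity filling a uniform medium: the central voxel
        dose equals E_mean x (histories per voxel) / voxel mass, within
        3 batch standard errors."""
        block = vd.water_block_phantom((20, 20, 20), density=1.0)
        n = 100_000
        batch = vd.sample_emissions(block, "liver", n, seed=12)
        dosemap, _ = vd.transport_mc(block, batch, options=ELECTRON_ONLY)
        expected = equilibrium_dose_cgy(0.937, n / 20**3)
        got = dosemap.dose_cgy[10, 10, 10]
        sigma = dosemap.relative_uncertainty[10, 10, 10] * got
        assert abs(got - expected) < 3 * sigma

    def test_locality_zero_dose_beyond_csda_range(self, physics):
        """With radiative losses off, voxels farther than the CSDA range
        + one voxel from the (single-voxel) source receive exactly zero."""
        block = vd.water_block_phantom((25, 25, 25), density=1.0)
        center = (12.5) * 0.3125
        dosemap, _ = vd.transport_mc(
            block, _point_batch(5000, np.array([center] * 3)), options=ELECTRON_ONLY
        )
        r_vox = vd.csda_range(0.937, physics=physics, include_radiative=False) / 0.3125
        ii = np.indices(block.grid.shape).reshape(3, -1).T + 0.5
        dist = np.linalg.norm(ii - 12.5, axis=1)
        far = dist > (r_vox + 1.0)
        assert np.all(dosemap.dose_cgy.ravel()[far] == 0.0)
        near = dist <= 0.5
        assert np.all(dosemap.dose_cgy.ravel()[near] > 0)

    def test_uncertainty_scales_as_inverse_sqrt_n(self):
        """Organ-mean relative uncertainty follows 1/sqrt(n) within a
        factor 1.3 across two decades of history counts."""
        block = vd.water_block_phantom((16, 16, 16), density=1.0)
        rel = {}
        for n in (10_000, 100_000, 1_000_000):
            batch = vd.sample_emissions(block, "liver", n, seed=21)
            dosemap, _ = vd.transport_mc(block, batch, options=ELECTRON_ONLY)
            s, sig = vd.s_value(dosemap, block, "liver")
            rel[n] = sig / s
        for n_lo, n_hi in ((10_000, 100_000), (100_000, 1_000_000)):
            ratio = rel[n_lo] / rel[n_hi]
            assert np.sqrt(n_hi / n_lo) / 1.3 < ratio < np.sqrt(n_hi / n_lo) * 1.3


class TestKernel:
    def test_kernel_energy_closure(self, kernel):
        """sum(dose x voxel mass) over the kernel = 0.937 MeV within 1%."""
        assert kernel.energy_integral_mev == pytest.approx(0.937, rel=0.01)

    def test_kernel_support_within_csda_range(self, kernel, physics):
        r_vox = vd.csda_range(0.937, physics=physics, include_radiative=False) / 0.3125
        h = kernel.dose_cgy.shape[0] // 2
        ii = np.indices(kernel.dose_cgy.shape).reshape(3, -1).T
        dist = np.linalg.norm(ii - h, axis=1)
        nz = kernel.dose_cgy.ravel() > 0
        assert dist[nz].max() <= r_vox + 1.0

    def test_kernel_cubic_symmetry(self, kernel):
        """The kernel respects the 48 cubic-lattice symmetries within MC
        noise: compare axis permutations and reflections voxelwise."""
        k = kernel.dose_cgy
        scale = k.max()
        for t in [(1, 0, 2), (2, 1, 0), (0, 2, 1)]:
            assert np.abs(k - np.transpose(k, t)).max() / scale < 0.02
        for ax in range(3):
            assert np.abs(k - np.flip(k, axis=ax)).max() / scale < 0.02

    def test_truncated_kernel_rejected(self, physics):
        """A kernel lattice smaller than the CSDA range is refused."""
        with pytest.raises(vd.ValidationError):
            vd.build_kernel(physics, energy_mev=0.937, voxel_side=0.1,
                            n_histories=2000, seed=1, half_size=2)


class TestKernelConvolution:
    def test_single_voxel_source_reproduces_kernel(self, kernel):
        from voxdose.phantom import LABELS

        block = vd.water_block_phantom((21, 21, 21), density=1.0)
        block.labels[:] = LABELS["body"]
        block.labels[10, 10, 10] = LABELS["liver"]
        dosemap = vd.kernel_convolve(block, "liver", kernel)
        h = kernel.dose_cgy.shape[0] // 2
        sub = dosemap.dose_cgy[10 - h: 10 + h + 1, 10 - h: 10 + h + 1, 10 - h: 10 + h + 1]
        np.testing.assert_allclose(sub, kernel.dose_cgy, atol=kernel.dose_cgy.max() * 1e-12)

    def test_uniform_source_equilibrium(self, kernel):
        block = vd.water_block_phantom((20, 20, 20), density=1.0)
        dosemap = vd.kernel_convolve(block, "liver", kernel)
        expected = equilibrium_dose_cgy(0.937, 1.0 / 20**3)
        assert dosemap.dose_cgy[10, 10, 10] == pytest.approx(expected, rel=0.01)

    def test_engines_agree_on_homogeneous_phantom(self, kernel, water_cube, cube_run):
        """MC and convolution organ-mean doses agree within 3 sigma."""
        dosemap_mc, _ = cube_run
        s_mc, sig_mc = vd.s_value(dosemap_mc, water_cube, "liver")
        dosemap_k = vd.kernel_convolve(water_cube, "liver", kernel)
        s_k, _ = vd.s_value(dosemap_k, water_cube, "liver")
        # include the kernel's own MC noise through its energy closure
        sigma = np.sqrt(sig_mc**2 + (0.005 * s_k) ** 2)
        assert abs(s_mc - s_k) < 3 * sigma

    def test_grid_mismatch_rejected(self, kernel):
        block = vd.water_block_phantom((8, 8, 8), voxel_side=0.2)
        with pytest.raises(vd.GridMismatchError):
            vd.kernel_convolve(block, "liver", kernel)


def test_transport_deterministic_given_batch(water_cube):
    batch = vd.sample_emissions(water_cube, "liver", 5000, seed=33)
    a, _ = vd.transport_mc(water_cube, batch, options=ELECTRON_ONLY)
    b, _ = vd.transport_mc(water_cube, batch, options=ELECTRON_ONLY)
    assert np.array_equal(a.dose_cgy, b.dose_cgy)


def test_uncertainty_bounded_and_missing_where_zero(water_cube, cube_run):
    dosemap, _ = cube_run
    rel = dosemap.relative_uncertainty
    dosed = dosemap.dose_cgy > 0
    assert np.all(rel[dosed] >= 0) and np.all(rel[dosed] <= 1)
    assert np.all(np.isnan(rel[~dosed]))
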
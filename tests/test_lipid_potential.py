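import numpy as np
import pytest

from memfield.constants import COULOMB_V_ANG
from memfield.ewald import periodic_gaussian_potential
from memfield.lipid_potential import (ChargeDensityGrid, ChargedBoxError,
                                      LipidPotentialProfile, PotentialProfile,
                                      fit_piecewise_potential,
                                      load_profile_library, plane_average,
                                      solve_poisson_periodic,
                                      synthetic_bilayer_density)


def gaussian_box(n=24, spacing=1.0, sigma=2.5, center=None, charge=1.0):
    center = center if center is not None else np.full(3, n * spacing / 2)
    ax = np.arange(n) * spacing
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    r2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
    rho = np.exp(-r2 / (2 * sigma ** 2))
    rho *= charge / (rho.sum() * spacing ** 3)
    rho -= rho.mean()      # uniform neutralizing background
    return ChargeDensityGrid(rho, (spacing,) * 3, np.zeros(3)), center


class TestPoissonSolver:
    def test_zero_density_gives_zero_potential(self):
        g = ChargeDensityGrid(np.zeros((8, 8, 8)), (1.0, 1.0, 1.0))
        pot = solve_poisson_periodic(g)
        assert np.allclose(pot.values, 0.0)

    def test_matches_ewald_oracle(self):
        g, center = gaussian_box(n=24)
        pot = solve_poisson_periodic(g)
        rng = np.random.default_rng(0)
        idx = rng.integers(0, 24, size=(30, 3))
        oracle = periodic_gaussian_potential(center, [1.0], 2.5, [24.0] * 3,
                                             idx.astype(float))
        got = pot.values[idx[:, 0], idx[:, 1], idx[:, 2]]
        assert np.max(np.abs(got - oracle)) / np.max(np.abs(oracle)) < 1e-5

    def test_parallel_plate_capacitor_profile(self):
        # plates at z=16 (+) and z=48 (-) in a 64-slab periodic box: the
        # periodic closed form is E = (sigma/eps0) * (1 - d/L) between plates
        nx, nz, h = 12, 64, 1.0
        sigma_s = 0.01
        vals = np.zeros((nx, nx, nz))
        vals[:, :, 16] = sigma_s / h
        vals[:, :, 48] = -sigma_s / h
        pot = solve_poisson_periodic(ChargeDensityGrid(vals, (h,) * 3))
        prof = plane_average(pot, "z")
        slope = (prof.psi[40] - prof.psi[24]) / (16 * h)
        expected = -4 * np.pi * COULOMB_V_ANG * sigma_s * (1 - 32 / 64)
        assert abs(slope - expected) < 1e-3 * abs(expected)
        # linearity between the plates (small discretization ripple allowed)
        seg = prof.psi[20:45]
        d = np.diff(seg)
        assert np.max(np.abs(d - d.mean())) < 0.01 * abs(d.mean())

    def test_laplacian_reproduces_source(self):
        g, _ = gaussian_box(n=24, sigma=3.0)
        psi = solve_poisson_periodic(g).values
        lap = sum((np.roll(psi, 1, axis=a) + np.roll(psi, -1, axis=a) - 2 * psi)
                  for a in range(3))      # periodic 2nd difference, h = 1
        expected = -4 * np.pi * COULOMB_V_ANG * g.values
        scale = np.abs(expected).max()
        assert np.max(np.abs(lap - expected)) < 0.05 * scale

    def test_charged_box_raises_unless_neutralized(self):
        vals = np.full((8, 8, 8), 1e-3)
        g = ChargeDensityGrid(vals, (1.0,) * 3)
        with pytest.raises(ChargedBoxError):
            solve_poisson_periodic(g)
        pot = solve_poisson_periodic(g, neutralize=True)
        assert np.allclose(pot.values, 0.0)

    def test_non_periodic_flag_rejected(self):
        g = ChargeDensityGrid(np.zeros((8, 8, 8)), (1.0,) * 3, periodic=False)
        with pytest.raises(ValueError):
            solve_poisson_periodic(g)

    def test_solution_is_mean_free(self):
        g, _ = gaussian_box()
        assert abs(solve_poisson_periodic(g).values.mean()) < 1e-12


class TestPlaneAverage:
    def test_constant_and_linear_profiles(self):
        c = ChargeDensityGrid(np.zeros((8, 8, 16)), (1.0,) * 3)
        pot = solve_poisson_periodic(c)
        pot.values[:] = 3.25
        assert np.allclose(plane_average(pot, "z").psi, 3.25)
        z = np.arange(16, dtype=float)
        pot.values = np.broadcast_to(z, (8, 8, 16)).copy()
        assert np.allclose(plane_average(pot, "z").psi, z)

    def test_matches_bruteforce_slab_means(self):
        rng = np.random.default_rng(3)
        vals = rng.standard_normal((9, 10, 11))
        pot = solve_poisson_periodic(
            ChargeDensityGrid(np.zeros((9, 10, 11)), (1.0,) * 3))
        pot.values = vals
        for axis, iax in (("x", 0), ("y", 1), ("z", 2)):
            prof = plane_average(pot, axis)
            brute = [vals.take(i, axis=iax).mean()
                     for i in range(vals.shape[iax])]
            assert np.allclose(prof.psi, brute)


def synthesize_profile(A, C4, zc, n=401):
    def sig(z):
        return A[0] + (A[0] - A[1]) / (1 + np.exp((z - A[2]) / A[3]))

    C5 = sig(zc) - np.polyval(np.append(C4, 0.0), zc)
    C = np.append(C4, C5)
    z = np.linspace(-40, 40, n)
    a = np.abs(z)
    return PotentialProfile(z, np.where(a >= zc, sig(a), np.polyval(C, a)))


class TestPiecewiseFit:
    def test_noise_free_recovery(self):
        prof = synthesize_profile([0.02, 0.55, 14.0, 1.8],
                                  [1e-6, -4e-5, 4e-4, 0.002], zc=11.0)
        lp = fit_piecewise_potential(prof, "X")
        assert lp.fit_rms < 1e-6

    def test_constant_zero_profile(self):
        z = np.linspace(-40, 40, 161)
        lp = fit_piecewise_potential(PotentialProfile(z, np.zeros_like(z)))
        assert lp.delta_psi == 0.0
        assert np.allclose(lp.evaluate(np.linspace(-40, 40, 50)), 0.0)

    def test_noisy_rms_bounded(self):
        prof = synthesize_profile([0.0, 0.5, 13.0, 2.0],
                                  [5e-7, -2e-5, 3e-4, 0.001], zc=10.0)
        sigma = 0.02
        rng = np.random.default_rng(11)
        for _ in range(3):
            noisy = PotentialProfile(prof.z,
                                     prof.psi + sigma * rng.standard_normal(len(prof.z)))
            lp = fit_piecewise_potential(noisy, "X")
            assert lp.fit_rms <= 1.5 * sigma


class TestProfileEvaluation:
    @pytest.fixture(scope="class")
    @staticmethod
    def library():
        return load_profile_library()

    def test_water_reference_is_zero(self, library):
        for lp in library.values():
            assert abs(lp.evaluate(40.0)) < 1e-3
            assert abs(lp.evaluate(-40.0)) < 1e-3
            assert lp.evaluate(55.0) == 0.0

    def test_symmetric_in_depth(self, library):
        z = np.linspace(0.1, 39.9, 57)
        for lp in library.values():
            assert np.allclose(lp.evaluate(z), lp.evaluate(-z))

    def test_branches_continuous_at_zc(self, library):
        for lp in library.values():
            lo = lp.evaluate(lp.zc - 1e-9)
            hi = lp.evaluate(lp.zc + 1e-9)
            assert abs(hi - lo) < 1e-3          # within 1 mV


class TestSyntheticBilayer:
    def test_neutral_and_symmetric(self):
        g = synthetic_bilayer_density("PC", 10.8, 0.0, 0)
        assert abs(g.net_charge()) < 1e-9
        prof = plane_average(solve_poisson_periodic(g), "z")
        z = np.linspace(1, 35, 35)
        up = np.interp(z, prof.z, prof.psi)
        dn = np.interp(-z, prof.z, prof.psi)
        assert np.allclose(up, dn, atol=1e-10)

    def _delta_psi(self, pattern, salt=0.0):
        g = synthetic_bilayer_density(pattern, 10.8, salt, 0)
        prof = plane_average(solve_poisson_periodic(g), "z")
        return (np.interp(0.0, prof.z, prof.psi)
                - np.interp(40.0, prof.z, prof.psi))

    def test_headgroup_ordering(self):
        pc, pe, pg = (self._delta_psi(p) for p in ("PC", "PE", "PG"))
        assert abs(pe) > abs(pc)       # denser PE head charge
        assert abs(pg) < abs(pc)       # counterion screening of PG

    def test_salt_screens_potential(self):
        assert abs(self._delta_psi("PC", salt=0.1)) < abs(self._delta_psi("PC"))

    def test_delta_psi_antisymmetric_under_charge_flip(self):
        g = synthetic_bilayer_density("PC", 10.8, 0.0, 0)
        flipped = ChargeDensityGrid(-g.values, g.spacing, g.origin)
        p1 = plane_average(solve_poisson_periodic(g), "z")
        p2 = plane_average(solve_poisson_periodic(flipped), "z")
        d1 = np.interp(0, p1.z, p1.psi) - np.interp(40, p1.z, p1.psi)
        d2 = np.interp(0, p2.z, p2.psi) - np.interp(40, p2.z, p2.psi)
        assert abs(d1 + d2) < 1e-12

    def test_seeded_noise_is_reproducible(self):
        a = synthetic_bilayer_density("PC", 10.8, 0.0, 5, noise=1e-5)
        b = synthetic_bilayer_density("PC", 10.8, 0.0, 5, noise=1e-5)
        assert np.array_equal(a.values, b.values)
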
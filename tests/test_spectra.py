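"""1D/2D spectra: stick intensities, sum rules, pathway cancellation,
polarization schemes, convolutions, ensemble statistics and peak finding."""

from collections import defaultdict

import numpy as np
import pytest

from amideir.fixtures import FixtureSpec, build_ideal_backbone, perturb_ensemble
from amideir.hamiltonian import build_two_exciton, diagonalize, two_quantum_dipoles
from amideir.spectra import (
    Spectrum1D,
    Spectrum2D,
    Stick1DList,
    convolve_gaussian,
    convolve_lorentzian_2d,
    default_grid_1d,
    enhanced_signal,
    ensemble_average,
    ensemble_spectrum_1d,
    find_peaks,
    orientational_factor,
    snapshot_spectrum_1d,
    spectrum_2d_sticks,
    stick_spectrum_1d,
)

from conftest import random_one_exciton


def sticks_2d(H, mu, delta, scheme="zzzz"):
    sys2 = build_two_exciton(np.asarray(H, float), anharmonicity=delta)
    T = two_quantum_dipoles(mu, sys2.pair_index)
    e1, v1 = diagonalize(np.asarray(H, float))
    e2, v2 = diagonalize(sys2.matrix)
    return spectrum_2d_sticks(e1, v1, e2, v2, mu, T, scheme)


def net_amplitude_by_position(sticks, decimals=6):
    acc = defaultdict(float)
    for o1, o3, w in zip(sticks.omega1, sticks.omega3, sticks.weight):
        acc[(round(float(o1), decimals), round(float(o3), decimals))] += float(w)
    return acc


class TestStick1D:
    def test_single_site(self):
        sticks = stick_spectrum_1d(np.array([1680.0]), np.eye(1),
                                   np.array([[1.0, 0, 0]]))
        assert sticks.positions[0] == 1680.0
        assert sticks.weights[0] == pytest.approx(1.0)

    def test_symmetric_dimer_intensity_partition(self):
        # parallel equal dipoles: the in-phase eigenstate takes everything
        H = np.array([[1680.0, 5.0], [5.0, 1680.0]])
        mu = np.array([[1.0, 0, 0], [1.0, 0, 0]])
        evals, evecs = diagonalize(H)
        sticks = stick_spectrum_1d(evals, evecs, mu)
        weights = dict(zip(sticks.positions.round(6), sticks.weights))
        assert weights[1675.0] == pytest.approx(0.0, abs=1e-12)
        assert weights[1685.0] == pytest.approx(2.0)

    def test_total_intensity_unitary_invariant(self, rng):
        for n in (2, 5, 9):
            H = random_one_exciton(rng, n)
            mu = rng.normal(size=(n, 3))
            evals, evecs = diagonalize(H)
            sticks = stick_spectrum_1d(evals, evecs, mu)
            assert sticks.total_weight == pytest.approx(
                float(np.sum(mu * mu)), rel=1e-12)


class TestConvolveGaussian:
    def test_peak_and_half_maximum(self):
        sticks = Stick1DList(np.array([1680.0]), np.array([1.0]), np.array([0]))
        grid = np.arange(1600.0, 1760.0, 0.1)
        spec = convolve_gaussian(sticks, fwhm=4.0, grid=grid)
        imax = np.argmax(spec.intensity)
        assert spec.grid[imax] == pytest.approx(1680.0, abs=0.05)
        half = spec.intensity[imax] / 2
        above = spec.grid[spec.intensity >= half]
        assert above.min() == pytest.approx(1678.0, abs=0.1)
        assert above.max() == pytest.approx(1682.0, abs=0.1)

    def test_two_resolved_maxima(self):
        sticks = Stick1DList(np.array([1660.0, 1700.0]), np.ones(2),
                             np.arange(2))
        spec = convolve_gaussian(sticks, fwhm=4.0)
        assert len(find_peaks(spec)) == 2

    def test_integral_conserved_under_refinement(self):
        sticks = Stick1DList(np.array([1650.0, 1700.0]),
                             np.array([2.0, 3.0]), np.arange(2))
        for step in (0.5, 0.1):
            grid = np.arange(1550.0, 1800.0, step)
            spec = convolve_gaussian(sticks, fwhm=4.0, grid=grid)
            assert np.trapezoid(spec.intensity, spec.grid) == pytest.approx(
                5.0, rel=1e-3)

    def test_narrow_grid_rejected(self):
        sticks = Stick1DList(np.array([1680.0]), np.array([1.0]), np.array([0]))
        with pytest.raises(ValueError, match="cover"):
            convolve_gaussian(sticks, fwhm=4.0, grid=np.arange(1670.0, 1690.0, 0.5))


class TestOrientationalFactors:
    def test_all_parallel_identities(self):
        z = np.array([0.0, 0.0, 1.0])
        assert orientational_factor(z, z, z, z, "zzzz") == pytest.approx(
            1.0 / 5.0, abs=1e-12)
        assert orientational_factor(z, z, z, z, "zxxz") == pytest.approx(
            1.0 / 15.0, abs=1e-12)
        assert orientational_factor(z, z, z, z, "enhanced") == pytest.approx(
            0.0, abs=1e-12)

    def test_perpendicular_pair(self):
        z = np.array([0.0, 0.0, 1.0])
        x = np.array([1.0, 0.0, 0.0])
        # α=β=z, γ=δ=x: only the first invariant survives
        assert orientational_factor(z, z, x, x, "zzzz") == pytest.approx(1 / 15)
        assert orientational_factor(z, z, x, x, "zxxz") == pytest.approx(-1 / 30)

    def test_nonunit_vectors_normalized_with_warning(self):
        z = np.array([0.0, 0.0, 2.0])
        with pytest.warns(UserWarning):
            val = orientational_factor(z, z, z, z, "zzzz")
        assert val == pytest.approx(1 / 5)


class TestSpectrum2DSticks:
    @pytest.mark.parametrize("n", [1, 2, 3, 5])
    def test_harmonic_cancellation(self, n, rng):
        H = random_one_exciton(rng, n)
        mu = rng.normal(size=(n, 3))
        sticks = sticks_2d(H, mu, delta=0.0)
        net = net_amplitude_by_position(sticks)
        bleach = sticks.weight[sticks.pathway == "GB"].max()
        assert max(abs(v) for v in net.values()) < 1e-8 * bleach

    def test_single_oscillator_anharmonic_positions(self):
        sticks = sticks_2d([[1680.0]], np.array([[1.0, 0, 0]]), delta=16.0)
        net = net_amplitude_by_position(sticks)
        nonzero = {k: v for k, v in net.items() if abs(v) > 1e-12}
        assert set(nonzero) == {(1680.0, 1680.0), (1680.0, 1664.0)}
        assert nonzero[(1680.0, 1680.0)] > 0
        assert nonzero[(1680.0, 1664.0)] < 0
        # ESA magnitude balances GB+SE in the isotropic all-parallel case
        assert nonzero[(1680.0, 1680.0)] == pytest.approx(
            -nonzero[(1680.0, 1664.0)], rel=1e-9)

    def test_uncoupled_sites_no_foreign_cross_peaks(self, rng):
        w = np.array([1650.0, 1700.0])
        mu = rng.normal(size=(2, 3))
        sticks = sticks_2d(np.diag(w), mu, delta=16.0)
        net = net_amplitude_by_position(sticks)
        for (o1, o3), v in net.items():
            if abs(v) < 1e-10:
                continue
            assert o1 in (1650.0, 1700.0)
            # ω3 only at a fundamental or its own anharmonically shifted ESA
            assert o3 in (1650.0, 1700.0, 1634.0, 1684.0)

    def test_dipole_scaling_fourth_power(self, rng):
        H = random_one_exciton(rng, 3)
        mu = rng.normal(size=(3, 3))
        s1 = sticks_2d(H, mu, delta=16.0)
        s2 = sticks_2d(H, 2.0 * mu, delta=16.0)
        assert np.allclose(s2.weight, 16.0 * s1.weight, rtol=1e-9)


class TestEnhancedSignal:
    def test_zero_zxxz_returns_zzzz(self):
        grid = np.arange(1600.0, 1700.0, 1.0)
        amp = np.random.default_rng(0).normal(size=(len(grid), len(grid)))
        s_zzzz = Spectrum2D(grid, grid, amp, scheme="zzzz")
        s_zxxz = Spectrum2D(grid, grid, np.zeros_like(amp), scheme="zxxz")
        out = enhanced_signal(s_zzzz, s_zxxz)
        assert np.allclose(out.amplitude, amp)
        assert out.scheme == "enhanced"

    def test_single_oscillator_enhanced_vanishes(self):
        sticks = sticks_2d([[1680.0]], np.array([[1.0, 0, 0]]),
                           delta=16.0, scheme="enhanced")
        assert np.max(np.abs(sticks.weight)) < 1e-15

    def test_dimer_perpendicular_dipoles_cross_peak_survives(self):
        # Under ⟨ZZZZ⟩ − 3⟨ZXXZ⟩ the net positive (GB + rephasing SE) weight
        # at each cross position cancels exactly, so the surviving cross-peak
        # signal is the anharmonically shifted ESA doublet: the diagonal must
        # be strongly attenuated relative to ZZZZ while the cross-peak region
        # keeps finite signal.
        H = np.array([[1660.0, 8.0], [8.0, 1700.0]])
        mu = np.array([[1.0, 0, 0], [0, 1.0, 0]])
        e1, _ = diagonalize(H)
        lo, hi = e1
        grid = np.arange(1600.0, 1761.0, 1.0)

        def region(spec, w1, w3, half=6.0):
            m1 = (spec.omega1_grid >= w1 - half) & (spec.omega1_grid <= w1 + half)
            m3 = (spec.omega3_grid >= w3 - half) & (spec.omega3_grid <= w3 + half)
            return np.abs(spec.amplitude[np.ix_(m1, m3)]).max()

        szz = convolve_lorentzian_2d(sticks_2d(H, mu, 16.0, "zzzz"),
                                     10.0, grid, grid)
        sen = convolve_lorentzian_2d(sticks_2d(H, mu, 16.0, "enhanced"),
                                     10.0, grid, grid)
        assert region(sen, lo, lo) < 0.2 * region(szz, lo, lo)  # diag suppressed
        assert region(sen, lo, hi) > 1e-4 * np.abs(szz.amplitude).max()
        # the net positive weight at the exact cross position cancels
        net = net_amplitude_by_position(sticks_2d(H, mu, 16.0, "enhanced"))
        assert abs(net[(round(lo, 6), round(hi, 6))]) < 1e-12

    def test_grid_mismatch_rejected(self):
        g1 = np.arange(1600.0, 1700.0, 1.0)
        g2 = np.arange(1600.0, 1700.0, 2.0)
        a = Spectrum2D(g1, g1, np.zeros((len(g1), len(g1))), scheme="zzzz")
        b = Spectrum2D(g2, g2, np.zeros((len(g2), len(g2))), scheme="zxxz")
        with pytest.raises(ValueError):
            enhanced_signal(a, b)


class TestLorentzian2D:
    def test_maximum_at_stick_position(self):
        sticks = sticks_2d([[1680.0]], np.array([[1.0, 0, 0]]), delta=30.0)
        spec = convolve_lorentzian_2d(sticks, width=10.0)
        i, j = np.unravel_index(np.argmax(spec.amplitude), spec.amplitude.shape)
        assert spec.omega1_grid[i] == pytest.approx(1680.0, abs=1.0)
        assert spec.omega3_grid[j] == pytest.approx(1680.0, abs=1.0)

    def test_signed_integral_proportional_to_weights(self):
        # numerical integration over a wide fine grid approximates Σ weights
        sticks = sticks_2d(np.diag([1660.0, 1690.0]),
                           np.array([[1.0, 0, 0], [0.5, 0.5, 0]]), delta=16.0)
        grid = np.arange(1200.0, 2150.0, 2.0)
        spec = convolve_lorentzian_2d(sticks, width=10.0, omega1_grid=grid,
                                      omega3_grid=grid)
        integral = np.trapezoid(np.trapezoid(spec.amplitude, grid, axis=1), grid)
        assert integral == pytest.approx(float(sticks.weight.sum()), abs=0.02)

    def test_kernel_even_in_both_axes(self):
        sticks = sticks_2d([[1650.0]], np.array([[1.0, 0, 0]]), delta=1e6)
        # keep only the positive stick at (1650, 1650) by using a huge Δ
        grid = np.arange(1600.0, 1701.0, 1.0)
        spec = convolve_lorentzian_2d(sticks, width=10.0, omega1_grid=grid,
                                      omega3_grid=grid)
        i = int(np.flatnonzero(grid == 1650.0)[0])
        for k in (5, 17):
            assert spec.amplitude[i + k, i] == pytest.approx(spec.amplitude[i - k, i])
            assert spec.amplitude[i, i + k] == pytest.approx(spec.amplitude[i, i - k])


class TestEnsembleAverage:
    def _spec(self, intensity):
        grid = np.arange(1600.0, 1700.0, 1.0)
        return Spectrum1D(grid, np.asarray(intensity, float))

    def test_identical_spectra(self):
        y = np.exp(-0.5 * ((np.arange(100) - 50) / 5.0) ** 2)
        specs = [self._spec(y) for _ in range(4)]
        mean, std, most, least = ensemble_average(specs)
        assert np.allclose(mean.intensity, y)
        assert np.allclose(std, 0.0)
        assert most == 0 and least == 0  # ties take the lowest index

    def test_two_spectra_equidistant(self):
        y = np.zeros(100)
        a, b = y.copy(), y.copy()
        a[30] = 1.0
        b[60] = 1.0
        mean, std, most, least = ensemble_average([self._spec(a), self._spec(b)])
        assert np.allclose(mean.intensity, (a + b) / 2)
        assert most == 0 and least == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ensemble_average([])


class TestFindPeaks:
    def test_single_gaussian(self):
        grid = np.arange(1600.0, 1760.0, 0.5)
        y = np.exp(-0.5 * ((grid - 1680.0) / 3.0) ** 2)
        peaks = find_peaks(Spectrum1D(grid, y))
        assert len(peaks) == 1
        assert peaks[0].position[0] == pytest.approx(1680.0, abs=0.5)

    def test_threshold_one_keeps_only_global_maximum(self):
        grid = np.arange(1600.0, 1760.0, 0.5)
        y = (np.exp(-0.5 * ((grid - 1660.0) / 3.0) ** 2)
             + 0.5 * np.exp(-0.5 * ((grid - 1700.0) / 3.0) ** 2))
        assert len(find_peaks(Spectrum1D(grid, y), threshold_fraction=1.0)) == 1

    def test_anharmonic_2d_map_peak_pair(self):
        sticks = sticks_2d([[1680.0]], np.array([[1.0, 0, 0]]), delta=16.0)
        spec = convolve_lorentzian_2d(sticks, width=10.0)
        peaks = find_peaks(spec)
        pos = find_peaks(spec)
        positive = [p for p in pos if p.amplitude > 0]
        negative = [p for p in pos if p.amplitude < 0]
        assert len(positive) == 1 and len(negative) == 1
        assert positive[0].position == (1680.0, 1680.0)
        assert positive[0].is_diagonal
        assert negative[0].position == (1680.0, 1664.0)
        assert not negative[0].is_diagonal

    def test_flat_spectrum_empty(self):
        grid = np.arange(1600.0, 1700.0, 1.0)
        assert find_peaks(Spectrum1D(grid, np.zeros_like(grid))) == []


class TestSpectralInvariants:
    def test_1d_intensity_scaling_squared(self, rng):
        H = random_one_exciton(rng, 4)
        mu = rng.normal(size=(4, 3))
        evals, evecs = diagonalize(H)
        w1 = stick_spectrum_1d(evals, evecs, mu).weights
        w2 = stick_spectrum_1d(evals, evecs, 3.0 * mu).weights
        assert np.allclose(w2, 9.0 * w1, rtol=1e-9)

    def test_zzzz_invariant_under_rigid_rotation(self, nnc_map, params):
        from scipy.spatial.transform import Rotation
        snap = build_ideal_backbone(FixtureSpec(kind="helix", n_residues=8))
        rot = Rotation.from_euler("zyx", [40.0, -25.0, 110.0], degrees=True)
        rotated = snap.with_coords(rot.apply(snap.coords))
        s_ref = snapshot_spectrum_1d(snap, params, nnc_map)
        s_rot = snapshot_spectrum_1d(rotated, params, nnc_map)
        assert np.allclose(s_ref.intensity, s_rot.intensity, atol=1e-9)

    def test_isotope_labeling_moves_band(self, nnc_map, params):
        snap = build_ideal_backbone(FixtureSpec(kind="helix", n_residues=10))
        plain = snapshot_spectrum_1d(snap, params, nnc_map)
        labeled = snapshot_spectrum_1d(snap, params, nnc_map,
                                       labeled_sites=range(0, 4))
        main = plain.grid[np.argmax(plain.intensity)]
        # the unlabeled band persists near its original position
        peaks = [p.position[0] for p in find_peaks(labeled, 0.10)]
        assert any(abs(p - main) < 10.0 for p in peaks)
        # new intensity appears ~65 cm⁻¹ below the main band
        lowband = (labeled.grid > main - 75.0) & (labeled.grid < main - 55.0)
        assert labeled.intensity[lowband].sum() > 5.0 * plain.intensity[lowband].sum()

    def test_ensemble_mean_broader_than_reference(self, nnc_map, params):
        snap = build_ideal_backbone(FixtureSpec(kind="helix", n_residues=12))
        ens = perturb_ensemble(snap, 0.02, 40, seed=1)
        mean, singles = ensemble_spectrum_1d(ens, params, nnc_map)

        def m2(spec):
            w = spec.intensity / spec.intensity.sum()
            c = np.sum(w * spec.grid)
            return np.sum(w * (spec.grid - c) ** 2)

        assert m2(mean) > m2(singles[0])  # singles[0] is the unperturbed model


class TestHDF5Export:
    def test_1d_round_trip(self, tmp_path):
        import h5py
        grid = np.arange(1600.0, 1700.0, 1.0)
        spec = Spectrum1D(grid, np.abs(np.sin(grid / 10.0)),
                          metadata={"omega0_cm-1": 1680.0})
        path = tmp_path / "spec.h5"
        spec.write_hdf5(path)
        with h5py.File(path) as f:
            assert np.allclose(f["grid_cm-1"][:], grid)
            assert np.allclose(f["intensity"][:], spec.intensity)
            assert f.attrs["omega0_cm-1"] == 1680.0

    def test_2d_round_trip(self, tmp_path):
        import h5py
        grid = np.arange(1600.0, 1650.0, 1.0)
        amp = np.random.default_rng(0).normal(size=(len(grid), len(grid)))
        spec = Spectrum2D(grid, grid, amp, scheme="zxxz")
        path = tmp_path / "spec2d.h5"
        spec.write_hdf5(path)
        with h5py.File(path) as f:
            assert np.allclose(f["amplitude"][:], amp)
            assert f.attrs["scheme"] == "zxxz"
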
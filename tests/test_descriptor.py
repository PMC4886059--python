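"""Fourier descriptor: DFT, invariance normalization, energy, truncation."""

import numpy as np
import pytest

from drfvt.descriptor import (DegenerateShapeError, SpectralCoefficients, dft,
                              energy, normalize, reconstruct, select_m,
                              truncate)

from conftest import random_blob_signal


def direct_dft(z):
    """O(N^2) evaluation of Z_m = sum_l z_l exp(-i 2 pi l m / N)."""
    z = np.asarray(z, dtype=complex)
    n = len(z)
    ls = np.arange(n)
    return SpectralCoefficients(
        Z=np.array([np.sum(z * np.exp(-2j * np.pi * ls * m / n))
                    for m in range(-n // 2, n // 2)]),
        N=n)


def direct_reconstruct(descriptor):
    """O(M^2) evaluation of the inverse transform."""
    m_idx = np.arange(-descriptor.M // 2, descriptor.M // 2)
    ls = np.arange(descriptor.M)
    return np.array([
        np.sum(descriptor.Zhat * np.exp(2j * np.pi * l * m_idx / descriptor.M))
        for l in ls]) / descriptor.M


def apply_transform(z, theta0=0.0, l0=0, scale=1.0, translation=0j):
    """Rotate, start-shift, scale and translate a closed outline signal."""
    return scale * np.exp(1j * theta0) * np.roll(z, l0) + translation


class TestDft:
    def test_ideal_circle_single_coefficient(self):
        n, r = 64, 5.0
        z = r * np.exp(2j * np.pi * np.arange(n) / n)
        co = dft(z)
        assert co.coeff(1) == pytest.approx(n * r, abs=1e-9)
        rest = co.Z.copy()
        rest[n // 2 + 1] = 0
        assert np.abs(rest).max() < 1e-9

    def test_constant_signal_dc_only(self):
        co = dft(np.full(16, 2.0 - 1.0j))
        assert co.coeff(0) == pytest.approx(16 * (2 - 1j), abs=1e-12)
        rest = co.Z.copy()
        rest[8] = 0
        assert np.abs(rest).max() < 1e-9

    def test_four_point_circle_by_hand(self):
        co = dft([1, 1j, -1, -1j])
        assert co.coeff(1) == pytest.approx(4, abs=1e-12)
        for m in (-2, -1, 0):
            assert co.coeff(m) == pytest.approx(0, abs=1e-12)

    @pytest.mark.parametrize("n", [8, 16, 64])
    def test_matches_direct_evaluation(self, n):
        rng = np.random.default_rng(n)
        z = random_blob_signal(rng, n=n)
        np.testing.assert_allclose(dft(z).Z, direct_dft(z).Z,
                                   rtol=1e-9, atol=1e-9)

    def test_odd_or_short_period_rejected(self):
        with pytest.raises(ValueError):
            dft(np.ones(7, dtype=complex))
        with pytest.raises(ValueError):
            dft(np.ones(2, dtype=complex))

    def test_nonfinite_rejected(self):
        z = np.ones(8, dtype=complex)
        z[3] = np.nan
        with pytest.raises(ValueError):
            dft(z)


class TestNormalize:
    @pytest.mark.parametrize("seed", range(8))
    def test_full_invariance(self, seed):
        rng = np.random.default_rng(seed)
        z = random_blob_signal(rng)
        t = apply_transform(z,
                            theta0=rng.uniform(0, 2 * np.pi),
                            l0=int(rng.integers(0, len(z))),
                            scale=rng.uniform(0.2, 5.0),
                            translation=complex(*rng.uniform(-100, 100, 2)))
        a, b = normalize(dft(z)).Z, normalize(dft(t)).Z
        assert np.abs(a - b).max() <= 1e-9 * np.abs(a).max()

    def test_circle_normalizes_to_unit_fundamental(self):
        n = 32
        z = 7.0 * np.exp(2j * np.pi * np.arange(n) / n) + (3 + 4j)
        norm = normalize(dft(z))
        assert norm.coeff(1) == pytest.approx(1.0, abs=1e-12)
        rest = norm.Z.copy()
        rest[n // 2 + 1] = 0
        assert np.abs(rest).max() < 1e-12

    def test_fundamental_phases_vanish(self):
        rng = np.random.default_rng(42)
        norm = normalize(dft(random_blob_signal(rng)))
        assert np.angle(norm.coeff(1)) == pytest.approx(0.0, abs=1e-12)
        assert np.angle(norm.coeff(-1)) == pytest.approx(0.0, abs=1e-12)

    def test_transformed_phases_reproduce_originals(self):
        # the phase rule cancels theta_0 and l_0 coefficient-by-coefficient
        rng = np.random.default_rng(3)
        z = random_blob_signal(rng)
        t = apply_transform(z, theta0=1.234, l0=17)
        a, b = normalize(dft(z)), normalize(dft(t))
        mism = np.abs(np.exp(1j * a.arguments) - np.exp(1j * b.arguments))
        informative = a.modules > 1e-9
        assert mism[informative].max() < 1e-9

    def test_degenerate_shape_rejected(self):
        with pytest.raises(DegenerateShapeError):
            normalize(dft(np.full(8, 1.0 + 0j)))


class TestEnergy:
    def test_ideal_circle_energy(self):
        n, r = 32, 3.0
        co = dft(r * np.exp(2j * np.pi * np.arange(n) / n))
        for m in (4, 8, 32):
            assert energy(co, m) == pytest.approx((n * r) ** 2, rel=1e-12)

    def test_full_window_is_parseval_total(self):
        rng = np.random.default_rng(9)
        z = random_blob_signal(rng, n=64)
        co = dft(z)
        parseval = 64 * np.sum(np.abs(z - z.mean()) ** 2)
        assert energy(co, 64) == pytest.approx(parseval, rel=1e-9)

    def test_asymmetric_window_by_hand(self):
        # |Z_1|^2 = 3, |Z_-1|^2 = 1: M=2 covers {-1} only, M=4 all
        z8 = np.zeros(8, dtype=complex)
        co = SpectralCoefficients(Z=z8.copy(), N=8)
        co.Z[8 // 2 + 1] = np.sqrt(3)
        co.Z[8 // 2 - 1] = 1.0
        assert energy(co, 2) == pytest.approx(1.0)
        assert energy(co, 4) == pytest.approx(4.0)

    def test_nondecreasing_in_m(self):
        rng = np.random.default_rng(10)
        co = dft(random_blob_signal(rng, n=64))
        values = [energy(co, m) for m in range(2, 65, 2)]
        # each window is summed independently, so allow summation noise
        assert np.all(np.diff(values) >= -1e-9 * values[-1])

    def test_out_of_range_rejected(self):
        co = dft(np.exp(2j * np.pi * np.arange(8) / 8))
        for bad in (0, 3, 10):
            with pytest.raises(ValueError):
                energy(co, bad)


class TestSelectM:
    def test_ideal_circles_need_m4(self):
        circles = [dft(r * np.exp(2j * np.pi * np.arange(32) / 32))
                   for r in (1.0, 2.0, 5.0)]
        sel = select_m(circles, 0.9)
        assert sel.M == 4
        assert sel.target_reached

    def test_asymmetric_window_selection(self):
        z8 = np.zeros(8, dtype=complex)
        z8[8 // 2 + 1] = np.sqrt(3)
        z8[8 // 2 - 1] = 1.0
        sel = select_m([SpectralCoefficients(Z=z8, N=8)], 0.74)
        assert sel.M == 4  # M=2 retains only 1/4 of the energy

    def test_curve_nondecreasing_and_ends_at_one(self):
        rng = np.random.default_rng(12)
        sel = select_m([dft(random_blob_signal(rng, n=64)) for _ in range(5)],
                       0.9)
        assert np.all(np.diff(sel.mean_energy_fraction) >= -1e-12)
        assert sel.mean_energy_fraction[-1] == pytest.approx(1.0)

    def test_power_of_two_rounding(self):
        rng = np.random.default_rng(13)
        sel = select_m([dft(random_blob_signal(rng, n=256))
                        for _ in range(10)], 0.999)
        assert sel.M & (sel.M - 1) == 0  # power of two

    def test_invalid_fraction_rejected(self):
        co = dft(np.exp(2j * np.pi * np.arange(8) / 8))
        with pytest.raises(ValueError):
            select_m([co], 1.5)


class TestTruncateReconstruct:
    def test_full_truncation_is_identity(self):
        rng = np.random.default_rng(20)
        norm = normalize(dft(random_blob_signal(rng, n=32)))
        desc = truncate(norm, 32)
        np.testing.assert_allclose(desc.Zhat, norm.Z)
        assert desc.retained_energy_fraction == pytest.approx(1.0)

    def test_circle_truncates_to_unit_fundamental(self):
        z = np.exp(2j * np.pi * np.arange(32) / 32)
        desc = truncate(normalize(dft(z)), 4)
        assert desc.retained_energy_fraction == pytest.approx(1.0)
        expected = np.zeros(4, dtype=complex)
        expected[2 + 1] = 1.0
        np.testing.assert_allclose(desc.Zhat, expected, atol=1e-12)

    def test_truncated_energy_equals_source_window(self):
        rng = np.random.default_rng(21)
        norm = normalize(dft(random_blob_signal(rng, n=64)))
        desc = truncate(norm, 16)
        assert energy(SpectralCoefficients(Z=desc.Zhat, N=16), 16) == \
            pytest.approx(energy(norm, 16), rel=1e-12)

    def test_reconstruct_circle_descriptor(self):
        desc_z = np.zeros(32, dtype=complex)
        desc_z[16 + 1] = 1.0
        from drfvt.descriptor import NormalizedDescriptor
        desc = NormalizedDescriptor(Zhat=desc_z, M=32,
                                    retained_energy_fraction=1.0)
        z = reconstruct(desc)
        expected = np.exp(2j * np.pi * np.arange(32) / 32) / 32
        np.testing.assert_allclose(z, expected, atol=1e-12)

    @pytest.mark.parametrize("m", [8, 16, 32, 64])
    def test_reconstruct_matches_direct_evaluation(self, m):
        rng = np.random.default_rng(m)
        desc = truncate(normalize(dft(random_blob_signal(rng, n=64))), m)
        np.testing.assert_allclose(reconstruct(desc),
                                   direct_reconstruct(desc),
                                   rtol=1e-9, atol=1e-12)

    def test_round_trip_full_resolution(self):
        rng = np.random.default_rng(22)
        z = random_blob_signal(rng, n=64)
        norm = normalize(dft(z))
        back = reconstruct(truncate(norm, 64))
        # the forward transform is unnormalized, the inverse carries 1/M,
        # so the round trip returns the normalized signal itself
        np.testing.assert_allclose(np.fft.fftshift(np.fft.fft(back)),
                                   norm.Z, atol=1e-9)

    def test_reconstruction_error_nonincreasing_in_m(self):
        # evaluate the truncated series on the common N-point grid: the
        # mean-squared error vs the full-window reconstruction can only
        # shrink as the window grows
        rng = np.random.default_rng(23)
        norm = normalize(dft(random_blob_signal(rng, n=128)))
        m_values = np.arange(-64, 64)
        reference = np.fft.ifft(np.fft.ifftshift(norm.Z))
        errors = []
        for m in (8, 16, 32, 64, 128):
            masked = np.where((m_values >= -m // 2) & (m_values < m // 2),
                              norm.Z, 0.0)
            recon = np.fft.ifft(np.fft.ifftshift(masked))
            errors.append(np.mean(np.abs(recon - reference) ** 2))
        assert np.all(np.diff(errors) <= 1e-12)

    def test_json_round_trip(self):
        from drfvt.descriptor import NormalizedDescriptor
        rng = np.random.default_rng(24)
        desc = truncate(normalize(dft(random_blob_signal(rng, n=32))), 8)
        again = NormalizedDescriptor.from_json(desc.to_json())
        np.testing.assert_allclose(again.Zhat, desc.Zhat)
        assert again.M == desc.M
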
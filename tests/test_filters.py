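"""Steerable Gaussian-derivative filter bank."""

import numpy as np
import pytest
from numpy.polynomial import hermite_e
from scipy import ndimage, signal

from wdgrain import filters as F


def analytic_rotated_kernel(order, sigma, theta, radius):
    """Independent rotation oracle: the analytic k-th x-derivative of the
    Gaussian evaluated in coordinates rotated by theta, normalized the same
    way as the package kernels (unit-sum Gaussian factor, zero DC)."""
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1].astype(float)
    u = xx * np.cos(theta) + yy * np.sin(theta)
    v = -xx * np.sin(theta) + yy * np.cos(theta)
    c = np.zeros(order + 1)
    c[order] = 1.0
    g = lambda t: np.exp(-0.5 * (t / sigma) ** 2)
    k = (-1.0) ** order * sigma ** (-order) * hermite_e.hermeval(u / sigma, c) * g(u) * g(v)
    k /= g(np.arange(-radius, radius + 1.0)).sum() ** 2
    return k - k.mean()


class TestKernels:
    def test_smoothing_kernel_unit_sum(self):
        k = F.gaussian_derivative_kernel(F.KernelSpec(0, 0, 1.3))
        assert abs(k.sum() - 1.0) < 1e-12

    def test_first_derivative_zero_sum_and_parity(self):
        k = F.gaussian_derivative_kernel(F.KernelSpec(1, 0, 1.0))
        assert abs(k.sum()) < 1e-12
        np.testing.assert_allclose(k, -k[:, ::-1], atol=1e-15)  # odd in x
        np.testing.assert_allclose(k, k[::-1, :], atol=1e-15)  # even in y

    def test_all_derivative_kernels_zero_sum(self):
        for ix, iy in [(2, 0), (1, 1), (0, 2), (3, 0), (2, 1)]:
            k = F.gaussian_derivative_kernel(F.KernelSpec(ix, iy, 0.5))
            assert abs(k.sum()) < 1e-12

    def test_first_derivative_matches_finite_differences(self):
        # fine-step central difference of the analytic Gaussian (normalized
        # like the sampled kernel) as an independent derivative oracle
        spec = F.KernelSpec(1, 0, 1.0)
        k = F.gaussian_derivative_kernel(spec)
        r = spec.truncation_radius
        u = np.arange(-r, r + 1, dtype=float)
        z = np.exp(-0.5 * u**2).sum()
        g = lambda t: np.exp(-0.5 * t**2) / z
        h = 1e-4
        fd = np.outer(g(u), (g(u + h) - g(u - h)) / (2 * h))
        assert np.abs(k - fd).max() < 1e-3

    def test_unsupported_order(self):
        with pytest.raises(ValueError):
            F.KernelSpec(2, 2, 1.0)


class TestBasisCounts:
    @pytest.mark.parametrize("order,m", [(1, 2), (2, 3), (3, 4)])
    def test_counts(self, order, m):
        assert F.min_basis_count(order) == m

    def test_unsupported(self):
        for order in (0, 4):
            with pytest.raises(ValueError):
                F.min_basis_count(order)

    def test_order3_count_matches_fourier_harmonics(self):
        # sample the analytic order-3 kernel on a ring; the angular Fourier
        # spectrum must carry exactly 4 nonzero harmonics (n = +-1, +-3)
        sigma, r0, nphi = 2.0, 2.0, 256
        phi = 2 * np.pi * np.arange(nphi) / nphi
        x, y = r0 * np.cos(phi), r0 * np.sin(phi)
        c = np.zeros(4)
        c[3] = 1.0
        vals = -hermite_e.hermeval(x / sigma, c) / sigma**3 * np.exp(
            -(x**2 + y**2) / (2 * sigma**2)
        )
        spec = np.abs(np.fft.fft(vals)) / nphi
        sig = spec > 1e-12 * spec.max()
        harmonics = np.fft.fftfreq(nphi, d=1 / nphi)[sig].astype(int)
        assert set(harmonics) == {1, 3, -1, -3}
        assert sig.sum() == F.min_basis_count(3)


class TestSteeringCoefficients:
    def test_order1_axes(self):
        np.testing.assert_allclose(F.steering_coefficients(1, 0.0), [1, 0], atol=1e-15)
        np.testing.assert_allclose(
            F.steering_coefficients(1, np.pi / 2), [0, 1], atol=1e-15
        )

    def test_order2_diagonal(self):
        np.testing.assert_allclose(
            F.steering_coefficients(2, np.pi / 4), [0.5, 1.0, 0.5], atol=1e-15
        )

    def test_unsupported_order(self):
        with pytest.raises(ValueError):
            F.steering_coefficients(4, 0.1)


class TestBasisResponses:
    def test_constant_image_null_responses(self):
        cfg = F.FilterBankConfig(orders=(1, 2, 3), scales=(0.5, 1.0), n_directions=4)
        basis = F.build_basis_responses(np.full((32, 32), 0.7), cfg)
        for stack in basis.planes.values():
            assert np.abs(stack).max() < 1e-12

    def test_ramp_image_gradient(self):
        yy, xx = np.mgrid[0:40, 0:40].astype(float)
        cfg = F.FilterBankConfig(orders=(1,), scales=(1.0,), n_directions=4)
        basis = F.build_basis_responses(xx, cfg)
        gx, gy = basis.planes[(1, 1.0)]
        interior = (slice(8, -8), slice(8, -8))
        np.testing.assert_allclose(gx[interior], 1.0, atol=1e-3)
        np.testing.assert_allclose(gy[interior], 0.0, atol=1e-10)

    def test_matches_dense_convolution_oracle(self, random_image):
        cfg = F.FilterBankConfig(orders=(1, 2, 3), scales=(1.0,), n_directions=4)
        basis = F.build_basis_responses(random_image, cfg)
        for order in cfg.orders:
            for m, (ix, iy) in enumerate(F.basis_orders(order)):
                k = F.gaussian_derivative_kernel(F.KernelSpec(ix, iy, 1.0))
                r = (k.shape[0] - 1) // 2
                padded = np.pad(random_image, r, mode="symmetric")
                oracle = signal.convolve2d(padded, k, mode="valid")
                got = basis.planes[(order, 1.0)][m]
                assert np.abs(got - oracle).max() < 1e-10

    def test_too_small_image(self):
        cfg = F.FilterBankConfig(orders=(1,), scales=(2.0,), n_directions=4)
        with pytest.raises(ValueError):
            F.build_basis_responses(np.zeros((8, 8)), cfg)


class TestSteering:
    @pytest.fixture
    def basis(self, random_image):
        cfg = F.FilterBankConfig(orders=(1, 2, 3), scales=(0.5, 1.0, 2.0), n_directions=8)
        return F.build_basis_responses(random_image, cfg)

    def test_theta_zero_is_x_basis_plane(self, basis):
        got = F.steer_response(basis, 1, 1.0, 0.0)
        np.testing.assert_array_equal(got, basis.planes[(1, 1.0)][0])

    def test_period_parity(self, basis):
        r0 = F.steer_response(basis, 1, 1.0, 0.3)
        r_pi = F.steer_response(basis, 1, 1.0, 0.3 + np.pi)
        np.testing.assert_allclose(r_pi, -r0, atol=1e-12)
        e0 = F.steer_response(basis, 2, 1.0, 0.3)
        e_pi = F.steer_response(basis, 2, 1.0, 0.3 + np.pi)
        np.testing.assert_allclose(e_pi, e0, atol=1e-12)

    @pytest.mark.parametrize("deg", [17.0, 63.0, 151.0])
    @pytest.mark.parametrize("order", [1, 2, 3])
    @pytest.mark.parametrize("sigma", [0.5, 1.0, 2.0])
    def test_rotated_kernel_oracle(self, basis, random_image, order, sigma, deg):
        th = np.deg2rad(deg)
        steered = F.steer_response(basis, order, sigma, th)
        kr = analytic_rotated_kernel(order, sigma, th, F.default_truncation_radius(sigma))
        resp = ndimage.convolve(random_image, kr, mode="reflect")
        r = F.default_truncation_radius(sigma)
        sl = (slice(2 * r, -2 * r), slice(2 * r, -2 * r))
        diff = np.abs((steered - resp)[sl]).max()
        assert diff < 1e-2 * np.abs(steered).max()

    def test_bicubic_rotation_cross_check_at_coarse_scale(self, basis, random_image):
        # interpolation-based rotation is only meaningful when the kernel is
        # well resolved; at sigma = 2 it confirms the steering convention
        sigma, deg = 2.0, 63.0
        k0 = F.gaussian_derivative_kernel(F.KernelSpec(1, 0, sigma))
        kr = ndimage.rotate(k0, -deg, reshape=False, order=3)
        resp = ndimage.convolve(random_image, kr, mode="reflect")
        steered = F.steer_response(basis, 1, sigma, np.deg2rad(deg))
        r = F.default_truncation_radius(sigma)
        sl = (slice(2 * r, -2 * r), slice(2 * r, -2 * r))
        assert np.abs((steered - resp)[sl]).max() < 1e-2 * np.abs(steered).max()

    def test_order1_cos_sin_law(self, basis):
        r0 = F.steer_response(basis, 1, 1.0, 0.0)
        r90 = F.steer_response(basis, 1, 1.0, np.pi / 2)
        for th in (0.4, 1.1, 2.9):
            expect = np.cos(th) * r0 + np.sin(th) * r90
            np.testing.assert_allclose(
                F.steer_response(basis, 1, 1.0, th), expect, atol=1e-12
            )

    def test_steering_in_kernel_space_identical(self, random_image):
        # steering responses == convolving with the explicitly steered kernel
        cfg = F.FilterBankConfig(orders=(2,), scales=(1.0,), n_directions=4)
        basis = F.build_basis_responses(random_image, cfg)
        th = 0.7
        w = F.steering_coefficients(2, th)
        k = sum(
            c * F.gaussian_derivative_kernel(F.KernelSpec(ix, iy, 1.0))
            for c, (ix, iy) in zip(w, F.basis_orders(2))
        )
        resp = ndimage.convolve(random_image, k, mode="reflect")
        np.testing.assert_allclose(F.steer_response(basis, 2, 1.0, th), resp, atol=1e-12)

    def test_rotation_equivariance_quarter_turn(self, random_image):
        cfg = F.FilterBankConfig(orders=(1,), scales=(1.0,), n_directions=4)
        b1 = F.build_basis_responses(random_image, cfg)
        # rot90(img) rotates content by +90 deg in the (x toward y) sense
        b2 = F.build_basis_responses(np.rot90(random_image), cfg)
        th = 0.6
        lhs = F.steer_response(b2, 1, 1.0, th)
        rhs = np.rot90(F.steer_response(b1, 1, 1.0, th + np.pi / 2))
        m = 8
        np.testing.assert_allclose(lhs[m:-m, m:-m], rhs[m:-m, m:-m], atol=1e-10)

    def test_missing_scale_lookup(self, basis):
        with pytest.raises(KeyError):
            F.steer_response(basis, 1, 7.0, 0.0)
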
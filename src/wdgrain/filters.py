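"""Steerable Gaussian-derivative filter banks.

A k-th order Gaussian derivative steered to angle theta is the directional
derivative (cos(theta) d/dx + sin(theta) d/dy)^k of the Gaussian envelope.
Expanding the power shows it is an exact linear combination of the k+1
separable basis kernels G_{x^(k-m) y^m} with trigonometric-binomial weights,
so one convolution per basis kernel suffices for any number of directions:
steering is applied to the response planes by linearity of convolution.

Coordinates: axis 1 of an image array is x, axis 0 is y; theta is measured
from the +x axis toward +y (i.e. toward increasing row index).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import hermite_e
from scipy import ndimage

__all__ = [
    "KernelSpec",
    "FilterBankConfig",
    "BasisResponses",
    "gaussian_derivative_kernel",
    "min_basis_count",
    "steering_coefficients",
    "basis_orders",
    "build_basis_responses",
    "steer_response",
]

_MAX_ORDER = 3
DEFAULT_SCALES = (0.5, math.sqrt(2.0) / 2.0, 1.0, math.sqrt(2.0), 2.0)


def default_truncation_radius(sigma: float) -> int:
    """Kernel half-width: 4 sigma, at least 2 pixels."""
    return max(2, int(math.ceil(4.0 * sigma)))


@dataclass(frozen=True)
class KernelSpec:
    """A sampled Gaussian-derivative kernel d^i/dx^i d^j/dy^j G(x, y; sigma)."""

    x_order: int
    y_order: int
    sigma: float
    truncation_radius: int | None = None

    def __post_init__(self) -> None:
        if self.x_order < 0 or self.y_order < 0:
            raise ValueError("derivative orders must be >= 0")
        if self.order > _MAX_ORDER:
            raise ValueError(f"unsupported order {self.order}; supported up to {_MAX_ORDER}")
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError("sigma must be finite and > 0")
        if self.truncation_radius is None:
            object.__setattr__(self, "truncation_radius", default_truncation_radius(self.sigma))
        elif self.truncation_radius < default_truncation_radius(self.sigma):
            raise ValueError("truncation_radius must be >= ceil(4 sigma) and >= 2")

    @property
    def order(self) -> int:
        return self.x_order + self.y_order


@dataclass(frozen=True)
class FilterBankConfig:
    """Derivative orders, Gaussian scales and direction sampling of the bank."""

    orders: tuple[int, ...] = (1, 2, 3)
    scales: tuple[float, ...] = DEFAULT_SCALES
    n_directions: int = 180
    boundary_mode: str = "reflect"

    def __post_init__(self) -> None:
        object.__setattr__(self, "orders", tuple(sorted(int(o) for o in self.orders)))
        object.__setattr__(self, "scales", tuple(sorted(float(s) for s in self.scales)))
        if not self.orders or any(o < 1 or o > _MAX_ORDER for o in self.orders):
            raise ValueError("orders must be a nonempty subset of {1, 2, 3}")
        if any(s <= 0 for s in self.scales) or not self.scales:
            raise ValueError("scales must be positive")
        if self.n_directions < 1:
            raise ValueError("n_directions must be >= 1")

    @property
    def thetas(self) -> np.ndarray:
        """Direction angles theta_i = i * 2 pi / N over [0, 2 pi), radians."""
        return 2.0 * np.pi * np.arange(self.n_directions) / self.n_directions

    @property
    def max_truncation_radius(self) -> int:
        return default_truncation_radius(max(self.scales))


def _gauss_deriv_1d(order: int, sigma: float, radius: int) -> np.ndarray:
    """Sampled n-th derivative of the (discretely normalized) 1-D Gaussian.

    g^(n)(u) = (-1)^n sigma^-n He_n(u / sigma) g(u), with He_n the
    probabilists' Hermite polynomial.  The order-0 factor is normalized to
    unit sum.
    """
    u = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-0.5 * (u / sigma) ** 2)
    g /= g.sum()
    if order == 0:
        return g
    coeffs = np.zeros(order + 1)
    coeffs[order] = 1.0
    return (-1.0) ** order * sigma ** (-order) * hermite_e.hermeval(u / sigma, coeffs) * g


def gaussian_derivative_kernel(spec: KernelSpec) -> np.ndarray:
    """Separable 2-D kernel on a (2R+1) x (2R+1) grid; rows are y, cols x.

    Derivative kernels (order >= 1) receive an exact zero-sum (DC)
    correction: truncated sampling leaves even-order derivatives with a
    small residual mass, which would make a constant image respond nonzero.
    The correction is a uniform offset, so it commutes with steering.
    """
    gx = _gauss_deriv_1d(spec.x_order, spec.sigma, spec.truncation_radius)
    gy = _gauss_deriv_1d(spec.y_order, spec.sigma, spec.truncation_radius)
    k = np.outer(gy, gx)
    if spec.order >= 1:
        k = k - k.mean()
    return k


def min_basis_count(order: int) -> int:
    """Minimal number of basis kernels steering order k exactly: k + 1."""
    if order not in (1, 2, 3):
        raise ValueError(f"unsupported order {order}; supported orders are 1, 2, 3")
    return order + 1


def basis_orders(order: int) -> list[tuple[int, int]]:
    """(x_order, y_order) of the basis kernels, ordered G_{x^k} ... G_{y^k}."""
    if order not in (1, 2, 3):
        raise ValueError(f"unsupported order {order}; supported orders are 1, 2, 3")
    return [(order - m, m) for m in range(order + 1)]


def steering_coefficients(order: int, theta: float) -> np.ndarray:
    """Binomial-trigonometric steering weights for the basis of ``order``.

    Order 1: [cos t, sin t]; order 2: [cos^2 t, 2 sin t cos t, sin^2 t];
    order 3: [cos^3 t, 3 cos^2 t sin t, 3 cos t sin^2 t, sin^3 t].
    """
    m = min_basis_count(order)
    c, s = np.cos(theta), np.sin(theta)
    return np.array(
        [math.comb(order, j) * c ** (order - j) * s**j for j in range(m)]
    )


@dataclass
class BasisResponses:
    """Basis-filter response planes per (derivative order, scale).

    ``planes[(order, sigma)]`` stacks the M = order + 1 basis responses in
    the :func:`basis_orders` ordering; ``margins[sigma]`` is the boundary
    band (in pixels) affected by padding at that scale.
    """

    planes: dict = field(default_factory=dict)
    margins: dict = field(default_factory=dict)
    config: FilterBankConfig | None = None
    shape: tuple[int, int] | None = None

    def key(self, order: int, scale: float) -> tuple[int, float]:
        for o, s in self.planes:
            if o == order and np.isclose(s, scale, rtol=1e-12, atol=1e-12):
                return (o, s)
        raise KeyError(f"no basis responses for order={order}, scale={scale}")


def build_basis_responses(image: np.ndarray, config: FilterBankConfig) -> BasisResponses:
    """Convolve the image with every basis kernel of every (order, scale)."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite-valued")
    rmax = config.max_truncation_radius
    if min(img.shape) < 2 * rmax + 1:
        raise ValueError(
            f"image of shape {img.shape} is smaller than the kernel support "
            f"({2 * rmax + 1} px at scale {max(config.scales)})"
        )
    out = BasisResponses(config=config, shape=img.shape)
    for sigma in config.scales:
        out.margins[sigma] = default_truncation_radius(sigma)
        for order in config.orders:
            stack = np.empty((order + 1,) + img.shape)
            for m, (ix, iy) in enumerate(basis_orders(order)):
                kern = gaussian_derivative_kernel(KernelSpec(ix, iy, sigma))
                stack[m] = ndimage.convolve(img, kern, mode=config.boundary_mode)
            out.planes[(order, sigma)] = stack
    return out


def steer_response(
    basis: BasisResponses, order: int, scale: float, theta: float
) -> np.ndarray:
    """Response to the kernel steered to ``theta``: weighted sum of basis planes."""
    stack = basis.planes[basis.key(order, scale)]
    w = steering_coefficients(order, theta)
    return np.tensordot(w, stack, axes=1)
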
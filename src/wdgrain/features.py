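"""Multiscale omnidirectional spatial-structure features (WDMPs).

For every derivative order, Gaussian scale and direction, the steered filter
response is summarized by the two fitted parameters of the integral-form
Weibull model: the contrast scale beta and the granularity shape lambda.
Per (order, scale) the layout is [beta over all directions, lambda over all
directions]; the full feature vector concatenates these blocks over orders
(ascending), then scales (ascending), giving |orders| * T * 2N entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import filters, wd
from ._exceptions import DegenerateDataError, FitNonConvergenceWarning

__all__ = [
    "ScaleFeature",
    "FeatureVector",
    "extract_scale_features",
    "extract_features",
    "feature_names",
    "dominant_direction",
    "WDMPExtractor",
]


@dataclass
class ScaleFeature:
    """WDMP profiles of one (order, scale): beta and lambda per direction."""

    order: int
    sigma: float
    thetas: np.ndarray
    betas: np.ndarray
    lambdas: np.ndarray
    converged: np.ndarray

    @property
    def values(self) -> np.ndarray:
        """[beta_theta1..thetaN, lambda_theta1..thetaN]."""
        return np.concatenate([self.betas, self.lambdas])


@dataclass
class FeatureVector:
    """Concatenated ScaleFeature blocks with the bank configuration used."""

    values: np.ndarray
    config: filters.FilterBankConfig


def _fit_direction(response: np.ndarray) -> wd.FitResult:
    flat = response.ravel()
    if not np.any(flat != 0.0):
        raise DegenerateDataError(
            "steered response is identically zero (blank image?); no WD fit exists"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FitNonConvergenceWarning)
        res = wd.fit_wd(flat)
    return res


def _scale_feature_from_basis(
    basis: filters.BasisResponses, order: int, sigma: float, thetas: np.ndarray
) -> ScaleFeature:
    margin = basis.margins[basis.key(order, sigma)[1]]
    h, w = basis.shape
    if h - 2 * margin < 4 or w - 2 * margin < 4:
        raise ValueError("image interior too small after excluding the boundary margin")
    sl = (slice(margin, h - margin), slice(margin, w - margin))
    betas = np.empty(thetas.size)
    lambdas = np.empty(thetas.size)
    conv = np.empty(thetas.size, dtype=bool)
    n_failed = 0
    for i, th in enumerate(thetas):
        resp = filters.steer_response(basis, order, sigma, th)[sl]
        res = _fit_direction(resp)
        betas[i] = res.params.beta_scale
        lambdas[i] = res.params.lambda_shape
        conv[i] = res.converged
        n_failed += not res.converged
    if n_failed:
        warnings.warn(
            f"{n_failed}/{thetas.size} directional WD fits did not converge at "
            f"order {order}, sigma {sigma}; last iterates recorded",
            FitNonConvergenceWarning,
            stacklevel=3,
        )
    return ScaleFeature(order, sigma, thetas.copy(), betas, lambdas, conv)


def extract_scale_features(
    image: np.ndarray,
    order: int,
    sigma: float,
    n_directions: int,
    boundary_mode: str = "reflect",
) -> ScaleFeature:
    """Fit the WD model to the steered response at every direction of one
    (order, scale); boundary bands of one truncation radius are excluded."""
    cfg = filters.FilterBankConfig(
        orders=(order,), scales=(sigma,), n_directions=n_directions, boundary_mode=boundary_mode
    )
    basis = filters.build_basis_responses(image, cfg)
    return _scale_feature_from_basis(basis, order, sigma, cfg.thetas)


def extract_features(
    image: np.ndarray,
    config: filters.FilterBankConfig,
    standardize_intensity: bool = False,
) -> FeatureVector:
    """Full multiscale omnidirectional feature vector of one image.

    ``standardize_intensity`` optionally removes per-image illumination
    differences ((I - mean) / std) before filtering; off by default since
    derivative responses are already mean-free.
    """
    img = np.asarray(image, dtype=float)
    if standardize_intensity:
        sd = img.std()
        img = (img - img.mean()) / (sd if sd > 0 else 1.0)
    basis = filters.build_basis_responses(img, config)
    blocks = []
    for order in config.orders:
        for sigma in config.scales:
            sf = _scale_feature_from_basis(basis, order, sigma, config.thetas)
            blocks.append(sf.values)
    return FeatureVector(values=np.concatenate(blocks), config=config)


def feature_names(config: filters.FilterBankConfig) -> list[str]:
    """Column names in vector order: order{k}_s{sigma}_{beta|lambda}_{i}."""
    names = []
    for order in config.orders:
        for sigma in config.scales:
            for param in ("beta", "lambda"):
                names += [
                    f"order{order}_s{sigma:g}_{param}_{i}"
                    for i in range(config.n_directions)
                ]
    return names


def dominant_direction(
    sf: ScaleFeature, which: str = "beta", flat_tol: float = 0.1
) -> float | None:
    """Dominant orientation (degrees in [0, 180)) of a WDMP polar profile.

    Profiles are pi-periodic (a response and its negation share |x|
    statistics), so the angle is found from the doubled-angle circular mean
    of the mean-removed profile.  A profile flat to within ``flat_tol``
    (relative max-min spread) is reported as isotropic (None).
    """
    if which not in ("beta", "lambda"):
        raise ValueError("which must be 'beta' or 'lambda'")
    p = sf.betas if which == "beta" else sf.lambdas
    mean = p.mean()
    if mean <= 0 or (p.max() - p.min()) <= flat_tol * mean:
        return None
    z = np.sum((p - mean) * np.exp(2j * sf.thetas))
    ang = 0.5 * np.angle(z)
    return float(np.degrees(ang) % 180.0)


class WDMPExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping grayscale images to WDMP feature matrices.

    Stateless (``fit`` only validates); composes with sklearn pipelines in
    front of a classifier.

    Parameters
    ----------
    orders : tuple of int
        Gaussian-derivative orders, subset of {1, 2, 3}.
    scales : tuple of float
        Gaussian scales sigma in pixels.
    n_directions : int
        Number of steering directions over [0, 360).
    boundary_mode : str
        Padding mode for convolution (default reflect).
    standardize_intensity : bool
        Per-image intensity standardization before filtering.
    """

    def __init__(
        self,
        orders=(1, 2, 3),
        scales=filters.DEFAULT_SCALES,
        n_directions=180,
        boundary_mode="reflect",
        standardize_intensity=False,
    ):
        self.orders = orders
        self.scales = scales
        self.n_directions = n_directions
        self.boundary_mode = boundary_mode
        self.standardize_intensity = standardize_intensity

    def _config(self) -> filters.FilterBankConfig:
        return filters.FilterBankConfig(
            orders=tuple(self.orders),
            scales=tuple(self.scales),
            n_directions=self.n_directions,
            boundary_mode=self.boundary_mode,
        )

    def fit(self, X, y=None):
        self._config()
        self.n_features_out_ = (
            len(tuple(self.orders)) * len(tuple(self.scales)) * 2 * self.n_directions
        )
        return self

    def transform(self, X) -> np.ndarray:
        """X: iterable of 2-D images (or a 3-D stack) -> (n_images, n_features)."""
        cfg = self._config()
        rows = [
            extract_features(img, cfg, self.standardize_intensity).values for img in X
        ]
        return np.vstack(rows)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(feature_names(self._config()), dtype=object)
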
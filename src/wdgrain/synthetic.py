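"""Synthetic grain scenes: a dead-leaves generator.

Scenes are built by dropping a Poisson number of elliptical particles onto a
uniform background; later particles occlude earlier ones, reproducing the
sequential-fragmentation picture in which overlapping homogeneous regions
tile the field of view.  Gaussian-derivative responses of such scenes are
near zero-mean, symmetric and heavy-tailed — the regime the integral-form
Weibull model describes.  Particle size, density, contrast, elongation and
noise are controllable, so labeled two-class image sets (e.g. fine
low-contrast vs coarse high-contrast grain) can be produced for classifier
experiments without any proprietary imagery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from skimage.draw import ellipse as _draw_ellipse

__all__ = ["GrainSceneConfig", "generate_grain_image", "generate_labeled_dataset"]


@dataclass(frozen=True)
class GrainSceneConfig:
    """Stated world of one grain-scene class.

    density is the expected particle count per 1000 px^2; radii follow a
    gamma law with the given mean (px) and relative dispersion (sd/mean);
    per-particle gray levels are normal (contrast_mean, contrast_spread)
    clipped to [0, 1]; elongation >= 1 stretches particles along
    ``orientation_deg``.
    """

    height: int = 64
    width: int = 64
    density: float = 5.0
    mean_radius: float = 4.0
    radius_dispersion: float = 0.25
    elongation: float = 1.0
    orientation_deg: float = 0.0
    contrast_mean: float = 0.5
    contrast_spread: float = 0.15
    background: float = 0.45
    noise_std: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValueError("image must be at least 8 x 8")
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if self.mean_radius <= 0 or self.radius_dispersion < 0:
            raise ValueError("mean_radius must be > 0 and radius_dispersion >= 0")
        if self.elongation < 1.0:
            raise ValueError("elongation must be >= 1")
        if not 0.0 <= self.background <= 1.0:
            raise ValueError("background must lie in [0, 1]")
        if self.noise_std < 0 or self.contrast_spread < 0:
            raise ValueError("spread parameters must be >= 0")


def _sample_radii(rng: np.random.Generator, cfg: GrainSceneConfig, n: int) -> np.ndarray:
    if cfg.radius_dispersion == 0:
        r = np.full(n, cfg.mean_radius)
    else:
        shape = 1.0 / cfg.radius_dispersion**2
        r = rng.gamma(shape=shape, scale=cfg.mean_radius / shape, size=n)
    return np.clip(r, 0.5, min(cfg.height, cfg.width) / 2.0)


def generate_grain_image(cfg: GrainSceneConfig, return_mask: bool = False):
    """One dead-leaves scene in [0, 1]; reproducible for a fixed seed.

    With ``return_mask=True`` also returns the boolean particle-coverage
    mask (before noise), for coverage diagnostics.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.height, cfg.width
    img = np.full((h, w), float(cfg.background))
    mask = np.zeros((h, w), dtype=bool)

    # centers form a homogeneous Poisson process on a margin-padded window so
    # boundary pixels see the same particle statistics as the interior
    pad = 2.0 * cfg.mean_radius
    area = (h + 2 * pad) * (w + 2 * pad)
    n = rng.poisson(cfg.density * area / 1000.0)
    if n == 0:
        warnings.warn("no particles drawn; returning background-only image", stacklevel=2)
    radii = _sample_radii(rng, cfg, n)
    cy = rng.uniform(-pad, h + pad, size=n)
    cx = rng.uniform(-pad, w + pad, size=n)
    grays = np.clip(
        rng.normal(cfg.contrast_mean, cfg.contrast_spread, size=n), 0.0, 1.0
    )
    stretch = np.sqrt(cfg.elongation)
    # skimage rotates the ellipse counterclockwise in (row, col); our angle is
    # measured from +x toward +y (rows), hence the sign flip
    rot = -np.deg2rad(cfg.orientation_deg)
    for k in range(n):
        rr, cc = _draw_ellipse(
            cy[k],
            cx[k],
            radii[k] / stretch,
            radii[k] * stretch,
            shape=(h, w),
            rotation=rot,
        )
        img[rr, cc] = grays[k]
        mask[rr, cc] = True

    if cfg.noise_std > 0:
        img = img + rng.normal(0.0, cfg.noise_std, size=(h, w))
    img = np.clip(img, 0.0, 1.0)
    return (img, mask) if return_mask else img


def generate_labeled_dataset(
    class_a: GrainSceneConfig,
    class_b: GrainSceneConfig,
    n_a: int,
    n_b: int,
    seed: int = 0,
):
    """Labeled two-class image set: class_a -> +1, class_b -> -1.

    Per-image seeds are spawned deterministically from the master seed, so
    the k-th image of either class does not depend on how many images of
    the other class were drawn.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("need at least one image per class")
    ss = np.random.SeedSequence(seed)
    seeds_a, seeds_b = ss.spawn(2)
    images, labels = [], []
    for child, cfg, n_img, lab in (
        (seeds_a, class_a, n_a, +1),
        (seeds_b, class_b, n_b, -1),
    ):
        for s in child.spawn(n_img):
            img_seed = int(s.generate_state(1)[0] % (2**31 - 1))
            images.append(generate_grain_image(replace(cfg, seed=img_seed)))
            labels.append(lab)
    return images, np.asarray(labels)
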
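# Methods

## Overview

`wdgrain` classifies the processing quality of grain imagery without
segmenting individual kernels.  The image is treated as a texture: a field
of overlapping, locally homogeneous particles.  Its pipeline has four
stages:

1. **Filter bank** — steerable Gaussian-derivative filtering at several
   scales and many orientations.
2. **Statistical model** — each oriented response histogram is summarized
   by the two parameters of an integral-form Weibull (generalized-Gaussian)
   law fitted by maximum likelihood.
3. **Classifier** — the concatenated parameters feed a least-squares SVM
   with a combined polynomial + RBF kernel, class-weighted penalties and a
   pivoted Gram-Schmidt sparsification of the kernel matrix.
4. **Tuning** — free hyperparameters are selected by particle swarm
   optimization of the cross-validated classification error.

## The contrast model

Filter responses of particle-composed scenes are symmetric, zero-centred
and heavy-tailed.  They are modelled by

    p(x | λ, β) = C exp(−(1/λ)|x/β|^λ),
    C = λ / (2 λ^{1/λ} β Γ(1/λ)),

where λ > 0 is a shape (granularity) parameter and β > 0 a contrast scale.
λ = 2 recovers the Gaussian with sd β, λ = 1 the Laplace with scale β, and
λ ≪ 1 approaches a symmetric power law; the associated fractal dimension is
D_f = −3λ.  Coarser scenes (larger particles) produce smaller fitted λ;
stronger particle contrast produces larger β.  Anisotropy appears as
orientation dependence of the fitted parameters: particle-shape anisotropy
in λ, contrast anisotropy in β.

### Fitting

The scale has the closed-form conditional MLE
β̂(λ) = ((1/n) Σ|x_i|^λ)^{1/λ}.  Substituting it into the log-likelihood
leaves a one-dimensional profile score ζ(λ) whose root is the shape MLE.
ζ is implemented as the *analytic derivative of the profile
log-likelihood* (digamma/trigamma terms via `scipy.special`), and is
unit-tested against central finite differences of the profile
log-likelihood; a transcription error in any printed form of the score
cannot therefore corrupt fits.  Numerical choices:

- moduli are rescaled by max|x| before power sums (exact cancellation in
  ζ), so extreme shapes do not overflow;
- samples equal to 0 contribute |x|^λ = 0 and their ln|x| terms are
  dropped (the λ > 0 limit of x^λ ln x is 0);
- Newton–Raphson from λ₀ = 1 with restarts {0.5, 2, 4}, iterates confined
  to (0.05, 20); on divergence a sign-scan + Brent bracketing fallback
  runs before non-convergence is reported (`converged=False`, never a
  hang).  Tolerance 1e−6 on |Δλ|, max 100 iterations;
- sampling uses the exact gamma transform |X| = β(λT)^{1/λ},
  T ~ Gamma(1/λ), with a random sign.

Light-tailed inputs (e.g. pure sinusoids) genuinely want λ above the box;
those fits stop at the boundary and are flagged non-convergent while the
recorded β remains meaningful.

## Steerable filtering

A k-th order Gaussian derivative steered to angle θ is
(cos θ ∂x + sin θ ∂y)^k G; expanding the power shows it is an exact linear
combination of the k + 1 separable basis kernels G_{x^{k−m} y^m} with
weights C(k,m) cos^{k−m}θ sin^mθ.  The order-1 and order-2 weights are the
familiar [cos θ, sin θ] and [cos²θ, 2 sin θ cos θ, sin²θ]; order 3 follows
the same binomial pattern, consistent with the count of nonzero angular
Fourier harmonics (k + 1 basis functions suffice).  The image is convolved
once per basis kernel; any number of directions then costs only cheap
linear combinations of response planes — mathematically identical to
convolving with explicitly steered kernels, and verified in tests against
an independently rotated analytic kernel to machine precision.

Numerical choices: kernels are sampled Hermite-polynomial forms truncated
at radius max(2, ⌈4σ⌉); the smoothing factor is normalized to unit sum;
derivative kernels receive a uniform zero-DC correction (truncation leaves
even orders with residual mass, which would make constant images respond
nonzero; a uniform offset commutes with steering).  Convolution uses
reflect padding, and a boundary band of one truncation radius is excluded
from all downstream statistics, because padding artifacts distort tail
statistics.  Interpolation-based (bicubic) kernel rotation is *not* a
usable reference below σ ≈ 2 — the kernel is not resolved on the pixel
grid — which is why the rotation oracle in the tests resamples the
analytic form instead.

Directions are θ_i = i·360°/N.  Even-order responses repeat with period π;
the duplicates are retained so the layout matches the N-direction protocol
exactly.  The full-scale protocol uses five scales
[0.5, √2/2, 1, √2, 2] and N = 180; the CLI defaults to N = 36 for
desk-scale runtime (180 via `--n-directions`).

## Features

Per (order, scale) the feature block is [β over all N directions, λ over
all N directions]; blocks are concatenated over orders (ascending), then
scales (ascending): |orders| · T · 2N values (5400 at full scale).
Responses are used signed and uncentred; an optional per-image intensity
standardization flag removes illumination differences.  Multiplying image
intensities by s > 0 multiplies every β by s and leaves λ unchanged.  A
non-convergent directional fit records its last iterate with a warning
(fixed feature length); an identically zero response (blank image) is an
error.  Order combinations (e.g. orders {1,2,3} vs {3}) are realized by
concatenating/slicing per-order blocks.

The dominant orientation of a β or λ polar profile is the doubled-angle
circular mean of the mean-removed profile (profiles are π-periodic).  A
profile with relative spread below `flat_tol = 0.1` is reported isotropic:
measured directional fit jitter on isotropic references is 2–5 % while
genuinely anisotropic scenes (elongation 3) show 30–40 % spread, so 0.1
separates the two regimes with margin.

## Classifier

LSSVM training solves one bordered linear system; the equality constraint
Σa_t = 0 is part of the system.  Class imbalance is handled by per-sample
penalty weights c_t (s₊ on the positive class, s₋ on the negative), with
class-balanced defaults s_± = n/(2 n_±) so the mean weight is 1.  The
kernel is K = η K_poly + (1−η) K_RBF with defaults η = 0.4, polynomial
exponent d = 0.25, offset c = 1, and regularization r = 8.4.

**Non-Mercer caveat.** With fractional d, the polynomial base 1 + u·v/c
can be negative; the implementation clamps it at 0 and warns.  The clamped
kernel matrix is generally *indefinite*.  The pivoted factorization
therefore stops at the numerical PSD rank during training (negative
residual directions are never pivoted); the strict API raises on
indefiniteness by default.  Exact properties (full-rank equivalence with
the dense solve, 100 % separable-blob accuracy) hold for Mercer settings
(η = 0 or integer d) and are tested there.

**Sparsification.** Greedy pivoted Gram-Schmidt of the Gram matrix: pick
the column with the largest residual diagonal, orthogonalize the rest
(rank-1 update), stop at rank γ.  This is algebraically pivoted Cholesky,
and the implementation is cross-checked step by step against LAPACK
`dpstrf`.  How the reduced matrix enters training is an open design point;
here the γ pivots become the support set (Nyström style): the bordered
system is solved on the pivot block and prediction sums kernels over
pivots only, which is exactly the dense model at γ = n.  Default
γ = ⌈0.2 n⌉.

Features are column-standardized with training-split statistics before the
kernels (RBF width comparability).  A decision value of exactly 0 maps to
the positive class.  Multiclass problems are handled as per-class binary
tasks; no multiclass coupling is implemented.

## PSO tuning

Constant-inertia PSO (v ← d·v + c₁r₁(P_i − x) + c₂r₂(P_g − x)) with fresh
uniform r₁, r₂ per component per step, positions clipped to the box and
velocities clamped to 20 % of the box width (prevents divergence under a
constant inertia weight).  Defaults: swarm 30, 100 iterations, c₁ = c₂ =
2.0, inertia 0.7 — standard folklore values, all configurable, reproducible
per seed.  The tuning objective is the mean stratified k-fold
classification error (percent), with fold assignment frozen at closure
creation.  Typical tuned parameters are the RBF width and/or the class
penalties.

## Synthetic scenes

Real grain imagery from processing lines is proprietary, so the generator
produces dead-leaves scenes: a Poisson number of elliptical particles
(density per 1000 px², gamma-distributed radii with chosen mean and
relative dispersion, normal per-particle gray levels, optional elongation
along a chosen orientation) dropped onto a uniform background with later
particles occluding earlier ones, plus additive Gaussian noise, clipped to
[0, 1].  Particle centers form a homogeneous Poisson process on a padded
window so border pixels see interior statistics; expected coverage follows
the Boolean-model formula 1 − exp(−ρ·E[πab]), which the tests use as an
independent oracle.  Per-image seeds are spawned from a master seed, so
the k-th image of one class is independent of the other class's count.

Default world: 64×64 px scenes, density 5, mean radius 4 px (dispersion
0.25), contrast mean 0.5 / spread 0.15 on background 0.45, noise sd 0.02.
The two-class benchmark scenario contrasts a fine, low-contrast-spread
class (radius 3, spread 0.12) with a coarser, wider-spread class (radius
6, spread 0.2) — differences realistic for visually distinct grain
qualities, chosen once before any accuracy was measured.

What the generator does *not* emulate: kernel-shaped (non-elliptical)
particles, specular highlights, line-scan optics, illumination gradients,
or inter-particle contact physics.  A green end-to-end test therefore
establishes that the pipeline separates particle-statistics differences of
the stated magnitude, not that it reproduces any production accuracy
figure.

## Scaled-down end-to-end benchmark

`scripts/acceptance.py` and the end-to-end test run 100 training + 50 test
images per class, orders {1,2,3}, scales {0.5, 1, 2}, N = 36 directions,
classifier defaults (r = 8.4, η = 0.4, d = 0.25), and PSO-tune the RBF
width (swarm 8, 12 iterations, 3-fold CV — a deliberately small budget
that fits desk-scale runtime).  Held-out accuracy is typically 97–99 %,
and the all-orders feature set is at least as accurate as order 3 alone.

## Known limitations

- The non-Mercer clamped polynomial kernel can reduce the reachable
  sparsification rank and breaks exact dense/full-rank equivalence; use
  η = 0 or integer d where exactness matters.
- Shape fits saturate at the λ ∈ (0.05, 20) box for extremely light- or
  heavy-tailed inputs and are flagged non-convergent.
- Feature extraction cost scales with orders × scales × directions; the
  full 180-direction protocol is ~5× the 36-direction default.
- The gamma radius law is light-tailed; scale-free (power-law) dead-leaves
  size distributions are not provided.
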
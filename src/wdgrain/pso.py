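"""Particle swarm optimization of classifier hyperparameters.

Constant-inertia PSO: v <- d*v + c1*r1*(P_i - x) + c2*r2*(P_g - x),
x <- x + v, with fresh uniform r1, r2 per component per step, positions
clipped to the search box and velocities clamped to a fraction of the box
width.  The default objective for hyperparameter tuning is the mean
stratified k-fold classification error (percent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .lssvm import SMKLSSVMClassifier, evaluate_error

__all__ = ["PSOConfig", "PSOResult", "pso_optimize", "cv_objective", "tune"]

TUNABLE = ("s_plus", "s_minus", "rbf_sigma", "poly_exponent")


@dataclass(frozen=True)
class PSOConfig:
    swarm_size: int = 30
    iterations: int = 100
    inertia: float = 0.7
    c1: float = 2.0
    c2: float = 2.0
    velocity_clamp: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.inertia <= 1.0:
            raise ValueError("inertia must lie in [0, 1]")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("learning rates c1, c2 must be > 0")
        if self.swarm_size < 1 or self.iterations < 1:
            raise ValueError("swarm_size and iterations must be >= 1")


@dataclass
class PSOResult:
    best_position: np.ndarray
    best_value: float
    trace: np.ndarray  # global best value after each iteration


def _evaluate(objective, x: np.ndarray) -> float:
    v = float(objective(x))
    if not np.isfinite(v):
        warnings.warn(
            f"objective returned non-finite value at {x}; candidate rejected",
            stacklevel=3,
        )
        return np.inf
    return v


def pso_optimize(objective, bounds, config: PSOConfig | None = None) -> PSOResult:
    """Minimize ``objective`` over a box; reproducible for a fixed seed."""
    config = config or PSOConfig()
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2:
        raise ValueError("bounds must be a sequence of (lo, hi) pairs")
    lo, hi = bounds[:, 0], bounds[:, 1]
    if not np.all(np.isfinite(bounds)) or np.any(lo >= hi):
        raise ValueError("bounds must be finite with lo < hi")
    ndim = bounds.shape[0]
    width = hi - lo
    vmax = config.velocity_clamp * width

    rng = np.random.default_rng(config.seed)
    x = lo + rng.uniform(size=(config.swarm_size, ndim)) * width
    v = rng.uniform(-1.0, 1.0, size=(config.swarm_size, ndim)) * vmax

    pbest = x.copy()
    pbest_f = np.array([_evaluate(objective, xi) for xi in x])
    g = int(np.argmin(pbest_f))
    gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])

    trace = np.empty(config.iterations)
    for it in range(config.iterations):
        r1 = rng.uniform(size=(config.swarm_size, ndim))
        r2 = rng.uniform(size=(config.swarm_size, ndim))
        v = (
            config.inertia * v
            + config.c1 * r1 * (pbest - x)
            + config.c2 * r2 * (gbest - x)
        )
        v = np.clip(v, -vmax, vmax)
        x = np.clip(x + v, lo, hi)
        f = np.array([_evaluate(objective, xi) for xi in x])
        improved = f < pbest_f
        pbest[improved] = x[improved]
        pbest_f[improved] = f[improved]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
        trace[it] = gbest_f
    return PSOResult(best_position=gbest, best_value=gbest_f, trace=trace)


def cv_objective(X, y, tunable, folds: int = 5, seed: int = 0, base_estimator=None):
    """Map a hyperparameter vector to mean stratified k-fold CE (percent).

    ``tunable`` names the vector components, a subset of
    {'s_plus', 's_minus', 'rbf_sigma', 'poly_exponent'}; fold assignment is
    fixed at closure creation by ``seed``.
    """
    tunable = tuple(tunable)
    bad = set(tunable) - set(TUNABLE)
    if bad:
        raise ValueError(f"unknown tunable parameters: {sorted(bad)}")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    counts = np.unique(y, return_counts=True)[1]
    if counts.min() < folds:
        raise ValueError(
            f"stratified {folds}-fold split infeasible: smallest class has {counts.min()} samples"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    base = base_estimator if base_estimator is not None else SMKLSSVMClassifier()

    def objective(theta) -> float:
        theta = np.asarray(theta, dtype=float).ravel()
        if theta.size != len(tunable):
            raise ValueError(f"expected {len(tunable)} parameters, got {theta.size}")
        params = dict(zip(tunable, theta))
        errs = []
        for tr, te in splits:
            clf = base.__class__(**{**base.get_params(), **params})
            clf.fit(X[tr], y[tr])
            errs.append(evaluate_error(clf, X[te], y[te]))
        return float(np.mean(errs))

    return objective


def tune(
    X,
    y,
    tunable,
    bounds,
    folds: int = 5,
    pso_config: PSOConfig | None = None,
    base_estimator=None,
) -> tuple[dict, PSOResult]:
    """PSO-minimize the CV error over named hyperparameters; returns the
    best parameter dict and the full optimization result."""
    pso_config = pso_config or PSOConfig()
    obj = cv_objective(
        X, y, tunable, folds=folds, seed=pso_config.seed, base_estimator=base_estimator
    )
    res = pso_optimize(obj, bounds, pso_config)
    return dict(zip(tuple(tunable), res.best_position)), res
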
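"""Sparse multikernel least-squares SVM (SMK-LSSVM).

The LSSVM replaces the inequality-constrained SVM program with equality
constraints, so training reduces to one bordered linear system

    [ 0   1^T          ] [b]   [0]
    [ 1   K + D^-1     ] [a] = [y],     D = diag(r * c_t),

where ``r`` is the regularization factor and ``c_t`` per-sample penalty
weights (class-dependent, to handle imbalance).  The kernel is a convex
combination of a polynomial and an RBF kernel,

    K(u, v) = eta (1 + u.v / c)^d + (1 - eta) exp(-||u - v||^2 / 2 sigma^2).

Sparseness is recovered by a pivoted Gram-Schmidt (equivalently pivoted
Cholesky) factorization of the Gram matrix: greedily pick the column with
the largest residual diagonal, orthogonalize the rest, stop at rank gamma.
The model then uses only the gamma pivot samples as support set (Nystrom
style): the bordered system is solved on the pivot block and prediction
sums kernel evaluations over pivots only; at gamma = n this is exactly the
dense weighted LSSVM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from ._exceptions import KernelDomainWarning, NotPSDError

__all__ = [
    "KernelConfig",
    "TrainConfig",
    "SparseGram",
    "multikernel",
    "class_penalties",
    "solve_lssvm",
    "schmidt_sparsify",
    "SMKLSSVMClassifier",
    "train",
    "predict",
    "evaluate_error",
]


@dataclass(frozen=True)
class KernelConfig:
    """Combined polynomial + RBF kernel parameters."""

    eta: float = 0.4
    poly_offset: float = 1.0
    poly_exponent: float = 0.25
    rbf_sigma: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")
        if self.poly_offset <= 0:
            raise ValueError("poly_offset must be > 0")
        if self.rbf_sigma <= 0:
            raise ValueError("rbf_sigma must be > 0")


@dataclass(frozen=True)
class TrainConfig:
    """Regularization, class penalties and sparsification rank."""

    r: float = 8.4
    s_plus: float | None = None
    s_minus: float | None = None
    gamma_rank: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("r must be > 0")
        for s in (self.s_plus, self.s_minus):
            if s is not None and s <= 0:
                raise ValueError("penalty multipliers must be > 0")


@dataclass
class SparseGram:
    """Rank-gamma pivoted factorization of a Gram matrix.

    ``factors`` is (gamma, n) with K ~= factors.T @ factors; ``pivots`` the
    selection order; ``residual_trace[t]`` the trace of the residual after
    t pivots (non-increasing, starts at trace(K)).
    """

    factors: np.ndarray
    pivots: np.ndarray
    rank: int
    residual_trace: np.ndarray

    def reconstruct(self) -> np.ndarray:
        return self.factors.T @ self.factors


def multikernel(u, v, kc: KernelConfig) -> np.ndarray | float:
    """Kernel matrix eta*K_poly + (1-eta)*K_rbf between rows of u and v.

    Accepts single vectors or (n, p) matrices.  A negative polynomial base
    with non-integer exponent is outside the Mercer domain; it is clamped
    at zero with a :class:`KernelDomainWarning`.
    """
    u = np.atleast_2d(np.asarray(u, dtype=float))
    v = np.atleast_2d(np.asarray(v, dtype=float))
    if u.shape[1] != v.shape[1]:
        raise ValueError(f"dimension mismatch: {u.shape[1]} vs {v.shape[1]}")
    scalar = u.shape[0] == 1 and v.shape[0] == 1

    base = 1.0 + u @ v.T / kc.poly_offset
    if float(kc.poly_exponent) != int(kc.poly_exponent) and np.any(base < 0):
        warnings.warn(
            "negative polynomial-kernel base with non-integer exponent; "
            "clamping at 0 (kernel is non-Mercer in this region)",
            KernelDomainWarning,
            stacklevel=2,
        )
        base = np.maximum(base, 0.0)
    poly = base**kc.poly_exponent
    sq = cdist(u, v, metric="sqeuclidean")
    rbf = np.exp(-sq / (2.0 * kc.rbf_sigma**2))
    k = kc.eta * poly + (1.0 - kc.eta) * rbf
    return float(k[0, 0]) if scalar else k


def class_penalties(y, s_plus: float | None = None, s_minus: float | None = None) -> np.ndarray:
    """Per-sample penalty weights c_t: s_plus where y=+1, s_minus where y=-1.

    Defaults are class-balanced, s_± = n / (2 n_±), giving mean weight 1.
    """
    y = np.asarray(y)
    if not np.all(np.isin(y, (-1, 1))):
        raise ValueError("labels must be in {-1, +1}")
    n = y.size
    n_pos = int(np.sum(y == 1))
    n_neg = n - n_pos
    if s_plus is None:
        s_plus = n / (2.0 * n_pos) if n_pos else 1.0
    if s_minus is None:
        s_minus = n / (2.0 * n_neg) if n_neg else 1.0
    return np.where(y == 1, float(s_plus), float(s_minus))


def solve_lssvm(K: np.ndarray, y, r: float, c_t=None) -> tuple[np.ndarray, float]:
    """Solve the bordered (n+1) linear system for (a, b).

    The diagonal ridge is 1/(r c_t); with c_t = 1 this is the plain
    unweighted system.  The equality constraint sum(a) = 0 is part of the
    system and holds to solver accuracy.
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if K.shape != (n, n):
        raise ValueError("K must be n x n matching y")
    if r <= 0:
        raise ValueError("r must be > 0")
    c_t = np.ones(n) if c_t is None else np.asarray(c_t, dtype=float).ravel()
    if np.any(c_t <= 0):
        raise ValueError("penalty weights must be > 0")

    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.diag(1.0 / (r * c_t))
    rhs = np.concatenate([[0.0], y])
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e14:
        raise linalg.LinAlgError(
            f"bordered LSSVM system is singular or near-singular (cond={cond:.3g})"
        )
    sol = linalg.solve(A, rhs)
    return sol[1:], float(sol[0])


def schmidt_sparsify(
    K: np.ndarray, gamma_rank: int, tol: float = 1e-10, on_indefinite: str = "raise"
) -> SparseGram:
    """Greedy pivoted Gram-Schmidt factorization of a PSD Gram matrix.

    At each step the column with the maximal residual diagonal is selected
    and the remaining columns are orthogonalized against it (a rank-1
    residual update).  Stops early if the residual diagonal is exhausted;
    a residual diagonal below -tol * trace(K) raises :class:`NotPSDError`
    when ``on_indefinite='raise'``.  With ``on_indefinite='stop'`` the
    factorization instead halts at the numerical PSD rank (negative
    residual directions are never pivoted) — needed because the fractional
    polynomial kernel is not Mercer on clamped inputs.
    """
    if on_indefinite not in ("raise", "stop"):
        raise ValueError("on_indefinite must be 'raise' or 'stop'")
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    if K.shape != (n, n):
        raise ValueError("K must be square")
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("K must be symmetric")
    if not 1 <= gamma_rank <= n:
        raise ValueError("gamma_rank must be in [1, n]")

    d = np.diag(K).astype(float).copy()
    scale = max(d.max(), 1.0)
    factors = np.zeros((gamma_rank, n))
    pivots = []
    trace = [float(d.sum())]
    for t in range(gamma_rank):
        if d.min() < -tol * scale and on_indefinite == "raise":
            raise NotPSDError(
                f"residual diagonal went negative ({d.min():.3g}); Gram matrix is not PSD"
            )
        i = int(np.argmax(d))
        if d[i] <= tol * scale:
            break
        row = (K[i, :] - factors[:t, :].T @ factors[:t, i]) / np.sqrt(d[i])
        factors[t] = row
        d -= row**2
        d[i] = 0.0
        pivots.append(i)
        trace.append(float(np.maximum(d, 0.0).sum()))
    rank = len(pivots)
    return SparseGram(
        factors=factors[:rank],
        pivots=np.asarray(pivots, dtype=int),
        rank=rank,
        residual_trace=np.asarray(trace),
    )


class SMKLSSVMClassifier(ClassifierMixin, BaseEstimator):
    """Sparse multikernel least-squares SVM binary classifier.

    Parameters
    ----------
    eta : float in [0, 1]
        Weight of the polynomial kernel in the combination (RBF gets 1-eta).
    poly_offset, poly_exponent : float
        Polynomial kernel (1 + u.v/c)^d parameters.
    rbf_sigma : float
        RBF kernel width.
    r : float
        Regularization factor (larger = less ridge on the Gram diagonal).
    s_plus, s_minus : float or None
        Class penalty multipliers; None selects the class-balanced default
        n / (2 n_±).
    gamma_rank : int or None
        Number of support pivots kept by the Gram sparsification; None
        keeps ceil(0.2 n).
    standardize : bool
        Column-standardize features (train statistics) before the kernels.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Class labels; the lexically smaller maps to -1, the larger to +1.
    support_ : ndarray
        Indices (into the training set) of the pivot support samples.
    dual_coef_ : ndarray
        Support coefficients a_t.
    intercept_ : float
        Bias b.
    """

    def __init__(
        self,
        eta: float = 0.4,
        poly_offset: float = 1.0,
        poly_exponent: float = 0.25,
        rbf_sigma: float = 1.0,
        r: float = 8.4,
        s_plus: float | None = None,
        s_minus: float | None = None,
        gamma_rank: int | None = None,
        standardize: bool = True,
    ):
        self.eta = eta
        self.poly_offset = poly_offset
        self.poly_exponent = poly_exponent
        self.rbf_sigma = rbf_sigma
        self.r = r
        self.s_plus = s_plus
        self.s_minus = s_minus
        self.gamma_rank = gamma_rank
        self.standardize = standardize

    def _kernel_config(self) -> KernelConfig:
        return KernelConfig(
            eta=self.eta,
            poly_offset=self.poly_offset,
            poly_exponent=self.poly_exponent,
            rbf_sigma=self.rbf_sigma,
        )

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=2)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError(
                f"exactly two classes required, got {self.classes_.size}"
            )
        ypm = np.where(y == self.classes_[1], 1.0, -1.0)

        if self.standardize:
            self.mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.scale_ = np.where(sd > 0, sd, 1.0)
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        Xs = (X - self.mean_) / self.scale_

        n = Xs.shape[0]
        gamma = self.gamma_rank
        if gamma is None:
            gamma = int(np.ceil(0.2 * n))
        gamma = int(min(max(gamma, 1), n))

        kc = self._kernel_config()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", KernelDomainWarning)
            K = multikernel(Xs, Xs, kc)
        sg = schmidt_sparsify(K, gamma, on_indefinite="stop")
        piv = sg.pivots
        c_t = class_penalties(ypm, self.s_plus, self.s_minus)
        a, b = solve_lssvm(K[np.ix_(piv, piv)], ypm[piv], self.r, c_t[piv])

        self.sparse_gram_ = sg
        self.support_ = piv
        self.support_vectors_ = Xs[piv]
        self.dual_coef_ = a
        self.intercept_ = b
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "dual_coef_")
        X = check_array(X)
        Xs = (X - self.mean_) / self.scale_
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", KernelDomainWarning)
            K = multikernel(Xs, self.support_vectors_, self._kernel_config())
        return K @ self.dual_coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        d = self.decision_function(X)
        # tie at exactly 0 maps to +1 (the second class), by convention
        return np.where(d >= 0, self.classes_[1], self.classes_[0])


def train(X, y, kernel_config: KernelConfig | None = None, train_config: TrainConfig | None = None) -> SMKLSSVMClassifier:
    """Fit an :class:`SMKLSSVMClassifier` from plain config dataclasses."""
    kc = kernel_config or KernelConfig()
    tc = train_config or TrainConfig()
    clf = SMKLSSVMClassifier(
        eta=kc.eta,
        poly_offset=kc.poly_offset,
        poly_exponent=kc.poly_exponent,
        rbf_sigma=kc.rbf_sigma,
        r=tc.r,
        s_plus=tc.s_plus,
        s_minus=tc.s_minus,
        gamma_rank=tc.gamma_rank,
    )
    return clf.fit(X, y)


def predict(model: SMKLSSVMClassifier, x) -> tuple[np.ndarray, np.ndarray]:
    """Labels and raw decision values for one vector or a matrix of rows."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    d = model.decision_function(x)
    labels = np.where(d >= 0, model.classes_[1], model.classes_[0])
    if labels.size == 1:
        return labels[0], float(d[0])
    return labels, d


def evaluate_error(model: SMKLSSVMClassifier, X, y) -> float:
    """Classification error CE = (1/N) sum |yhat - y| / 2 * 100%."""
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("evaluation set is empty")
    yhat = model.predict(X)
    ypm = np.where(y == model.classes_[1], 1.0, -1.0)
    yhatpm = np.where(yhat == model.classes_[1], 1.0, -1.0)
    return float(np.mean(np.abs(yhatpm - ypm) / 2.0) * 100.0)
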
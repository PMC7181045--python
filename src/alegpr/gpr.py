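"""Gaussian process regression with a squared-exponential kernel.

The model places a zero-mean GP prior over the latent function,

    k(xi, xj) = sigma_f^2 * exp(-||xi - xj||^2 / (2 l^2)) + delta_ij * sigma_n^2,

with an isotropic length-scale ``l``, signal variance ``sigma_f^2`` and
observation-noise variance ``sigma_n^2``.  Hyperparameters are estimated by
maximizing the log marginal likelihood

    L = -n/2 log(2 pi) - 1/2 log det K - 1/2 y^T K^-1 y

with a quasi-Newton optimizer on (log l, log sigma_f^2, log sigma_n^2),
restarted from a seeded log-uniform box because the objective is multimodal.
Posterior prediction at a query point x* is

    mu = k*^T K^-1 y,    var = k(x*, x*) - k*^T K^-1 k*.

The point estimate reported by the soft sensor is the posterior mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize
from scipy.spatial.distance import cdist

JITTER_LADDER = (0.0, 1e-10, 1e-9, 1e-8, 1e-7, 1e-6)

# noise variance is kept strictly positive during optimization so that the
# kernel matrix stays invertible for duplicated inputs
_LOG_BOUNDS = (np.log(1e-6), np.log(1e4))


class FitError(RuntimeError):
    """All optimizer starts failed to produce a usable model."""


class ConditioningError(RuntimeError):
    """Kernel matrix not positive definite even at the maximum jitter."""


@dataclass(frozen=True)
class Hyperparams:
    """Kernel hyperparameter set {l, sigma_f^2, sigma_n^2}."""

    l: float
    sigma_f2: float
    sigma_n2: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.l) and self.l > 0):
            raise ValueError("length-scale must be finite and positive")
        if not (np.isfinite(self.sigma_f2) and self.sigma_f2 > 0):
            raise ValueError("signal variance must be finite and positive")
        if not (np.isfinite(self.sigma_n2) and self.sigma_n2 >= 0):
            raise ValueError("noise variance must be finite and non-negative")


def kernel(xi: np.ndarray, xj: np.ndarray, h: Hyperparams, same_index: bool = False) -> float:
    """Squared-exponential covariance between two points.

    ``same_index`` adds the Kronecker noise term (i == j in the training
    covariance matrix).
    """
    xi = np.asarray(xi, dtype=float).ravel()
    xj = np.asarray(xj, dtype=float).ravel()
    if xi.shape != xj.shape:
        raise ValueError("kernel inputs must have equal dimension")
    sq = float(np.sum((xi - xj) ** 2))
    value = h.sigma_f2 * np.exp(-0.5 * sq / h.l**2)
    if same_index:
        value += h.sigma_n2
    return float(value)


def kernel_matrix(
    Xa: np.ndarray, Xb: np.ndarray, h: Hyperparams, noise_diag: bool = False
) -> np.ndarray:
    """Cross-covariance matrix; ``noise_diag`` adds sigma_n^2 on the diagonal
    (only meaningful when Xa is Xb, i.e. the training Gram matrix)."""
    D2 = cdist(np.atleast_2d(Xa), np.atleast_2d(Xb), metric="sqeuclidean")
    K = h.sigma_f2 * np.exp(-0.5 * D2 / h.l**2)
    if noise_diag:
        K = K + h.sigma_n2 * np.eye(K.shape[0])
    return K


def _cholesky_with_jitter(K: np.ndarray) -> tuple[np.ndarray, float]:
    """Lower Cholesky factor of K + jitter*I, escalating jitter on failure."""
    scale = float(np.mean(np.diag(K))) or 1.0
    for jit in JITTER_LADDER:
        try:
            L = linalg.cholesky(K + jit * scale * np.eye(K.shape[0]), lower=True)
            return L, jit * scale
        except linalg.LinAlgError:
            continue
    raise ConditioningError("kernel matrix not positive definite at maximum jitter")


def log_marginal_likelihood(h: Hyperparams, X: np.ndarray, y: np.ndarray) -> float:
    """Log marginal likelihood of the data under hyperparameters ``h``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y are not conformable")
    K = kernel_matrix(X, X, h, noise_diag=True)
    L, _ = _cholesky_with_jitter(K)
    alpha = linalg.cho_solve((L, True), y)
    n = y.shape[0]
    return float(
        -0.5 * n * np.log(2 * np.pi) - np.sum(np.log(np.diag(L))) - 0.5 * y @ alpha
    )


def _negative_lml_and_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray, D2: np.ndarray):
    """Objective and gradient in (log l, log sigma_f^2, log sigma_n^2)."""
    log_l, log_sf2, log_sn2 = theta
    l2 = np.exp(2.0 * log_l)
    sf2 = np.exp(log_sf2)
    sn2 = np.exp(log_sn2)
    n = y.shape[0]
    Kf = sf2 * np.exp(-0.5 * D2 / l2)
    K = Kf + sn2 * np.eye(n)
    try:
        L, _ = _cholesky_with_jitter(K)
    except ConditioningError:
        return np.inf, np.zeros(3)
    alpha = linalg.cho_solve((L, True), y)
    lml = -0.5 * n * np.log(2 * np.pi) - np.sum(np.log(np.diag(L))) - 0.5 * y @ alpha
    # dL/dtheta = 1/2 tr((alpha alpha^T - K^-1) dK/dtheta)
    Kinv = linalg.cho_solve((L, True), np.eye(n))
    A = np.outer(alpha, alpha) - Kinv
    dK_dlogl = Kf * (D2 / l2)          # d/d log l of exp(-D2/(2 l^2))
    grad = np.array(
        [
            0.5 * np.sum(A * dK_dlogl),
            0.5 * np.sum(A * Kf),       # dK/d log sf2 = Kf
            0.5 * sn2 * np.trace(A),    # dK/d log sn2 = sn2 * I
        ]
    )
    return -lml, -grad


@dataclass(frozen=True)
class GPRModel:
    """Fitted GP regressor: hyperparameters plus cached training solve."""

    hyperparams: Hyperparams
    X_train: np.ndarray
    y_train: np.ndarray
    L: np.ndarray          # lower Cholesky factor of K + jitter
    alpha: np.ndarray      # (K + jitter)^-1 y
    jitter: float
    log_marginal: float

    def predict(self, Xq: np.ndarray, include_noise: bool = True):
        return predict(self, Xq, include_noise=include_noise)

    def to_json(self) -> str:
        return json.dumps(
            {
                "hyperparams": {
                    "l": self.hyperparams.l,
                    "sigma_f2": self.hyperparams.sigma_f2,
                    "sigma_n2": self.hyperparams.sigma_n2,
                },
                "X_train": self.X_train.tolist(),
                "y_train": self.y_train.tolist(),
                "log_marginal": self.log_marginal,
            }
        )

    @staticmethod
    def from_json(doc: str) -> "GPRModel":
        payload = json.loads(doc)
        h = Hyperparams(**payload["hyperparams"])
        return make_model(
            np.array(payload["X_train"]), np.array(payload["y_train"]), h
        )


def make_model(X: np.ndarray, y: np.ndarray, h: Hyperparams) -> GPRModel:
    """Assemble a GPRModel from data and fixed hyperparameters."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    K = kernel_matrix(X, X, h, noise_diag=True)
    L, jit = _cholesky_with_jitter(K)
    alpha = linalg.cho_solve((L, True), y)
    lml = float(
        -0.5 * y.size * np.log(2 * np.pi) - np.sum(np.log(np.diag(L))) - 0.5 * y @ alpha
    )
    return GPRModel(h, X, y, L, alpha, jit, lml)


def fit(X: np.ndarray, y: np.ndarray, restarts: int = 5, seed: int = 0) -> GPRModel:
    """Maximum marginal-likelihood fit with seeded multi-start L-BFGS-B.

    Starts are drawn log-uniformly from [1e-2, 1e2] for each of l, sigma_f^2
    and sigma_n^2; a unit start (1, var(y), var(y)/10) is always included.
    The best converged optimum over all starts is returned.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0] or X.shape[0] == 0:
        raise ValueError("X and y are not conformable")
    D2 = cdist(X, X, metric="sqeuclidean")
    rng = np.random.default_rng(seed)
    yvar = float(np.var(y)) or 1.0
    starts = [np.log([1.0, yvar, max(yvar / 10.0, 1e-4)])]
    starts.extend(
        np.log(10.0 ** rng.uniform(-2.0, 2.0, size=3)) for _ in range(restarts)
    )
    bounds = [(_LOG_BOUNDS[0], _LOG_BOUNDS[1])] * 3
    best = None
    diagnostics = []
    for theta0 in starts:
        res = optimize.minimize(
            _negative_lml_and_grad,
            np.clip(theta0, *_LOG_BOUNDS),
            args=(X, y, D2),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
        )
        diagnostics.append(res.message)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitError(f"all optimizer starts failed: {diagnostics}")
    log_l, log_sf2, log_sn2 = best.x
    h = Hyperparams(float(np.exp(log_l)), float(np.exp(log_sf2)), float(np.exp(log_sn2)))
    return make_model(X, y, h)


def predict(
    model: GPRModel, Xq: np.ndarray, include_noise: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and variance at the query points.

    ``include_noise`` adds sigma_n^2 to the prior self-covariance k(x*, x*),
    i.e. predicts the noisy observation rather than the latent function.
    Variances are clamped at zero against round-off.
    """
    Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
    if Xq.shape[1] != model.X_train.shape[1]:
        raise ValueError("query dimension does not match training dimension")
    h = model.hyperparams
    Kt = kernel_matrix(Xq, model.X_train, h)        # (q, n)
    mean = Kt @ model.alpha
    v = linalg.solve_triangular(model.L, Kt.T, lower=True)
    prior = h.sigma_f2 + (h.sigma_n2 if include_noise else 0.0)
    var = prior - np.sum(v * v, axis=0)
    return mean, np.maximum(var, 0.0)
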
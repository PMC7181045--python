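"""Gaussian mixture modelling of the process input space.

A K-component mixture p(x) = sum_k pi_k N(x | mu_k, Sigma_k) is fitted by
expectation-maximization on the labeled inputs; its components represent
fermentation operating phases (growth, production, autolysis).  Component
number is selected by the Bayesian information criterion

    BIC = -2 log L(X | Xi) + 3 K log N,

minimized over K (the penalty is used exactly in this 3K log N form; a
standard free-parameter-count penalty is available behind a flag).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.special import logsumexp

COV_REG_FACTOR = 1e-6      # diagonal loading: 1e-6 * trace(Sigma)/m each M step
EM_TOL = 1e-6
EM_MAX_ITER = 500


class EMError(RuntimeError):
    """EM failed persistently (empty component / singular covariance)."""


@dataclass(frozen=True)
class GMMParams:
    """Mixture parameter vector {pi_k, mu_k, Sigma_k}, k = 1..K."""

    weights: np.ndarray        # (K,)
    means: np.ndarray          # (K, m)
    covariances: np.ndarray    # (K, m, m)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError("mixture weights must sum to 1")
        if np.any(w <= 0):
            raise ValueError("mixture weights must be positive")

    @property
    def K(self) -> int:
        return self.weights.shape[0]

    @property
    def m(self) -> int:
        return self.means.shape[1]

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": self.weights.tolist(),
                "means": self.means.tolist(),
                "covariances": self.covariances.tolist(),
            }
        )

    @staticmethod
    def from_json(doc: str) -> "GMMParams":
        payload = json.loads(doc)
        return GMMParams(
            np.array(payload["weights"]),
            np.array(payload["means"]),
            np.array(payload["covariances"]),
        )


@dataclass
class EMTrace:
    log_likelihoods: list[float]
    converged: bool
    iterations: int


def _component_log_density(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Multivariate normal log-density of each row of X."""
    m = mean.shape[0]
    try:
        L = linalg.cholesky(cov, lower=True)
    except linalg.LinAlgError as exc:
        raise EMError("singular component covariance") from exc
    dev = X - mean
    sol = linalg.solve_triangular(L, dev.T, lower=True)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (m * np.log(2.0 * np.pi) + logdet + maha)


def component_density(x: np.ndarray, k: int, params: GMMParams) -> float:
    """Density of component k at a single point."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if not 0 <= k < params.K:
        raise IndexError(f"component {k} out of range")
    return float(np.exp(_component_log_density(x, params.means[k], params.covariances[k]))[0])


def _log_joint(params: GMMParams, X: np.ndarray) -> np.ndarray:
    """(n, K) matrix of log(pi_k) + log N(x_i | mu_k, Sigma_k)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.empty((X.shape[0], params.K))
    for k in range(params.K):
        out[:, k] = np.log(params.weights[k]) + _component_log_density(
            X, params.means[k], params.covariances[k]
        )
    return out


def log_likelihood(params: GMMParams, X: np.ndarray) -> float:
    """Total data log-likelihood log L(X | Xi)."""
    return float(logsumexp(_log_joint(params, X), axis=1).sum())


def responsibilities(params: GMMParams, X: np.ndarray) -> np.ndarray:
    """Posterior component probabilities per sample, computed in log space.

    Rows are non-negative and sum to one; this is the same Bayesian posterior
    used to weight local model predictions at query time.
    """
    lj = _log_joint(params, X)
    return np.exp(lj - logsumexp(lj, axis=1, keepdims=True))


def hard_assign(params: GMMParams, X: np.ndarray) -> np.ndarray:
    """Maximum-responsibility component per row (ties break to lower index)."""
    return np.argmax(responsibilities(params, X), axis=1)


def _regularize(cov: np.ndarray, scale: float) -> np.ndarray:
    """Diagonal loading proportional to the pooled data variance ``scale``;
    keyed to the data (not the component) so a component cannot buy unbounded
    likelihood by collapsing onto near-duplicate points."""
    m = cov.shape[0]
    return cov + (COV_REG_FACTOR * scale + 1e-12) * np.eye(m)


def _kmeanspp_means(X: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding of component means from the data rows."""
    n = X.shape[0]
    means = [X[rng.integers(n)]]
    for _ in range(1, K):
        d2 = np.min(
            [np.sum((X - mu) ** 2, axis=1) for mu in means], axis=0
        )
        total = d2.sum()
        if total <= 0:
            means.append(X[rng.integers(n)])
            continue
        means.append(X[rng.choice(n, p=d2 / total)])
    return np.array(means)


def _em_single(X: np.ndarray, K: int, rng: np.random.Generator) -> tuple[GMMParams, EMTrace]:
    n, m = X.shape
    pooled = np.atleast_2d(np.cov(X, rowvar=False, bias=True))
    scale = float(np.trace(pooled)) / m
    pooled = _regularize(pooled, scale)
    params = GMMParams(
        weights=np.full(K, 1.0 / K),
        means=_kmeanspp_means(X, K, rng),
        covariances=np.repeat(pooled[None, :, :], K, axis=0),
    )
    trace = EMTrace(log_likelihoods=[], converged=False, iterations=0)
    prev = -np.inf
    for it in range(1, EM_MAX_ITER + 1):
        lj = _log_joint(params, X)
        lse = logsumexp(lj, axis=1)
        ll = float(lse.sum())
        trace.log_likelihoods.append(ll)
        trace.iterations = it
        if ll - prev < EM_TOL and it > 1:
            trace.converged = True
            break
        prev = ll
        R = np.exp(lj - lse[:, None])          # E step
        nk = R.sum(axis=0)
        if np.any(nk < 1e-10):
            raise EMError("empty component during EM")
        weights = nk / n                       # M step
        means = (R.T @ X) / nk[:, None]
        covs = np.empty((K, m, m))
        for k in range(K):
            dev = X - means[k]
            covs[k] = _regularize((R[:, k][:, None] * dev).T @ dev / nk[k], scale)
        params = GMMParams(weights, means, covs)
    return params, trace


def fit_em(
    X: np.ndarray, K: int, seed: int = 0, n_init: int = 8
) -> tuple[GMMParams, EMTrace]:
    """Best-of-restarts EM fit of a K-component mixture.

    K=1 reduces to the closed-form sample mean / MLE covariance.  Restart
    streams are derived from ``seed``; a restart whose initialization leads
    to an empty component is retried with the next stream.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < K:
        raise ValueError(f"need at least K={K} samples, got {n}")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite rows")
    best: tuple[GMMParams, EMTrace] | None = None
    failures = []
    attempts = 0
    for init in range(3 * n_init):
        if attempts >= n_init:
            break
        rng = np.random.default_rng([seed, init])
        try:
            params, trace = _em_single(X, K, rng)
        except EMError as exc:
            failures.append(str(exc))
            continue
        attempts += 1
        if best is None or trace.log_likelihoods[-1] > best[1].log_likelihoods[-1]:
            best = (params, trace)
    if best is None:
        raise EMError(f"EM failed on all restarts: {failures}")
    return best


def bic(params: GMMParams, X: np.ndarray, penalty: str = "3k") -> float:
    """Bayesian information criterion of a fitted mixture.

    Default penalty is 3 K log N; ``penalty='free-params'`` uses the standard
    GMM free-parameter count (K-1) + K m + K m (m+1)/2 instead.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N = X.shape[0]
    ll = log_likelihood(params, X)
    if penalty == "3k":
        pen = 3.0 * params.K * np.log(N)
    elif penalty == "free-params":
        m = params.m
        pen = (params.K - 1 + params.K * m + params.K * m * (m + 1) / 2) * np.log(N)
    else:
        raise ValueError(f"unknown penalty {penalty!r}")
    return float(-2.0 * ll + pen)


KNEE_FRACTION = 0.15


def select_k(
    X: np.ndarray,
    k_range: range | tuple[int, int] = (1, 6),
    seeds: list[int] | None = None,
    penalty: str = "3k",
    method: str = "knee",
    n_init: int = 16,
) -> tuple[int, dict[int, float]]:
    """Select the mixture order from the mean-BIC curve over seeds.

    On process-trajectory data the BIC decreases essentially monotonically in
    K — extra components keep paying for fine trajectory structure — so the
    default ``knee`` rule reproduces the practitioner's reading of the elbow
    curve: it returns the smallest K after which the next component's BIC
    improvement drops below ``KNEE_FRACTION`` of the total BIC decline over
    the whole range (further increases of K no longer cause comparable
    decreases).
    ``method='argmin'`` instead returns the literal minimizer, ties toward
    smaller K.  The per-K mean-BIC table is returned for reporting.
    """
    if isinstance(k_range, tuple):
        ks = range(k_range[0], k_range[1] + 1)
    else:
        ks = k_range
    seeds = list(seeds) if seeds else [0]
    table: dict[int, float] = {}
    for K in ks:
        values = []
        for s in seeds:
            try:
                params, _ = fit_em(X, K, seed=s, n_init=n_init)
                values.append(bic(params, X, penalty=penalty))
            except (EMError, ValueError):
                continue
        if values:
            table[K] = float(np.mean(values))
    if not table:
        raise EMError("no component count could be fitted")
    if method == "argmin":
        best_k = min(table, key=lambda k: (table[k], k))
        return best_k, table
    if method != "knee":
        raise ValueError(f"unknown method {method!r}")
    ks_sorted = sorted(table)
    if len(ks_sorted) == 1:
        return ks_sorted[0], table
    gains = {
        k1: table[k0] - table[k1]
        for k0, k1 in zip(ks_sorted[:-1], ks_sorted[1:])
    }
    # gains at the overfitting scale are noise: a spurious extra component
    # gains about its free-parameter count in -2 log L (chi-square heuristic,
    # inflated several-fold by best-of-restarts maximization), which the weak
    # 3K log N penalty does not cancel for m > 2
    m = X.shape[1]
    p_extra = m + m * (m + 1) // 2 + 1
    floor = max(4.0 * p_extra, 6.0 * np.log(X.shape[0]))
    significant = {k: g for k, g in gains.items() if g > floor}
    if not significant:
        return ks_sorted[0], table
    threshold = max(KNEE_FRACTION * sum(significant.values()), floor)
    best_k = ks_sorted[-1]
    for k in ks_sorted[:-1]:
        nxt = gains[ks_sorted[ks_sorted.index(k) + 1]]
        if nxt <= threshold:
            best_k = k
            break
    return best_k, table


def merge_small_components(
    params: GMMParams, labels: np.ndarray, min_count: int = 3
) -> np.ndarray:
    """Reassign members of under-occupied components to the nearest viable one.

    Components with fewer than ``min_count`` assigned samples cannot support a
    local regressor; their samples move to the component whose mean is closest
    in Mahalanobis distance (under the receiving component's covariance).
    Returns the updated label vector (component indices unchanged otherwise).
    """
    labels = np.asarray(labels).copy()
    counts = np.bincount(labels, minlength=params.K)
    viable = np.flatnonzero(counts >= min_count)
    if viable.size == 0:
        # degenerate: single pooled component
        return np.zeros_like(labels)
    for k in range(params.K):
        if counts[k] >= min_count or counts[k] == 0:
            continue
        dists = []
        for j in viable:
            if j == k:
                continue
            dev = params.means[k] - params.means[j]
            dists.append((float(dev @ linalg.solve(params.covariances[j], dev)), j))
        target = min(dists)[1]
        labels[labels == k] = target
    return labels
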
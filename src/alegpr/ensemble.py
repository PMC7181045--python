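"""Ensemble GPR soft sensor: GMM-partitioned local models with Bayesian fusion.

The labeled inputs are partitioned into K operating phases by a Gaussian
mixture model (hard assignment for training); one GP regressor is fitted per
phase, and at query time the local posterior means are fused by the mixture
posterior responsibilities,

    y_p(x_q) = sum_k  y_qk(x_q) * p(C_k | x_q, Xi),

so the weights form a probability simplex per query.  Four soft-sensor
variants share this surface: global GPR vs the ensemble, each driven either
by random sampling or by the tree-based active learner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import gmm as gmm_mod
from . import gpr as gpr_mod
from .data import LabeledSet, UnlabeledPool, fit_target_scaler

VARIANTS = ("GPR", "EGPR", "AL-GPR", "AL-EGPR")
MIN_COMPONENT_SIZE = 3


@dataclass(frozen=True)
class EnsembleModel:
    """GMM phase model plus per-component local GP regressors.

    ``local_models`` maps component index -> GPRModel; components whose
    samples were merged away have no entry and contribute through their
    absorbing neighbor (their responsibilities are folded in at predict
    time via ``component_map``).
    """

    gmm: gmm_mod.GMMParams
    local_models: dict[int, gpr_mod.GPRModel]
    component_map: dict[int, int]          # raw component -> model component
    y_mean: float
    y_sd: float
    variant: str = "EGPR"

    @property
    def K(self) -> int:
        return self.gmm.K


COV_STABILIZATION = 0.1


def _stabilize_covariances(params: gmm_mod.GMMParams, X: np.ndarray) -> gmm_mod.GMMParams:
    """Blend each component covariance toward the pooled covariance.

    Early in the learning loop a component may hold barely more samples than
    the input dimension, making its ML covariance a near-singular needle:
    its density is then enormous inside a thin slab and effectively zero for
    the rest of its own operating phase, which misroutes query points to a
    neighboring local model.  Blending with weight m/n_k (scaled by
    ``COV_STABILIZATION``) vanishes as components fill up and leaves the
    mixture's means and weights untouched.
    """
    m = params.m
    pooled = np.atleast_2d(np.cov(X, rowvar=False, bias=True))
    n_k = gmm_mod.responsibilities(params, X).sum(axis=0)
    covs = params.covariances.copy()
    for k in range(params.K):
        lam = min(1.0, COV_STABILIZATION * m / max(n_k[k], 1.0))
        covs[k] = (1.0 - lam) * covs[k] + lam * pooled
    return gmm_mod.GMMParams(params.weights, params.means, covs)


def fit_ensemble(
    labeled: LabeledSet,
    K: int | str = 3,
    seed: int = 0,
    restarts: int = 5,
    k_range: tuple[int, int] = (1, 6),
) -> EnsembleModel:
    """Fit the GMM phase partition and one local GPR per occupied component.

    ``K='auto'`` selects the component count by the BIC criterion.  Targets
    are z-scored with labeled-set statistics shared by all local models so
    the fused mixture lives on a single scale.  Components left with fewer
    than 3 samples are merged into the Mahalanobis-nearest component before
    local fitting.
    """
    X, y = labeled.X, labeled.y
    if isinstance(K, str):
        if K != "auto":
            raise ValueError(f"unknown K specification {K!r}")
        K, _ = gmm_mod.select_k(X, k_range=k_range, seeds=[seed])
    K = min(int(K), max(1, X.shape[0] // MIN_COMPONENT_SIZE))
    params, _ = gmm_mod.fit_em(X, K, seed=seed)
    params = _stabilize_covariances(params, X)
    raw_labels = gmm_mod.hard_assign(params, X)
    labels = gmm_mod.merge_small_components(params, raw_labels, MIN_COMPONENT_SIZE)
    component_map = {}
    for k in range(params.K):
        assigned = np.unique(labels[raw_labels == k])
        component_map[k] = int(assigned[0]) if assigned.size else int(
            np.bincount(labels).argmax()
        )
    y_mean, y_sd = fit_target_scaler(y)
    z = (y - y_mean) / y_sd
    local_models: dict[int, gpr_mod.GPRModel] = {}
    for k in np.unique(labels):
        members = labels == k
        if members.sum() < MIN_COMPONENT_SIZE and len(np.unique(labels)) > 1:
            raise gpr_mod.FitError(
                f"component {k} has {int(members.sum())} samples after merging; "
                "reduce K"
            )
        local_models[int(k)] = gpr_mod.fit(
            X[members], z[members], restarts=restarts, seed=seed + int(k)
        )
    return EnsembleModel(
        gmm=params,
        local_models=local_models,
        component_map=component_map,
        y_mean=y_mean,
        y_sd=y_sd,
    )


def predict_ensemble(
    model: EnsembleModel, Xq: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Posterior-weighted fusion of the local predictions.

    Returns the fused point predictions (back-transformed to the original
    target scale) and a trace holding the per-component responsibilities,
    local means and local variances.
    """
    Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
    resp = gmm_mod.responsibilities(model.gmm, Xq)           # (q, K_raw)
    # fold merged components' weight into their absorbing model
    model_keys = sorted(model.local_models)
    weights = np.zeros((Xq.shape[0], len(model_keys)))
    col = {k: j for j, k in enumerate(model_keys)}
    for k in range(model.gmm.K):
        weights[:, col[model.component_map[k]]] += resp[:, k]
    local_means = np.empty((Xq.shape[0], len(model_keys)))
    local_vars = np.empty((Xq.shape[0], len(model_keys)))
    for j, k in enumerate(model_keys):
        mu, var = gpr_mod.predict(model.local_models[k], Xq)
        local_means[:, j] = mu
        local_vars[:, j] = var
    fused = np.sum(weights * local_means, axis=1)
    y_hat = fused * model.y_sd + model.y_mean
    trace = {
        "weights": weights,
        "components": model_keys,
        "local_means": local_means * model.y_sd + model.y_mean,
        "local_variances": local_vars * model.y_sd**2,
    }
    return y_hat, trace


@dataclass(frozen=True)
class GlobalModel:
    """A single GPR over all labeled data, on the shared variant surface."""

    gpr: gpr_mod.GPRModel
    y_mean: float
    y_sd: float
    variant: str = "GPR"


def fit_global(labeled: LabeledSet, seed: int = 0, restarts: int = 5) -> GlobalModel:
    y_mean, y_sd = fit_target_scaler(labeled.y)
    z = (labeled.y - y_mean) / y_sd
    return GlobalModel(
        gpr=gpr_mod.fit(labeled.X, z, restarts=restarts, seed=seed),
        y_mean=y_mean,
        y_sd=y_sd,
    )


def predict_global(model: GlobalModel, Xq: np.ndarray) -> np.ndarray:
    mu, _ = gpr_mod.predict(model.gpr, Xq)
    return mu * model.y_sd + model.y_mean


def predict_variant(model, Xq: np.ndarray) -> np.ndarray:
    if isinstance(model, EnsembleModel):
        return predict_ensemble(model, Xq)[0]
    return predict_global(model, Xq)


@dataclass
class VariantRun:
    """Outcome of running one soft-sensor variant through its sampling loop."""

    variant: str
    model: object
    labeled: LabeledSet
    pool: UnlabeledPool
    history: list[dict]

    def save_history(self, path) -> None:
        """Per-iteration audit log as JSON lines (selection traces included
        for the active variants)."""
        with open(path, "w") as fh:
            for entry in self.history:
                fh.write(json.dumps(entry) + "\n")


def fit_variant(
    tag: str,
    labeled: LabeledSet,
    pool: UnlabeledPool,
    oracle,
    *,
    ns: int = 20,
    n_iterations: int = 20,
    K: int | str = 3,
    pruning_size: int = 150,
    seed: int = 0,
    restarts: int = 5,
    beta: float = 2.0,
    n_classes: int = 3,
    per_iteration=None,
    early_stop_rmse: float | None = None,
    score=None,
) -> VariantRun:
    """Run one of the four Table-style variants through its sampling loop.

    Sampling is random for GPR/EGPR and tree-based active for AL-GPR /
    AL-EGPR; the learner is a global GPR for GPR/AL-GPR and the
    GMM-partitioned ensemble for EGPR/AL-EGPR.  The model is refitted from
    scratch after every query round.  ``per_iteration(it, model, labeled)``
    is invoked after each refit (iteration 0 = initial fit); ``score(model)``
    feeds the optional early-stop RMSE target.
    """
    if tag not in VARIANTS:
        raise ValueError(f"unknown variant {tag!r}; expected one of {VARIANTS}")
    use_active = tag.startswith("AL-")
    use_ensemble = tag.endswith("EGPR")
    rng = np.random.default_rng(seed)

    def refit():
        if use_ensemble:
            model = fit_ensemble(labeled, K=K, seed=seed, restarts=restarts)
        else:
            model = fit_global(labeled, seed=seed, restarts=restarts)
        object.__setattr__(model, "variant", tag)
        return model

    state = None
    if use_active:
        from . import sampler as sampler_mod
        from .hctree import build_tree, initial_pruning

        tree = build_tree(pool.X, pool.ids)
        pruning = initial_pruning(tree, min(pruning_size, pool.n))
        labels, scheme = sampler_mod.class_labels_from_targets(labeled.y, k_c=n_classes)
        state = sampler_mod.make_state(
            tree, pruning, scheme, n_classes=n_classes, beta=beta, seed=seed
        )
        # the initial labeled samples are known but sit outside the pool tree;
        # only queried pool leaves enter the node statistics
        sampler_mod.refine_pruning(state)

    model = refit()
    history = [{"iteration": 0, "n_labeled": labeled.n, "queried": []}]
    if per_iteration is not None:
        per_iteration(0, model, labeled)
    for it in range(1, n_iterations + 1):
        if pool.n == 0:
            break
        if use_active:
            from . import sampler as sampler_mod

            state, labeled, pool, batch = sampler_mod.al_iteration(
                state, labeled, pool, oracle, ns
            )
            queried = batch.ids
            audit = {
                "traces": batch.traces,
                "pruning_size": len(state.pruning),
                "weighted_error": sampler_mod.total_weighted_error(state),
            }
        else:
            take = min(ns, pool.n)
            pick = rng.choice(pool.n, size=take, replace=False)
            queried = [int(s) for s in pool.ids[pick]]
            y_new = np.asarray(oracle(queried), dtype=float)
            labeled = labeled.extend(np.asarray(queried), pool.X[pick], y_new)
            pool = pool.remove(queried)
            audit = {}
        if not queried:
            break
        model = refit()
        history.append(
            {"iteration": it, "n_labeled": labeled.n, "queried": queried, **audit}
        )
        if per_iteration is not None:
            per_iteration(it, model, labeled)
        if early_stop_rmse is not None and score is not None:
            if score(model) <= early_stop_rmse:
                break
    return VariantRun(tag, model, labeled, pool, history)


def save_bundle(model, path) -> None:
    """Serialize a fitted model (global or ensemble) to a JSON manifest."""
    if isinstance(model, EnsembleModel):
        payload = {
            "kind": "ensemble",
            "variant": model.variant,
            "gmm": json.loads(model.gmm.to_json()),
            "component_map": {str(k): v for k, v in model.component_map.items()},
            "y_mean": model.y_mean,
            "y_sd": model.y_sd,
            "local_models": {
                str(k): json.loads(m.to_json()) for k, m in model.local_models.items()
            },
        }
    else:
        payload = {
            "kind": "global",
            "variant": model.variant,
            "y_mean": model.y_mean,
            "y_sd": model.y_sd,
            "gpr": json.loads(model.gpr.to_json()),
        }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_bundle(path):
    with open(path) as fh:
        payload = json.load(fh)
    if payload["kind"] == "ensemble":
        return EnsembleModel(
            gmm=gmm_mod.GMMParams.from_json(json.dumps(payload["gmm"])),
            local_models={
                int(k): gpr_mod.GPRModel.from_json(json.dumps(doc))
                for k, doc in payload["local_models"].items()
            },
            component_map={int(k): v for k, v in payload["component_map"].items()},
            y_mean=payload["y_mean"],
            y_sd=payload["y_sd"],
            variant=payload["variant"],
        )
    return GlobalModel(
        gpr=gpr_mod.GPRModel.from_json(json.dumps(payload["gpr"])),
        y_mean=payload["y_mean"],
        y_sd=payload["y_sd"],
        variant=payload["variant"],
    )
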
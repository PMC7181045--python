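"""Cluster-adaptive active learning over the Ward tree.

The sampler maintains a *pruning* — an antichain of tree nodes covering all
pool leaves — together with per-node class statistics computed from the
queried (labeled) samples inside each subtree:

    p_{v,c}   = n_{v,c} / n_v                       empirical class fraction
    d_{v,c}   = 1 - n_{v,c} / n_v
    Delta     = d/n_v + sqrt(d * p (1-p) / n_v)     confidence half-width
    bounds    = [max(p - Delta, 0), min(p + Delta, 1)]

A class c is *admissible* at node v when its pessimistic error is within a
factor beta (default 2) of every rival's optimistic error:
(1 - p^LB_c) < beta * (1 - p^UB_c') for all c' != c.  The node's error is
1 - p of the most probable admissible class, or 1 if none is admissible.
Refinement replaces a pruning node by descendants whenever that lowers the
leaf-mass-weighted total error; queries then descend from the least
confident pruning node to an unqueried leaf.

The classes adapt the classification-style machinery to a regression task:
by default the labeled targets are quantile-binned into three levels whose
edges are frozen from the initial labeled set (mirroring the three
physiological phases); a GMM-component labeling scheme is the alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .hctree import HCTree, Node, check_antichain


@dataclass(frozen=True)
class ClassScheme:
    """Deterministic class labeling of targets (or inputs) for the sampler."""

    kind: str                      # "quantile-bins" | "gmm-component"
    edges: np.ndarray | None = None
    gmm_params: object | None = None

    def labels_for_targets(self, y: np.ndarray) -> np.ndarray:
        if self.kind != "quantile-bins":
            raise ValueError("target labeling requires the quantile-bins scheme")
        return np.searchsorted(self.edges, np.asarray(y, dtype=float), side="right")


def class_labels_from_targets(
    y_labeled: np.ndarray, scheme: str = "quantile-bins", k_c: int = 3, gmm_params=None,
    X_labeled: np.ndarray | None = None,
) -> tuple[np.ndarray, ClassScheme]:
    """Build the sampler's class labels from the initial labeled data.

    ``quantile-bins`` (default): k_c equal-probability bins of the labeled
    target; the bin edges are frozen so later relabeling is consistent.
    ``gmm-component``: hard GMM assignment of the labeled inputs.
    """
    y_labeled = np.asarray(y_labeled, dtype=float)
    if scheme == "quantile-bins":
        if k_c < 2:
            raise ValueError("k_c must be >= 2")
        qs = np.quantile(y_labeled, np.linspace(0, 1, k_c + 1)[1:-1])
        if np.ptp(y_labeled) == 0:
            warnings.warn(
                "all labeled targets equal; sampler degenerates to a single class",
                stacklevel=2,
            )
        sch = ClassScheme(kind="quantile-bins", edges=np.asarray(qs))
        return sch.labels_for_targets(y_labeled), sch
    if scheme == "gmm-component":
        from . import gmm as gmm_mod

        if gmm_params is None or X_labeled is None:
            raise ValueError("gmm-component scheme needs gmm_params and X_labeled")
        sch = ClassScheme(kind="gmm-component", gmm_params=gmm_params)
        return gmm_mod.hard_assign(gmm_params, X_labeled), sch
    raise ValueError(f"unknown scheme {scheme!r}")


@dataclass
class NodeStats:
    """Queried-sample class statistics and confidence bounds at one node."""

    n_labeled: int
    counts: np.ndarray                    # per-class queried counts
    p: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    admissible: np.ndarray                # boolean per class
    best_class: int | None
    error: float                          # epsilon-tilde in [0, 1]


@dataclass
class QueryBatch:
    ids: list[int]
    traces: list[list[int]]               # node-index path per selection
    exhausted: bool = False


@dataclass
class PruningState:
    """Mutable sampler state: the tree, its pruning, stats, and bookkeeping."""

    tree: HCTree
    pruning: list[Node]
    scheme: ClassScheme
    n_classes: int
    beta: float = 2.0
    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))
    queried_class: dict[int, int] = field(default_factory=dict)  # sample id -> class
    stats: dict[int, NodeStats] = field(default_factory=dict)    # node index -> stats
    weighted_error_mode: str = "mass"     # "mass" | "verbatim"

    def __post_init__(self) -> None:
        if self.beta <= 1:
            raise ValueError("beta must exceed 1")


def make_state(
    tree: HCTree,
    pruning: list[Node],
    scheme: ClassScheme,
    n_classes: int,
    beta: float = 2.0,
    seed: int = 0,
    weighted_error_mode: str = "mass",
) -> PruningState:
    state = PruningState(
        tree=tree,
        pruning=list(pruning),
        scheme=scheme,
        n_classes=n_classes,
        beta=beta,
        rng=np.random.default_rng(seed),
        weighted_error_mode=weighted_error_mode,
    )
    update_node_stats(state, {})
    return state


def _node_stats(state: PruningState, node: Node) -> NodeStats:
    k = state.n_classes
    members = [state.queried_class[s] for s in node.leaf_ids
               if int(s) in state.queried_class]
    n_lab = len(members)
    counts = np.bincount(members, minlength=k).astype(float) if n_lab else np.zeros(k)
    if n_lab == 0:
        p = np.zeros(k)
        lb = np.zeros(k)
        ub = np.ones(k)
    else:
        p = counts / n_lab
        d = 1.0 - p                              # d_{v,c} = 1 - n_{v,c}/n_v
        delta = d / n_lab + np.sqrt(d * p * (1.0 - p) / n_lab)
        lb = np.maximum(p - delta, 0.0)
        ub = np.minimum(p + delta, 1.0)
    admissible = np.zeros(k, dtype=bool)
    for c in range(k):
        rivals = np.delete(np.arange(k), c)
        admissible[c] = bool(
            np.all((1.0 - lb[c]) < state.beta * (1.0 - ub[rivals]))
        ) if rivals.size else True
    if admissible.any():
        cand = np.flatnonzero(admissible)
        best = int(cand[np.argmax(p[cand])])     # ties -> lower class index
        error = float(1.0 - p[best])
    else:
        best, error = None, 1.0
    return NodeStats(n_lab, counts, p, lb, ub, admissible, best, error)


def update_node_stats(state: PruningState, new_labels: dict[int, int]) -> PruningState:
    """Absorb newly queried (id -> class) labels and recompute all node stats."""
    state.queried_class.update({int(k): int(v) for k, v in new_labels.items()})
    state.stats = {nd.index: _node_stats(state, nd) for nd in state.tree.nodes}
    return state


def admissible(state: PruningState, node: Node, c: int) -> bool:
    return bool(state.stats[node.index].admissible[c])


def node_error(state: PruningState, node: Node) -> tuple[int | None, float]:
    st = state.stats[node.index]
    return st.best_class, st.error


def _weight(state: PruningState, node: Node) -> float:
    if state.weighted_error_mode == "verbatim":
        return 1.0
    return node.n_leaves / state.tree.n_leaves


def _best_refinement(state: PruningState, node: Node) -> tuple[float, list[Node]]:
    """Minimal weighted error over all prunings of this subtree (exact DP)."""
    own = _weight(state, node) * state.stats[node.index].error
    if node.is_leaf:
        return own, [node]
    le, lp = _best_refinement(state, node.left)
    re_, rp = _best_refinement(state, node.right)
    if le + re_ < own:
        return le + re_, lp + rp
    return own, [node]


def refine_pruning(state: PruningState) -> PruningState:
    """Replace pruning nodes by descendants wherever that lowers total error.

    The root-down replacement rule (swap a node for its children when the
    children's summed weighted error is lower) is applied to fixpoint via an
    exact subtree recursion, so the returned pruning attains the minimum
    total weighted error among all refinements of the current pruning.
    """
    new_pruning: list[Node] = []
    for nd in state.pruning:
        _, part = _best_refinement(state, nd)
        new_pruning.extend(part)
    state.pruning = new_pruning
    assert check_antichain(state.tree, state.pruning)
    return state


def total_weighted_error(state: PruningState) -> float:
    return float(sum(_weight(state, nd) * state.stats[nd.index].error
                     for nd in state.pruning))


def _n_unqueried(state: PruningState, node: Node) -> int:
    return int(sum(1 for s in node.leaf_ids if int(s) not in state.queried_class))


def _node_plb(state: PruningState, node: Node) -> float:
    st = state.stats[node.index]
    return float(st.lb[st.best_class]) if st.best_class is not None else 0.0


def select_batch(state: PruningState, ns: int) -> QueryBatch:
    """Select up to ``ns`` unqueried samples by confidence-guided descent.

    Each selection starts at the pruning node whose best-class lower bound
    is smallest (vacuous nodes rank first at 0), then descends choosing a
    child with probability proportional to its unqueried leaf count, ending
    at an unqueried leaf.  Confidence bounds cannot change until the batch
    labels arrive, so ties are broken toward nodes not yet visited in this
    batch (then larger remaining pool content, then lower node index): one
    query round spreads over as many distinct uncertain regions as it can,
    which is the point of hierarchical sampling.  Selections are marked
    immediately so a batch never repeats a sample.
    """
    batch = QueryBatch(ids=[], traces=[])
    selected: set[int] = set()
    pending: dict[int, int] = {}          # pruning-node index -> picks this batch

    def unqueried(node: Node) -> int:
        return int(
            sum(
                1
                for s in node.leaf_ids
                if int(s) not in state.queried_class and int(s) not in selected
            )
        )

    for _ in range(ns):
        candidates = [nd for nd in state.pruning if unqueried(nd) > 0]
        if not candidates:
            batch.exhausted = True
            break
        start = min(
            candidates,
            key=lambda nd: (
                _node_plb(state, nd),
                pending.get(nd.index, 0),
                -unqueried(nd),
                nd.index,
            ),
        )
        pending[start.index] = pending.get(start.index, 0) + 1
        node = start
        trace = [node.index]
        while not node.is_leaf:
            w = np.array([unqueried(node.left), unqueried(node.right)], dtype=float)
            if w.sum() == 0:  # pragma: no cover - guarded by candidate filter
                break
            child = (node.left, node.right)[int(state.rng.choice(2, p=w / w.sum()))]
            node = child
            trace.append(node.index)
        sid = int(node.sample_id)
        selected.add(sid)
        batch.ids.append(sid)
        batch.traces.append(trace)
    if not batch.ids:
        batch.exhausted = True
    return batch


def al_iteration(
    state: PruningState,
    labeled,
    pool,
    oracle,
    ns: int,
):
    """One active-learning round: select, query, update, refine.

    ``oracle`` maps a list of sample ids to their true target values.
    Returns the updated (state, labeled, pool, batch).  The oracle call is
    atomic: on failure nothing is mutated.
    """
    if ns == 0:
        return state, labeled, pool, QueryBatch(ids=[], traces=[])
    batch = select_batch(state, ns)
    if not batch.ids:
        return state, labeled, pool, batch
    y_new = np.asarray(oracle(batch.ids), dtype=float)
    if y_new.shape[0] != len(batch.ids) or not np.all(np.isfinite(y_new)):
        raise RuntimeError("oracle failed to label the requested ids")
    idx = pool.id_index(batch.ids) if hasattr(pool, "id_index") else None
    if idx is None:
        lookup = {int(s): i for i, s in enumerate(pool.ids)}
        idx = np.array([lookup[int(s)] for s in batch.ids], dtype=np.intp)
    X_new = pool.X[idx]
    labeled = labeled.extend(np.asarray(batch.ids), X_new, y_new)
    pool = pool.remove(batch.ids)
    if state.scheme.kind == "gmm-component":
        from . import gmm as gmm_mod

        classes = gmm_mod.hard_assign(state.scheme.gmm_params, X_new)
    else:
        classes = state.scheme.labels_for_targets(y_new)
    update_node_stats(state, dict(zip(batch.ids, (int(c) for c in classes))))
    refine_pruning(state)
    return state, labeled, pool, batch
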
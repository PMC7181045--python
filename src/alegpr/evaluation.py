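"""Benchmark protocol: metrics, iteration loops and learning-curve reports.

The protocol mirrors a fed-batch soft-sensing study: one simulated batch is
split alternately into 400 training and 400 test samples; 8 training samples
(2%) start labeled and the remaining 392 form the unlabeled pool.  Four
soft-sensor variants — global GPR or the GMM/GPR ensemble, each fed by
random sampling or by the hierarchical active learner — query ``ns`` pool
samples per iteration, refit, and are scored on the fixed test set after
every iteration.  Reported figures of merit:

    RMSE = sqrt(mean((y - y_hat)^2))
    TP   = 1 - Var(y_hat - y) / Var(y)       (tracking precision)

Results are aggregated as the arithmetic mean (and sd) over repeat seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from . import ensemble as ens
from .data import Dataset, SplitSpec, Scaler, fit_standardizer, apply_standardizer, split_initial
from .fermentation import KineticParams, LabelOracle, generate_dataset

log = logging.getLogger("alegpr.protocol")


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Root-mean-square prediction error."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("inputs must be equal-length and non-empty")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def tracking_precision(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """1 - Var(error)/Var(truth); insensitive to a constant prediction bias."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("inputs must be equal-length with at least 2 points")
    var_true = float(np.var(y_true))
    if var_true <= 0:
        raise ValueError("true values have zero variance")
    return 1.0 - float(np.var(y_pred - y_true)) / var_true


def alternating_split(data: Dataset) -> tuple[Dataset, Dataset]:
    """Even rows for training, odd rows for testing (no extrapolation)."""
    idx = np.arange(data.n)
    return data.rows(idx % 2 == 0), data.rows(idx % 2 == 1)


@dataclass(frozen=True)
class ProtocolConfig:
    """Study conditions for the four-variant benchmark."""

    n_samples: int = 800
    n_labeled_initial: int = 8
    ns: int = 20                              # learning step (queries/iteration)
    n_iterations: int = 7
    pruning_size: int = 150
    K: int | str = 3                          # mixture order or "auto"
    variants: tuple[str, ...] = ("GPR", "EGPR", "AL-GPR", "AL-EGPR")
    seeds: tuple[int, ...] = tuple(range(10))
    checkpoints: tuple[int, ...] = (3, 7)
    restarts: int = 5                         # GPR optimizer restarts
    early_stop_rmse: float | None = None
    kinetics: KineticParams = field(default_factory=KineticParams)

    def __post_init__(self) -> None:
        if self.ns < 0:
            raise ValueError("ns must be non-negative")
        if not self.seeds:
            raise ValueError("at least one seed required")


@dataclass
class IterationReport:
    """Tidy per-(variant, seed, iteration) scores plus failure log."""

    records: list[dict] = field(default_factory=list)
    failures: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def aggregate(self) -> pd.DataFrame:
        """Mean/sd over seeds per (variant, iteration)."""
        df = self.to_frame()
        return (
            df.groupby(["variant", "iteration"])
            .agg(
                rmse_mean=("rmse", "mean"),
                rmse_sd=("rmse", "std"),
                tp_mean=("tp", "mean"),
                tp_sd=("tp", "std"),
                n_labeled=("n_labeled", "first"),
                n_seeds=("seed", "nunique"),
            )
            .reset_index()
        )

    def checkpoint_table(self, checkpoints: tuple[int, ...]) -> pd.DataFrame:
        agg = self.aggregate()
        return agg[agg["iteration"].isin(checkpoints)].reset_index(drop=True)

    def save(self, json_path=None, csv_path=None) -> None:
        if csv_path is not None:
            self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            payload = {
                "records": self.records,
                "failures": self.failures,
                "aggregate": self.aggregate().to_dict(orient="records"),
            }
            with open(json_path, "w") as fh:
                json.dump(payload, fh, indent=1, sort_keys=True)


def _run_cell(
    config: ProtocolConfig,
    variant: str,
    seed: int,
    report: IterationReport,
    pruning_size: int | None = None,
) -> None:
    """One (variant, seed) benchmark cell: generate, split, iterate, score."""
    data = generate_dataset(config.kinetics, config.n_samples, seed=seed)
    train, test = alternating_split(data)
    scaler = fit_standardizer(train)
    train_std = apply_standardizer(scaler, train)
    test_std = apply_standardizer(scaler, test)
    labeled, pool = split_initial(
        train_std, SplitSpec(n_labeled_initial=config.n_labeled_initial, seed=seed)
    )
    oracle = LabelOracle(train_std)

    def score_iteration(it: int, model, labeled_now) -> None:
        y_hat = ens.predict_variant(model, test_std.X)
        r = rmse(test_std.y, y_hat)
        tp = tracking_precision(test_std.y, y_hat)
        report.records.append(
            {
                "variant": variant,
                "seed": seed,
                "iteration": it,
                "n_labeled": labeled_now.n,
                "rmse": r,
                "tp": tp,
                "queries": oracle.query_count,
            }
        )
        log.info(
            "variant=%s seed=%d iteration=%d n_labeled=%d rmse=%.5f tp=%.5f",
            variant, seed, it, labeled_now.n, r, tp,
        )

    ens.fit_variant(
        variant,
        labeled,
        pool,
        oracle,
        ns=config.ns,
        n_iterations=config.n_iterations,
        K=config.K,
        pruning_size=pruning_size or config.pruning_size,
        seed=seed,
        restarts=config.restarts,
        per_iteration=score_iteration,
        early_stop_rmse=config.early_stop_rmse,
        score=lambda model: report.records[-1]["rmse"],
    )


def run_protocol(config: ProtocolConfig) -> IterationReport:
    """Run every (variant, seed) cell; failures are recorded, not fatal."""
    report = IterationReport()
    for seed in config.seeds:
        for variant in config.variants:
            try:
                _run_cell(config, variant, seed, report)
            except Exception as exc:  # noqa: BLE001 - cell isolation is the contract
                log.exception("cell failed: variant=%s seed=%d", variant, seed)
                report.failures.append(
                    {"variant": variant, "seed": seed, "error": repr(exc)}
                )
    return report


def pruning_sweep(config: ProtocolConfig, sizes: list[int]) -> pd.DataFrame:
    """Learning curves of the active variants under different pruning sizes."""
    frames = []
    al_variants = tuple(v for v in config.variants if v.startswith("AL-")) or (
        "AL-GPR",
    )
    for size in sizes:
        report = IterationReport()
        for seed in config.seeds:
            for variant in al_variants:
                try:
                    _run_cell(config, variant, seed, report, pruning_size=size)
                except Exception as exc:  # noqa: BLE001
                    report.failures.append(
                        {"variant": variant, "seed": seed, "error": repr(exc)}
                    )
        agg = report.aggregate()
        agg.insert(0, "pruning_size", size)
        frames.append(agg)
    return pd.concat(frames, ignore_index=True)
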
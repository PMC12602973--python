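"""Repeated five-fold cross-validation with error-index and accuracy metrics.

For each of ``repeats`` independent shuffles the cohort is partitioned into
``k`` approximately equal folds; each fold serves once as the test set.  Per
(train, test) pair the feature scaler is fitted on the training fold only,
the network is trained (plain BP or GA-BP), and the test-fold predictions are
scored per output on the percent scale with

* the error index  EI = sqrt( sum (Shat_i - S_i)^2 / sum S_i^2 ),  a
  scale-free aggregate error, and
* the predictive accuracy  PA = 100 n / N,  the percentage of test samples
  whose signed relative error  (Shat_i - S_i) / S_i  has magnitude below 0.2.

Results are reported as mean ± SD over all k × repeats fold-results
(25 by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from dvhpredict.ga import GAConfig, ga_bp_train
from dvhpredict.network import NetworkParams, TrainConfig, predict, train
from dvhpredict.preprocessing import apply_scaler, fit_scaler
from dvhpredict.synthetic import OUTPUT_NAMES, CaseRecord

MODEL_KINDS = ("bp", "ga-bp")


@dataclass
class FoldPlan:
    """Deterministic fold assignments for repeated k-fold cross-validation."""

    n: int
    k: int
    repeats: int
    seed: int
    #: shape (repeats, n): fold label of each case in each repeat
    assignments: np.ndarray = field(repr=False)

    def fold_indices(self, repeat: int, fold: int) -> tuple[np.ndarray, np.ndarray]:
        labels = self.assignments[repeat]
        test = np.flatnonzero(labels == fold)
        trainset = np.flatnonzero(labels != fold)
        return trainset, test


def make_folds(n: int, k: int, repeats: int, seed: int) -> FoldPlan:
    """Partition n cases into k folds, ``repeats`` times with distinct shuffles."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError("cannot split fewer cases than folds")
    if repeats < 1:
        raise ValueError("repeats must be at least 1")
    children = np.random.SeedSequence(seed).spawn(repeats)
    assignments = np.empty((repeats, n), dtype=int)
    for r, child in enumerate(children):
        perm = np.random.default_rng(child).permutation(n)
        for fold, chunk in enumerate(np.array_split(perm, k)):
            assignments[r, chunk] = fold
    return FoldPlan(n=n, k=k, repeats=repeats, seed=seed, assignments=assignments)


def error_index(pred: Sequence[float], actual: Sequence[float]) -> float:
    """EI = sqrt( sum (pred - actual)^2 / sum actual^2 ); scale-free, >= 0."""
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape or pred.size == 0:
        raise ValueError("pred and actual must be equal-length nonempty vectors")
    denom = float(np.sum(actual**2))
    if denom == 0.0:
        raise ValueError("error index undefined for an all-zero actual vector")
    return float(np.sqrt(np.sum((pred - actual) ** 2) / denom))


def relative_errors(pred: Sequence[float], actual: Sequence[float]) -> np.ndarray:
    """Signed per-sample relative errors eta_i = (pred_i - actual_i) / actual_i."""
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape:
        raise ValueError("pred and actual must have equal length")
    zero = np.flatnonzero(actual == 0.0)
    if zero.size:
        raise ValueError(f"relative error undefined for zero actual value at index {zero[0]}")
    return (pred - actual) / actual


def predictive_accuracy(
    pred: Sequence[float], actual: Sequence[float], threshold: float = 0.2
) -> float:
    """PA = 100 x (count of |relative error| < threshold) / N, in percent."""
    eta = relative_errors(pred, actual)
    return 100.0 * float(np.count_nonzero(np.abs(eta) < threshold)) / eta.size


@dataclass
class MetricReport:
    """Per-output EI and PA of one model, aggregated over all fold-results."""

    model_kind: str
    outputs: tuple[str, ...]
    ei_mean: dict[str, float]
    ei_sd: dict[str, float]
    pa_mean: dict[str, float]
    pa_sd: dict[str, float]
    fold_results: dict[str, list[dict[str, float]]]

    def to_dict(self) -> dict:
        return {
            "model": self.model_kind,
            "outputs": list(self.outputs),
            "ei_mean": self.ei_mean,
            "ei_sd": self.ei_sd,
            "pa_mean": self.pa_mean,
            "pa_sd": self.pa_sd,
            "fold_results": self.fold_results,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def _train_for_fold(
    train_records: Sequence[CaseRecord],
    model_kind: str,
    fold_seed: int,
    train_cfg: TrainConfig,
    ga_cfg: GAConfig,
):
    """Fit scaler and model on a training fold; all randomness from fold_seed."""
    scaler = fit_scaler(train_records)
    X, Y = apply_scaler(train_records, scaler)
    tcfg = TrainConfig(
        eta=train_cfg.eta,
        target_error=train_cfg.target_error,
        max_epochs=train_cfg.max_epochs,
        shuffle_seed=fold_seed,
    )
    if model_kind == "bp":
        params0 = NetworkParams.random(fold_seed)
        params, state = train(params0, X, Y, tcfg)
    elif model_kind == "ga-bp":
        gcfg = GAConfig(
            pop_size=ga_cfg.pop_size,
            generations=ga_cfg.generations,
            crossover_rate=ga_cfg.crossover_rate,
            mutation_rate=ga_cfg.mutation_rate,
            gene_bounds=ga_cfg.gene_bounds,
            elitism=ga_cfg.elitism,
            mutation_span=ga_cfg.mutation_span,
            seed=fold_seed,
        )
        params, state = ga_bp_train(X, Y, gcfg, tcfg)
    else:
        raise ValueError(f"unknown model kind {model_kind!r}; choose from {MODEL_KINDS}")
    return params, scaler, state


def run_cv(
    cohort: Sequence[CaseRecord],
    model_kind: str,
    seed: int,
    train_cfg: TrainConfig | None = None,
    ga_cfg: GAConfig | None = None,
    k: int = 5,
    repeats: int = 5,
    pa_threshold: float = 0.2,
) -> MetricReport:
    """Repeated k-fold cross-validation of one model kind over the cohort.

    The scaler is fitted on each training fold only (no leakage); fold shuffles
    and per-fold training seeds all derive from ``seed``.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}; choose from {MODEL_KINDS}")
    train_cfg = train_cfg or TrainConfig()
    ga_cfg = ga_cfg or GAConfig()
    cohort = list(cohort)
    plan = make_folds(len(cohort), k, repeats, seed)
    # independent stream for per-fold training seeds, decoupled from the folds
    fold_seed_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    fold_seeds = fold_seed_rng.integers(0, 2**31 - 1, size=(repeats, k))

    fold_results: dict[str, list[dict[str, float]]] = {name: [] for name in OUTPUT_NAMES}
    for r in range(repeats):
        for f in range(k):
            train_idx, test_idx = plan.fold_indices(r, f)
            train_records = [cohort[i] for i in train_idx]
            test_records = [cohort[i] for i in test_idx]
            params, scaler, _ = _train_for_fold(
                train_records, model_kind, int(fold_seeds[r, f]), train_cfg, ga_cfg
            )
            feats = np.array([rec.features() for rec in test_records])
            preds = predict(params, scaler, feats)  # percent scale
            actual = np.array([rec.outcomes() for rec in test_records])
            for j, name in enumerate(OUTPUT_NAMES):
                fold_results[name].append(
                    {
                        "ei": error_index(preds[:, j], actual[:, j]),
                        "pa": predictive_accuracy(preds[:, j], actual[:, j], pa_threshold),
                    }
                )

    ei_mean, ei_sd, pa_mean, pa_sd = {}, {}, {}, {}
    for name in OUTPUT_NAMES:
        eis = np.array([c["ei"] for c in fold_results[name]])
        pas = np.array([c["pa"] for c in fold_results[name]])
        ei_mean[name] = float(eis.mean())
        ei_sd[name] = float(eis.std(ddof=1))
        pa_mean[name] = float(pas.mean())
        pa_sd[name] = float(pas.std(ddof=1))
    return MetricReport(
        model_kind=model_kind,
        outputs=OUTPUT_NAMES,
        ei_mean=ei_mean,
        ei_sd=ei_sd,
        pa_mean=pa_mean,
        pa_sd=pa_sd,
        fold_results=fold_results,
    )
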
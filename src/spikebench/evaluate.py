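"""The classification benchmark: spike-based prediction, accuracy/error,
pairwise performance loss, and the end-to-end nine-model comparison.

Each single neuron classifies a scalar sample by whether it emits at least one
spike while driven by a constant current equal to the feature (the default
*unit* mapping).  The alternative *population* mapping drives a population of
neurons whose input weights are drawn from Normal(0, 1) and predicts class 1
when more than half of the population spikes.  No learning of any kind takes
place: the benchmark probes the intrinsic input-to-spike transfer of each
model's dynamics under its benchmark parameters.

Accuracy is ``100 * mean(predictions == labels)``; the error rate is its
complement ``100 - accuracy``.  The performance loss of model A relative to a
reference model B is the relative accuracy difference
``L(A, B) = 100 * (acc_A - acc_B) / acc_B`` (negative when A is worse).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import LabeledDataset, generate_dataset
from .models import MODEL_NAMES, Model, make_model
from .simulate import simulate_batch

__all__ = ["WeightVector", "EvaluationReport", "classify_dataset",
           "accuracy_error", "performance_loss_matrix", "run_benchmark"]

DEFAULT_WINDOW_STEPS = 100
DEFAULT_N_SEEDS = 10


@dataclass(frozen=True)
class WeightVector:
    """Per-neuron input weights, drawn from Normal(0, 1) under ``seed``."""

    weights: np.ndarray
    seed: int

    @classmethod
    def draw(cls, n_neurons: int, seed: int) -> "WeightVector":
        rng = np.random.default_rng(seed)
        return cls(weights=rng.normal(0.0, 1.0, n_neurons), seed=seed)


@dataclass
class EvaluationReport:
    """Per-model benchmark metrics plus everything needed to reproduce them."""

    accuracy: dict[str, float]
    error: dict[str, float]
    spike_totals: dict[str, int]
    seeds: tuple[int, ...]
    config_snapshot: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "model": list(self.accuracy),
            "accuracy_pct": [self.accuracy[m] for m in self.accuracy],
            "error_pct": [self.error[m] for m in self.accuracy],
            "spike_total": [self.spike_totals[m] for m in self.accuracy],
        })

    def ranking(self) -> list[str]:
        return sorted(self.accuracy, key=self.accuracy.get, reverse=True)


def classify_dataset(model: Model, dataset: LabeledDataset,
                     mapping: str = "unit",
                     window_steps: int = DEFAULT_WINDOW_STEPS,
                     weight_seed: int | None = None,
                     population_size: int = 1000,
                     return_counts: bool = False):
    """Predict a binary class for every sample from the model's spiking.

    Unit mapping: one neuron per sample, input current equal to the feature;
    class 1 iff it spikes at least once in the window.  Population mapping:
    ``population_size`` neurons with Normal(0, 1) input weights per sample;
    class 1 iff more than half of them spike.
    """
    if dataset.n_samples == 0:
        raise ValueError("dataset is empty")
    if mapping == "unit":
        counts = simulate_batch(model, dataset.features, window_steps)
        predictions = (counts >= 1).astype(np.int64)
    elif mapping == "population":
        wv = WeightVector.draw(population_size, 0 if weight_seed is None else weight_seed)
        currents = np.outer(dataset.features, wv.weights)
        counts = simulate_batch(model, currents, window_steps)
        fraction = (counts >= 1).mean(axis=1)
        predictions = (fraction > 0.5).astype(np.int64)
        counts = counts.sum(axis=1)
    else:
        raise ValueError(f"unknown mapping {mapping!r}")
    if return_counts:
        return predictions, counts
    return predictions


def accuracy_error(predictions: Sequence[int], labels: Sequence[int]
                   ) -> tuple[float, float]:
    """``(accuracy_pct, error_pct)`` with error = 100 - accuracy."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape or predictions.size == 0:
        raise ValueError("predictions and labels must be nonempty and equal-length")
    accuracy = 100.0 * float(np.mean(predictions == labels))
    return accuracy, 100.0 - accuracy


def performance_loss_matrix(accuracies: Mapping[str, float]) -> pd.DataFrame:
    """Pairwise relative performance loss, in percent.

    ``L(A, B) = 100 * (acc_A - acc_B) / acc_B``: how far model A's accuracy
    deviates from reference model B's, as a percentage of the reference.  The
    diagonal is inapplicable (NaN).  Requires strictly positive accuracies.
    """
    names = list(accuracies)
    for name, acc in accuracies.items():
        if not acc > 0:
            raise ValueError(f"reference accuracy must be > 0 ({name}: {acc})")
    mat = np.full((len(names), len(names)), np.nan)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i != j:
                mat[i, j] = 100.0 * (accuracies[a] - accuracies[b]) / accuracies[b]
    return pd.DataFrame(mat, index=names, columns=names)


def run_benchmark(regime: str = "table3",
                  models: Iterable[str] = MODEL_NAMES,
                  n_per_class: int = 1000,
                  seeds: Sequence[int] | None = None,
                  mapping: str = "unit",
                  window_steps: int = DEFAULT_WINDOW_STEPS,
                  ) -> tuple[EvaluationReport, pd.DataFrame]:
    """Run the full spike-classification benchmark.

    For every requested model and every seed, a fresh dataset is generated,
    classified via :func:`classify_dataset`, and scored; per-model accuracies
    are the means over seeds.  Returns the report and the pairwise
    performance-loss matrix computed from the mean accuracies.
    """
    if seeds is None:
        seeds = tuple(range(DEFAULT_N_SEEDS))
    seeds = tuple(int(s) for s in seeds)
    if not seeds:
        raise ValueError("seeds must be nonempty")
    model_names = list(models)
    accuracy: dict[str, float] = {}
    error: dict[str, float] = {}
    spike_totals: dict[str, int] = {}
    for name in model_names:
        model = make_model(name, params_source=regime)
        accs = []
        spikes = 0
        for seed in seeds:
            dataset = generate_dataset(n_per_class, seed)
            predictions, counts = classify_dataset(
                model, dataset, mapping=mapping, window_steps=window_steps,
                weight_seed=seed, return_counts=True)
            acc, _ = accuracy_error(predictions, dataset.labels)
            accs.append(acc)
            spikes += int(np.sum(counts))
        accuracy[model.name] = float(np.mean(accs))
        error[model.name] = 100.0 - accuracy[model.name]
        spike_totals[model.name] = spikes
    loss = performance_loss_matrix(accuracy)
    report = EvaluationReport(
        accuracy=accuracy, error=error, spike_totals=spike_totals, seeds=seeds,
        config_snapshot={"regime": regime, "n_per_class": n_per_class,
                         "mapping": mapping, "window_steps": window_steps,
                         "models": list(accuracy)})
    return report, loss
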
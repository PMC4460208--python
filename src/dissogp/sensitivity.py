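"""Input-importance analysis of trained perceptrons.

A trained network's sensitivity to input i is the mean absolute partial
derivative of its output with respect to that input over the dataset
(exact Jacobians, not finite differences), normalized so the scores sum to
one.  An ensemble variant averages normalized scores across several trained
networks — the "collective" reading that makes the ranking robust to any
single run's idiosyncrasies.  Feature selection keeps the inputs whose mean
score clears a threshold; in the study design this reduces (d, L, t) to
(d, t), discarding extrudate length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ann import MLPModel

__all__ = ["SensitivityReport", "input_sensitivity", "collective_sensitivity",
           "reduce_inputs", "ReductionError"]


class ReductionError(ValueError):
    """Threshold would discard every input."""


def input_sensitivity(model: MLPModel, X) -> np.ndarray:
    """Normalized mean |d(output)/d(input_i)| over the records of X.

    Returns a vector of nonnegative scores summing to one (all-zero if the
    network is constant).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    J = model.input_jacobian(X)
    raw = np.mean(np.abs(J), axis=0)
    total = raw.sum()
    return raw / total if total > 0 else raw


@dataclass
class SensitivityReport:
    """Ensemble-mean scores with the descending importance ranking."""

    input_names: tuple
    mean_scores: np.ndarray
    ranking: tuple  # input indices, most important first

    def ranked_names(self) -> tuple:
        return tuple(self.input_names[i] for i in self.ranking)

    def to_dict(self) -> dict:
        return {
            "inputs": list(self.input_names),
            "mean_scores": [float(s) for s in self.mean_scores],
            "ranking": [self.input_names[i] for i in self.ranking],
        }


def collective_sensitivity(models, X, input_names=None) -> SensitivityReport:
    """Mean of per-model normalized scores across an ensemble.

    The ranking is by descending mean score with ties broken by input
    order; it is invariant to the order of the model list.
    """
    models = list(models)
    if not models:
        raise ValueError("need at least one model")
    arities = {m.n_inputs for m in models}
    if len(arities) != 1:
        raise ValueError(f"models disagree on input arity: {sorted(arities)}")
    scores = np.mean([input_sensitivity(m, X) for m in models], axis=0)
    if input_names is None:
        input_names = tuple(f"x{i}" for i in range(len(scores)))
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    return SensitivityReport(tuple(input_names), scores, tuple(order))


def reduce_inputs(report: SensitivityReport, threshold: float = 0.05) -> tuple:
    """Names of inputs whose mean score >= threshold, in input order."""
    keep = tuple(name for name, s in zip(report.input_names, report.mean_scores)
                 if s >= threshold)
    if not keep:
        raise ReductionError(
            f"threshold {threshold} discards every input "
            f"(scores {[float(s) for s in report.mean_scores]})"
        )
    return keep
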
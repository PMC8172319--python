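"""Joint multitask objective: weighted MSE (age) + BCE (gender, diagnosis).

The objective is

    L = w1 * MSE(age) + w2 * BCE(gender) + w3 * BCE(diagnosis)

with every term a batch mean.  Probabilities are clamped to
``[eps, 1 - eps]`` (eps = 1e-7) before the logarithm.  The L2 kernel penalty
is *not* part of this function; the training loop adds it to the gradient
directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPS = 1e-7
TASKS = ("age", "gender", "diagnosis")


@dataclass(frozen=True)
class LossWeights:
    """Per-task weights (w1 age, w2 gender, w3 diagnosis); untuned default 1."""

    age: float = 1.0
    gender: float = 1.0
    diagnosis: float = 1.0

    def __post_init__(self):
        vals = (self.age, self.gender, self.diagnosis)
        if any(v < 0 for v in vals):
            raise ValueError("loss weights must be nonnegative")
        if all(v == 0 for v in vals):
            raise ValueError("at least one loss weight must be positive")

    def as_dict(self) -> dict[str, float]:
        return {"age": self.age, "gender": self.gender, "diagnosis": self.diagnosis}


def _validate(targets, preds):
    out_t, out_p = {}, {}
    for task in TASKS:
        t = np.asarray(targets[task], dtype=np.float64).ravel()
        p = np.asarray(preds[task], dtype=np.float64).ravel()
        if t.size == 0:
            raise ValueError("empty batch")
        if t.shape != p.shape:
            raise ValueError(f"target/prediction shape mismatch for task {task!r}")
        if not (np.isfinite(t).all() and np.isfinite(p).all()):
            raise ValueError(f"non-finite values in task {task!r}")
        out_t[task], out_p[task] = t, p
    return out_t, out_p


def bce(labels: np.ndarray, probs: np.ndarray) -> float:
    """Binary cross-entropy (batch mean), probabilities clamped at 1e-7."""
    p = np.clip(probs, EPS, 1.0 - EPS)
    return float(-np.mean(labels * np.log(p) + (1.0 - labels) * np.log(1.0 - p)))


def task_losses(targets: dict, preds: dict) -> dict[str, float]:
    """Unweighted per-task losses: MSE for age, BCE for gender/diagnosis."""
    t, p = _validate(targets, preds)
    return {
        "age": float(np.mean((t["age"] - p["age"]) ** 2)),
        "gender": bce(t["gender"], p["gender"]),
        "diagnosis": bce(t["diagnosis"], p["diagnosis"]),
    }


def objective_loss(targets: dict, preds: dict, weights: LossWeights = LossWeights()) -> float:
    """Weighted sum of the three task losses (each a batch mean)."""
    per_task = task_losses(targets, preds)
    w = weights.as_dict()
    return float(sum(w[k] * per_task[k] for k in TASKS))


def objective_gradients(targets: dict, preds: dict,
                        weights: LossWeights = LossWeights()) -> dict[str, np.ndarray]:
    """Analytic gradient of :func:`objective_loss` w.r.t. each prediction array.

    For age: d/dp mean((t-p)^2) = 2 (p - t) / n.
    For the classification tasks: d/dp BCE = (p - t) / (p (1 - p) n) on the
    clamped probability (zero where clamping is active, matching the
    piecewise-constant clamp).
    """
    t, p = _validate(targets, preds)
    n = t["age"].size
    w = weights.as_dict()
    grads = {"age": w["age"] * 2.0 * (p["age"] - t["age"]) / n}
    for task in ("gender", "diagnosis"):
        pc = np.clip(p[task], EPS, 1.0 - EPS)
        g = (pc - t[task]) / (pc * (1.0 - pc) * n)
        g = np.where((p[task] > EPS) & (p[task] < 1.0 - EPS), g, 0.0)
        grads[task] = w[task] * g
    return grads
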
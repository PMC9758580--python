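"""Reinforcement-learning replay scheduler (the hippocampus-like side network).

A linear value network with one input per class and a single output learns,
through trial and error, which class is most valuable to replay.  After
each replayed batch the main classifier is re-evaluated on the validation
split and the scheduler receives as reward the *reduction* of a chi-square
gap — the Pearson distance between perfect per-class prediction and the
observed per-class correct counts.  Class values are turned into selection
probabilities through a softmax, so classes whose replay keeps paying off
are chosen more often.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import LayeredClassifier, OptimizerConfig, truncate_at, activations_at
from .replay import ActivationDistribution, sample_distribution

__all__ = [
    "SchedulerState",
    "RewardRecord",
    "chi_square_gap",
    "softmax_probabilities",
    "select_class",
    "update_scheduler",
    "initialize_values",
    "rl_replay_night",
]


def chi_square_gap(per_class_correct, per_class_total, pooled: bool = False) -> float:
    """Pearson chi-square between perfect and observed correct counts.

    With expected counts equal to the per-class totals (all-correct), the
    statistic is ``sum_c (total_c - correct_c)^2 / total_c``; it is zero iff
    classification is perfect.  ``pooled=True`` collapses all classes into a
    single cell before computing the same quantity.
    """
    correct = np.asarray(per_class_correct, dtype=np.float64)
    total = np.asarray(per_class_total, dtype=np.float64)
    if correct.shape != total.shape:
        raise ValueError("correct and total must have equal length")
    if np.any(total <= 0):
        raise ValueError("every per-class total must be positive")
    if np.any(correct < 0) or np.any(correct > total):
        raise ValueError("correct counts must lie in [0, total]")
    if pooled:
        return float((total.sum() - correct.sum()) ** 2 / total.sum())
    return float(np.sum((total - correct) ** 2 / total))


@dataclass
class RewardRecord:
    chi2_before: float
    chi2_after: float

    @property
    def reward(self) -> float:
        return self.chi2_before - self.chi2_after


@dataclass
class SchedulerState:
    """Value weights of the side network plus its (persistent) Adam state."""

    n_classes: int
    side_lr: float = 1e-3
    side_epochs: int = 50
    temperature: float = 1.0
    class_values: np.ndarray = field(default=None)  # type: ignore[assignment]
    selection_log: list[tuple[int, int, float]] = field(default_factory=list)
    initialized: bool = False
    # Adam moments, one slot per class weight; step counts are per class
    # because each update touches only the chosen class's weight.
    _m: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _v: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _t: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.class_values is None:
            self.class_values = np.zeros(self.n_classes, dtype=np.float64)
        if self._m is None:
            self._m = np.zeros(self.n_classes)
            self._v = np.zeros(self.n_classes)
            self._t = np.zeros(self.n_classes, dtype=np.int64)

    def probabilities(self) -> np.ndarray:
        return softmax_probabilities(self.class_values, self.temperature)

    def to_json_dict(self) -> dict:
        return {
            "n_classes": self.n_classes,
            "side_lr": self.side_lr,
            "side_epochs": self.side_epochs,
            "temperature": self.temperature,
            "initialized": self.initialized,
            "class_values": self.class_values.tolist(),
            "selection_log": [[int(s), int(c), float(r)] for s, c, r in self.selection_log],
        }

    @staticmethod
    def from_json_dict(blob: dict) -> "SchedulerState":
        state = SchedulerState(
            n_classes=int(blob["n_classes"]), side_lr=float(blob["side_lr"]),
            side_epochs=int(blob["side_epochs"]),
            temperature=float(blob["temperature"]),
            class_values=np.asarray(blob["class_values"], dtype=np.float64),
            selection_log=[(int(s), int(c), float(r))
                           for s, c, r in blob["selection_log"]],
            initialized=bool(blob["initialized"]))
        return state


def softmax_probabilities(values: np.ndarray, temperature: float = 1.0) -> np.ndarray:
    z = np.asarray(values, dtype=np.float64) / temperature
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def select_class(state: SchedulerState, rng: np.random.Generator) -> int:
    """Draw a class from the softmax over current values."""
    if not state.initialized:
        raise RuntimeError("scheduler state is not initialized")
    return int(rng.choice(state.n_classes, p=state.probabilities()))


def update_scheduler(state: SchedulerState, chosen: int, reward: float) -> SchedulerState:
    """Fit the side network to the latest (one-hot(chosen) -> reward) pair.

    ``side_epochs`` full-batch Adam steps on the squared error
    ``(value[chosen] - reward)^2``.  With a one-hot input and no bias term,
    only the chosen class's weight receives gradient; other values are
    untouched.  The state is updated in place and returned.
    """
    if not 0 <= chosen < state.n_classes:
        raise ValueError(f"invalid class id {chosen}")
    if not np.isfinite(reward):
        raise ValueError("reward must be finite")
    lr, b1, b2, eps = state.side_lr, 0.9, 0.999, 1e-7
    for _ in range(state.side_epochs):
        g = 2.0 * (state.class_values[chosen] - reward)
        state._t[chosen] += 1
        t = state._t[chosen]
        state._m[chosen] = b1 * state._m[chosen] + (1 - b1) * g
        state._v[chosen] = b2 * state._v[chosen] + (1 - b2) * g * g
        mhat = state._m[chosen] / (1 - b1 ** t)
        vhat = state._v[chosen] / (1 - b2 ** t)
        state.class_values[chosen] -= lr * mhat / (np.sqrt(vhat) + eps)
    state.selection_log.append((len(state.selection_log), int(chosen), float(reward)))
    return state


# ---------------------------------------------------------------------------
# Interaction with the main network
# ---------------------------------------------------------------------------


def _val_counts_via_head(head, val_acts: np.ndarray, val_labels: np.ndarray,
                         n_classes: int) -> tuple[np.ndarray, np.ndarray]:
    preds = head.predict(val_acts)
    total = np.bincount(val_labels, minlength=n_classes)
    correct = np.bincount(val_labels[preds == val_labels], minlength=n_classes)
    return correct, total


def initialize_values(model: LayeredClassifier, distributions: dict[int, ActivationDistribution],
                      data, state: SchedulerState, cut_point: str,
                      opt: OptimizerConfig, rng: np.random.Generator,
                      head=None, batch_size: int = 36) -> SchedulerState:
    """Seed each class's value by replaying one batch of it and measuring reward.

    For each class in turn, one generative batch is replayed through the
    truncated network and the change in the validation chi-square gap sets
    that class's initial value.  The replays do train the main network.
    """
    missing = [c for c in range(state.n_classes) if c not in distributions]
    if missing:
        raise ValueError(f"missing replay distributions for classes {missing}")
    if head is None:
        head = truncate_at(model, cut_point)
    Xv, yv = data.arrays("val")
    val_acts = activations_at(model, cut_point, Xv, channel_means=data.channel_means)
    for c in range(state.n_classes):
        correct, total = _val_counts_via_head(head, val_acts, yv, state.n_classes)
        before = chi_square_gap(correct, total)
        batch = sample_distribution(distributions[c], batch_size, rng)
        head.train_epoch(batch.arrays, batch.labels, opt, rng)
        correct, total = _val_counts_via_head(head, val_acts, yv, state.n_classes)
        after = chi_square_gap(correct, total)
        state.class_values[c] = before - after
    state.initialized = True
    return state


def rl_replay_night(model: LayeredClassifier, state: SchedulerState,
                    distributions: dict[int, ActivationDistribution], data,
                    n_steps: int, opt: OptimizerConfig, rng: np.random.Generator,
                    cut_point: str, batch_size: int = 36, head=None) -> np.ndarray:
    """One night of scheduler-driven replay; returns per-class selection counts.

    Each step: select a class from the softmax, sample one generative batch
    of ``batch_size`` for it, replay it through the truncated network,
    re-evaluate the validation split, reward the scheduler with the
    chi-square reduction, and update the side network.  Validation
    activations at the cut are computed once per night (upstream weights are
    frozen during the night by construction).  Passing the same ``head``
    night after night keeps its optimizer state, as regular training does
    across epochs; scheduled replay then becomes gentler as training
    progresses.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not state.initialized:
        raise RuntimeError("scheduler state must be initialized first")
    if head is None:
        head = truncate_at(model, cut_point)
    Xv, yv = data.arrays("val")
    val_acts = activations_at(model, cut_point, Xv, channel_means=data.channel_means)
    counts = np.zeros(state.n_classes, dtype=np.int64)
    correct, total = _val_counts_via_head(head, val_acts, yv, state.n_classes)
    chi2 = chi_square_gap(correct, total)
    for _ in range(n_steps):
        c = select_class(state, rng)
        counts[c] += 1
        batch = sample_distribution(distributions[c], batch_size, rng)
        head.train_epoch(batch.arrays, batch.labels, opt, rng)
        correct, total = _val_counts_via_head(head, val_acts, yv, state.n_classes)
        chi2_after = chi_square_gap(correct, total)
        update_scheduler(state, c, chi2 - chi2_after)
        chi2 = chi2_after
    return counts
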
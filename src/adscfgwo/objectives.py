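"""Objective functions: analytic benchmarks and classifier-tuning fitness.

The optimizer is validated on standard closed-form landscapes (sphere,
Rastrigin, Rosenbrock) and exercised end-to-end on a classifier-tuning
objective: decode a unit-cube position into training options, train a
small model on the 70% training split, and return ``1 - accuracy`` on
the 20% validation split (minimization).  Evaluations are cached by the
decoded configuration, so revisiting a grid point costs nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .phantoms import ImageDataset
from .space import SearchSpace
from .trainers import TrainerContract, train_and_score

__all__ = [
    "benchmark_objective",
    "DatasetSplit",
    "make_split",
    "classifier_fitness",
    "ClassifierObjective",
]


def benchmark_objective(name: str, dim: int):
    """Standard test landscape with global minimum 0 (sphere/rastrigin/rosenbrock)."""
    if dim < 1:
        raise ValueError("dim must be >= 1")

    if name == "sphere":

        def f(x: np.ndarray) -> float:
            x = np.asarray(x, dtype=float)
            return float(np.sum(x * x))

    elif name == "rastrigin":

        def f(x: np.ndarray) -> float:
            x = np.asarray(x, dtype=float)
            return float(10.0 * len(x) + np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x)))

    elif name == "rosenbrock":

        def f(x: np.ndarray) -> float:
            x = np.asarray(x, dtype=float)
            return float(
                np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2)
            )

    else:
        raise ValueError(f"unknown benchmark objective {name!r}")
    f.__name__ = name
    return f


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test index sets over a labeled image set."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    fractions: tuple[float, float, float]
    seed: int

    def __post_init__(self) -> None:
        all_idx = np.concatenate([self.train, self.validation, self.test])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("split index sets must be disjoint")


def make_split(
    n_items: int,
    fractions: tuple[float, float, float] = (0.70, 0.20, 0.10),
    seed: int = 0,
) -> DatasetSplit:
    """Seeded shuffle then contiguous 70/20/10 partition (sizes rounded to sum to n)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if n_items < 10:
        raise ValueError("need at least 10 items to split")
    # distinct seed stream: a dataset generated from the same integer seed
    # must not share its permutation with the split
    order = np.random.default_rng(np.random.SeedSequence([seed, 0x517]))  # noqa: E501
    order = order.permutation(n_items)
    n_train = int(np.floor(fractions[0] * n_items + 0.5))
    n_val = int(np.floor(fractions[1] * n_items + 0.5))
    n_val = min(n_val, n_items - n_train)
    return DatasetSplit(
        train=order[:n_train],
        validation=order[n_train : n_train + n_val],
        test=order[n_train + n_val :],
        fractions=fractions,
        seed=seed,
    )


def classifier_fitness(
    u: np.ndarray,
    space: SearchSpace,
    data: ImageDataset,
    split: DatasetSplit,
    trainer: TrainerContract,
    cache: dict | None = None,
) -> float:
    """Validation error of the contracted trainer under the decoded configuration.

    Returns ``1 - validation_accuracy`` in [0, 1].  A diverging trainer
    (non-finite loss/weights) yields the worst fitness 1.0 with a warning
    instead of raising, so population updates stay total.
    """
    cfg = space.decode(np.asarray(u, dtype=float))
    key = space.to_json(cfg)
    if cache is not None and key in cache:
        return cache[key]
    try:
        acc = train_and_score(
            cfg,
            data.images[split.train],
            data.labels[split.train],
            data.images[split.validation],
            data.labels[split.validation],
            trainer,
        )
        value = 1.0 - acc
    except FloatingPointError:
        warnings.warn("trainer diverged; assigning worst fitness", RuntimeWarning)
        value = 1.0
    if cache is not None:
        cache[key] = value
    return value


@dataclass
class ClassifierObjective:
    """Callable objective over the unit cube with a built-in evaluation cache.

    Records every evaluation (decoded config JSON + fitness) for export.
    """

    space: SearchSpace
    data: ImageDataset
    split: DatasetSplit
    trainer: TrainerContract
    cache: dict = field(default_factory=dict)
    log: list = field(default_factory=list)

    def __call__(self, u: np.ndarray) -> float:
        value = classifier_fitness(u, self.space, self.data, self.split, self.trainer, self.cache)
        self.log.append((len(self.log), self.space.to_json(self.space.decode(u)), value))
        return value

    def test_accuracy(self, u: np.ndarray) -> float:
        """Held-out test accuracy of the configuration decoded from ``u``."""
        cfg = self.space.decode(np.asarray(u, dtype=float))
        return train_and_score(
            cfg,
            self.data.images[self.split.train],
            self.data.labels[self.split.train],
            self.data.images[self.split.test],
            self.data.labels[self.split.test],
            self.trainer,
        )
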
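"""Typed hyperparameter search spaces and unit-cube decoding.

The optimizer works in a continuous cube; this module declares the
hyperparameter axes of a CNN training run (learning rate, batch size,
momentum, ...) and maps positions in ``[0, 1]^d`` to concrete, valid
training options.  Four axis kinds are supported:

* ``continuous`` — affine map onto ``[lo, hi]``;
* ``log_continuous`` — affine map in log10 space (for rates spanning
  decades);
* ``integer`` — stratified floor map hitting each integer in ``[lo, hi]``
  with equal measure;
* ``categorical`` — equal-width bins over an ordered choice list.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

__all__ = [
    "HyperparamSpec",
    "SearchSpace",
    "decode",
    "default_cnn_space",
    "validate_config",
]

DecodedConfig = dict[str, Any]

_KINDS = ("continuous", "log_continuous", "integer", "categorical")


@dataclass
class HyperparamSpec:
    """One hyperparameter axis in native units."""

    name: str
    kind: str
    lo: float | None = None
    hi: float | None = None
    choices: Sequence[Any] | None = None
    default: Any = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown axis kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.choices:
                raise ValueError(f"{self.name}: categorical axis needs non-empty choices")
        else:
            if self.lo is None or self.hi is None or not self.lo < self.hi:
                raise ValueError(f"{self.name}: need lo < hi")
            if self.kind == "log_continuous" and self.lo <= 0:
                raise ValueError(f"{self.name}: log axis needs lo > 0")

    def decode_one(self, u: float) -> Any:
        if not 0.0 <= u <= 1.0:
            raise ValueError(f"{self.name}: coordinate {u} outside [0, 1]")
        if self.kind == "continuous":
            return self.lo + u * (self.hi - self.lo)
        if self.kind == "log_continuous":
            lg = math.log10(self.lo) + u * (math.log10(self.hi) - math.log10(self.lo))
            return 10.0 ** lg
        if self.kind == "integer":
            lo, hi = int(self.lo), int(self.hi)
            return int(min(max(math.floor(lo + u * (hi - lo + 1)), lo), hi))
        k = len(self.choices)
        return self.choices[min(math.floor(u * k), k - 1)]

    def encode_one(self, value: Any) -> float:
        """Unit-cube coordinate whose decode recovers ``value`` (grid points)."""
        if self.kind == "continuous":
            return (value - self.lo) / (self.hi - self.lo)
        if self.kind == "log_continuous":
            return (math.log10(value) - math.log10(self.lo)) / (
                math.log10(self.hi) - math.log10(self.lo)
            )
        if self.kind == "integer":
            lo, hi = int(self.lo), int(self.hi)
            return (value - lo + 0.5) / (hi - lo + 1)
        idx = list(self.choices).index(value)
        return (idx + 0.5) / len(self.choices)

    def contains(self, value: Any) -> bool:
        if self.kind == "categorical":
            return value in list(self.choices)
        if self.kind == "integer":
            return float(value) == int(value) and self.lo <= value <= self.hi
        return self.lo <= value <= self.hi


@dataclass
class SearchSpace:
    """An ordered collection of hyperparameter axes plus fixed options.

    ``constants`` carries non-tunable training options (shuffle mode,
    schedule type, ...) that are merged verbatim into every decoded
    configuration.
    """

    specs: list[HyperparamSpec]
    constants: DecodedConfig = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate hyperparameter names")

    @property
    def dim(self) -> int:
        return len(self.specs)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def decode(self, u: np.ndarray) -> DecodedConfig:
        return decode(u, self)

    def default_position(self) -> np.ndarray:
        """Unit-cube point decoding to every axis's default value."""
        return np.array([s.encode_one(s.default) for s in self.specs])

    def to_json(self, cfg: DecodedConfig) -> str:
        return json.dumps(cfg, sort_keys=True)


def decode(u: np.ndarray, space: SearchSpace) -> DecodedConfig:
    """Map a unit-cube position to a concrete hyperparameter configuration."""
    u = np.asarray(u, dtype=float)
    if u.shape != (space.dim,):
        raise ValueError(f"expected a vector of length {space.dim}, got shape {u.shape}")
    cfg = {spec.name: spec.decode_one(float(ui)) for spec, ui in zip(space.specs, u)}
    cfg.update(space.constants)
    return cfg


def default_cnn_space() -> SearchSpace:
    """Tunable CNN training options with their published default values.

    The seven numeric training knobs are searchable; environment and
    reporting options (shuffle, schedule type, gradient threshold method)
    are carried as constants.  Bounds are centered on the defaults and can
    be overridden in experiment configs.
    """
    specs = [
        HyperparamSpec("InitialLearnRate", "log_continuous", 1e-5, 1e-1, default=1e-4),
        HyperparamSpec("MiniBatchSize", "categorical", choices=(4, 8, 16, 32), default=8),
        HyperparamSpec("MaxEpochs", "integer", 5, 30, default=20),
        HyperparamSpec("Momentum", "continuous", 0.5, 0.99, default=0.9),
        HyperparamSpec("L2Regularization", "log_continuous", 1e-6, 1e-2, default=1e-4),
        HyperparamSpec("RateDropFactor", "continuous", 0.05, 0.5, default=0.1),
        HyperparamSpec("LearnRateDropPeriod", "integer", 2, 20, default=10),
    ]
    constants = {
        "Shuffle": "every-epoch",
        "LearnRateSchedule": "piecewise",
        "GradientThresholdMethod": "l2norm",
        "GradientThreshold": math.inf,
        "ValidationPatience": math.inf,
    }
    return SearchSpace(specs=specs, constants=constants)


def validate_config(cfg: DecodedConfig, space: SearchSpace) -> tuple[bool, list[str]]:
    """Check a decoded configuration against its space.

    Returns ``(ok, violations)``; unknown names and missing axes are
    reported as violations rather than raised.
    """
    violations: list[str] = []
    known = {s.name: s for s in space.specs}
    for name, spec in known.items():
        if name not in cfg:
            violations.append(f"{name}: missing")
        elif not spec.contains(cfg[name]):
            violations.append(f"{name}: value {cfg[name]!r} outside spec")
    for name in cfg:
        if name not in known and name not in space.constants:
            violations.append(f"{name}: unknown hyperparameter")
    return (not violations, violations)
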
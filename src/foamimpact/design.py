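"""Factorial design of the falling-weight impact study.

The experiment drops a rigid impactor of fixed mass from a set of heights
onto foam specimens built from 1-3 stacked layers.  Each specimen is struck
several times in a row so that degradation under repeated loading can be
quantified.  Two blocks exist:

* a *standard* block: every (height, layer-count) cell gets
  ``specimens_per_condition`` fresh specimens, each struck
  ``repetitions_standard`` times;
* an *extra* block at a single drop height (0.50 m by default):
  ``extra_specimens_50cm`` additional fresh specimens per layer count,
  each struck ``repetitions_extra`` times, feeding the repeated-loading
  statistics.

With the defaults this yields 36 specimens and 126 individual tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

__all__ = [
    "StudyConfig",
    "TestCondition",
    "Design",
    "enumerate_design",
    "impact_velocity",
    "impact_energy",
]


@dataclass(frozen=True)
class StudyConfig:
    """Physical constants and factorial grid of the drop-test study.

    All quantities are SI: kg, m, s, N, J.
    """

    impactor_mass: float = 8.0
    gravity: float = 9.81
    drop_heights: tuple[float, ...] = (0.15, 0.25, 0.50)
    layer_counts: tuple[int, ...] = (1, 2, 3)
    layer_thickness: float = 0.018
    specimen_diameter: float = 0.074
    specimens_per_condition: int = 3
    repetitions_standard: int = 3
    extra_specimens_50cm: int = 3
    repetitions_extra: int = 5
    extra_drop_height: float = 0.50
    significance_level: float = 0.05
    force_threshold: float = 10000.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "drop_heights", tuple(self.drop_heights))
        object.__setattr__(self, "layer_counts", tuple(int(n) for n in self.layer_counts))
        if self.impactor_mass <= 0:
            raise ValueError("impactor_mass must be > 0")
        if self.gravity <= 0:
            raise ValueError("gravity must be > 0")
        if self.layer_thickness <= 0:
            raise ValueError("layer_thickness must be > 0")
        if self.specimen_diameter <= 0:
            raise ValueError("specimen_diameter must be > 0")
        if any(h <= 0 for h in self.drop_heights):
            raise ValueError("drop_heights must be strictly positive")
        if any(n <= 0 for n in self.layer_counts):
            raise ValueError("layer_counts must be positive integers")
        if len(set(self.layer_counts)) != len(self.layer_counts):
            raise ValueError("layer_counts must be distinct")
        if self.repetitions_standard < 1 or self.repetitions_extra < 1:
            raise ValueError("repetition counts must be >= 1")
        if self.specimens_per_condition < 0 or self.extra_specimens_50cm < 0:
            raise ValueError("specimen counts must be >= 0")
        if not (0 < self.significance_level < 1):
            raise ValueError("significance_level must be in (0, 1)")

    def specimen_thickness(self, n_layers: int) -> float:
        """Nominal stack thickness in metres."""
        return n_layers * self.layer_thickness

    def to_dict(self) -> dict:
        d = asdict(self)
        d["drop_heights"] = list(self.drop_heights)
        d["layer_counts"] = list(self.layer_counts)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class TestCondition:
    """One individual drop: which specimen, from which height, which strike."""

    drop_height: float
    n_layers: int
    specimen_id: str
    repetition: int

    def __post_init__(self) -> None:
        if self.repetition < 1:
            raise ValueError("repetition is 1-based and must be >= 1")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.drop_height < 0:
            raise ValueError("drop_height must be >= 0")


@dataclass(frozen=True)
class Design:
    """Enumerated test grid plus its size summary."""

    conditions: tuple[TestCondition, ...]
    n_specimens: int

    @property
    def n_tests(self) -> int:
        return len(self.conditions)


def _specimen_label(height: float, n_layers: int, index: int, extra: bool) -> str:
    # deterministic, human-readable; 'X' marks the extra repeated-loading block
    tag = "X" if extra else "S"
    return f"h{round(height * 100):02d}_L{n_layers}_{tag}{index}"


def enumerate_design(config: StudyConfig) -> Design:
    """Enumerate every individual test of the study, in a stable order.

    Standard block: |heights| x |layers| x specimens x repetitions_standard.
    Extra block: |layers| x extra specimens x repetitions_extra, at
    ``extra_drop_height`` only (and only if that height is part of the grid).
    """
    conditions: list[TestCondition] = []
    specimens: set[str] = set()
    for height in config.drop_heights:
        for n_layers in config.layer_counts:
            for s in range(1, config.specimens_per_condition + 1):
                sid = _specimen_label(height, n_layers, s, extra=False)
                specimens.add(sid)
                for rep in range(1, config.repetitions_standard + 1):
                    conditions.append(
                        TestCondition(height, n_layers, sid, rep)
                    )
    if config.extra_drop_height in config.drop_heights:
        height = config.extra_drop_height
        for n_layers in config.layer_counts:
            for s in range(1, config.extra_specimens_50cm + 1):
                sid = _specimen_label(height, n_layers, s, extra=True)
                specimens.add(sid)
                for rep in range(1, config.repetitions_extra + 1):
                    conditions.append(
                        TestCondition(height, n_layers, sid, rep)
                    )
    return Design(conditions=tuple(conditions), n_specimens=len(specimens))


def impact_velocity(drop_height: float, gravity: float = 9.81) -> float:
    """Free-fall contact speed sqrt(2 g h) in m/s."""
    if drop_height < 0:
        raise ValueError("drop_height must be >= 0")
    if gravity <= 0:
        raise ValueError("gravity must be > 0")
    return math.sqrt(2.0 * gravity * drop_height)


def impact_energy(mass: float, drop_height: float, gravity: float = 9.81) -> float:
    """Gravitational potential energy m g h (J) released by the drop."""
    if mass <= 0:
        raise ValueError("mass must be > 0")
    if drop_height < 0:
        raise ValueError("drop_height must be >= 0")
    return mass * gravity * drop_height
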
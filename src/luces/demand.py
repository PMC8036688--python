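"""Markov land-demand projection.

The quantitative side of scenario simulation: estimate a 6×6 class
transition matrix from two land-use snapshots, project per-class cell
demand forward, and adjust the projection for policy scenarios by
enforcing protection floors (cultivated land, or woodland + water) paid
for out of built-land growth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ArgumentError, ConfigError
from .grids import CLASS_CODES, CLASS_NAMES, N_CLASSES, LandUseMap


@dataclass
class TransitionMatrix:
    """Row-stochastic class-transition probabilities over ``period`` years."""

    probs: np.ndarray
    period: float = 10.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (N_CLASSES, N_CLASSES):
            raise ArgumentError("transition matrix must be 6×6")
        if (self.probs < 0).any() or (self.probs > 1).any():
            raise ArgumentError("transition probabilities must lie in [0, 1]")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ArgumentError("transition-matrix rows must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        names = [CLASS_NAMES[c] for c in range(1, N_CLASSES + 1)]
        return pd.DataFrame(self.probs, index=names, columns=names)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, period: float = 10.0) -> "TransitionMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), period)


@dataclass
class DemandVector:
    """Per-class target cell counts at the horizon date (codes 1..6)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (N_CLASSES,):
            raise ArgumentError("demand vector must have 6 entries")
        if (self.counts < 0).any():
            raise ArgumentError("demand counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_series(self) -> pd.Series:
        return pd.Series(
            self.counts, index=[CLASS_NAMES[c] for c in range(1, N_CLASSES + 1)]
        )


def estimate_transition(
    map_t0: LandUseMap, map_t1: LandUseMap, period: float = 10.0
) -> TransitionMatrix:
    """Row-normalized cross-tabulation of classes at two dates.

    Rows with no source cells become identity rows (a class absent at t0
    is assumed to persist).
    """
    if map_t0.shape != map_t1.shape:
        raise ArgumentError("snapshots must share a shape")
    if not np.array_equal(map_t0.active, map_t1.active):
        raise ArgumentError("snapshots must share a nodata pattern")
    act = map_t0.active
    a = map_t0.classes[act].astype(np.int64) - 1
    b = map_t1.classes[act].astype(np.int64) - 1
    counts = np.zeros((N_CLASSES, N_CLASSES))
    np.add.at(counts, (a, b), 1.0)
    rowsum = counts.sum(axis=1)
    probs = np.eye(N_CLASSES)
    nz = rowsum > 0
    probs[nz] = counts[nz] / rowsum[nz, None]
    return TransitionMatrix(probs, period)


def _largest_remainder_round(x: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative reals to integers conserving ``total`` exactly."""
    floors = np.floor(x).astype(np.int64)
    deficit = int(total - floors.sum())
    if deficit > 0:
        order = np.argsort(-(x - floors), kind="stable")
        floors[order[:deficit]] += 1
    return floors


def project_demand(
    tm: TransitionMatrix, counts_t1: np.ndarray, steps: int = 1
) -> DemandVector:
    """Project class counts ``steps`` transitions ahead.

    counts = counts_t1 · Pˢ, rounded by largest remainder so the total
    cell count is conserved exactly.
    """
    if steps < 1:
        raise ArgumentError("steps must be ≥ 1")
    counts_t1 = np.asarray(counts_t1, dtype=float)
    if counts_t1.shape != (N_CLASSES,):
        raise ArgumentError("counts_t1 must have 6 entries")
    if (counts_t1 < 0).any():
        raise ArgumentError("counts must be non-negative")
    raw = counts_t1 @ np.linalg.matrix_power(tm.probs, steps)
    return DemandVector(_largest_remainder_round(raw, int(round(counts_t1.sum()))))


def apply_scenario_demand(
    dv: DemandVector,
    scenario: str,
    counts_t1: np.ndarray,
    rules: dict | None = None,
) -> DemandVector:
    """Adjust a Markov demand vector for a policy scenario.

    ``natural_evolution`` leaves the projection unchanged.
    ``cultivated_protection`` floors cultivated demand at its current
    (t1) count; ``ecological_protection`` floors woodland and water
    likewise.  Any shortfall against a floor is added to that class and
    removed from built-land demand, so the total is conserved — the
    arithmetic expression of protection policies damping built-land
    growth.  ``rules`` may override the per-class floors:
    ``{"floors": {"cultivated": 1234, ...}}``.
    """
    counts_t1 = np.asarray(counts_t1, dtype=float)
    floors = np.zeros(N_CLASSES)
    if scenario == "natural_evolution":
        pass
    elif scenario == "cultivated_protection":
        floors[CLASS_CODES["cultivated"] - 1] = counts_t1[CLASS_CODES["cultivated"] - 1]
    elif scenario == "ecological_protection":
        floors[CLASS_CODES["woodland"] - 1] = counts_t1[CLASS_CODES["woodland"] - 1]
        floors[CLASS_CODES["water"] - 1] = counts_t1[CLASS_CODES["water"] - 1]
    else:
        raise ArgumentError(f"unknown scenario {scenario!r}")
    if rules and "floors" in rules:
        for name, val in rules["floors"].items():
            if name not in CLASS_CODES:
                raise ConfigError(f"unknown class name in floors: {name!r}")
            floors[CLASS_CODES[name] - 1] = float(val)
    if floors.sum() > dv.total:
        raise ConfigError("scenario floors exceed the total cell count")

    counts = dv.counts.astype(np.int64).copy()
    deficit = np.maximum(np.ceil(floors).astype(np.int64) - counts, 0)
    need = int(deficit.sum())
    if need == 0:
        return DemandVector(counts)
    built = CLASS_CODES["built"] - 1
    if counts[built] < need:
        raise ConfigError(
            "built-land demand cannot absorb the protection floors "
            f"(need {need}, built demand {counts[built]})"
        )
    counts += deficit
    counts[built] -= need
    return DemandVector(counts)
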
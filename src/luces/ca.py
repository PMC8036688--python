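"""Cellular-automata land allocation with adaptive inertia and roulette
competition.

Each iteration combines, per cell p and candidate class k,

    TProb(p, k) = sp(p, k) · Ω(p, k) · Inertia_k · (1 − sc[c→k])

where sp is the ANN suitability probability, Ω the Moore-neighborhood
effect (share of class-k cells among the 8 neighbors, weighted by ω_k),
Inertia_k a per-class coefficient adapted from the last two demand gaps,
and sc the conversion-cost matrix (sc = 1 forbids a conversion).  Cells
are visited in random order and resolved by roulette-wheel selection;
a change is accepted only while the target class is under demand and
the source class is over demand, so class counts move monotonically
toward the demand vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

import pandas as pd

from .demand import DemandVector
from .exceptions import ArgumentError, SimulationError
from .grids import CLASS_NAMES, CLASSES, N_CLASSES, NODATA, ConstraintMask, LandUseMap
from .suitability import SuitabilityCube

INERTIA_MIN = 1e-3
INERTIA_MAX = 1e3

#: floor applied to the neighborhood factor inside run_simulation so a
#: class with no local presence can still be seeded by roulette
OMEGA_FLOOR = 1e-4


@dataclass
class NeighborhoodWeights:
    """Per-class neighborhood effect weights ω_k ≥ 0."""

    omega: np.ndarray = field(default_factory=lambda: np.ones(N_CLASSES))

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        if self.omega.shape != (N_CLASSES,):
            raise ArgumentError("omega must have 6 entries")
        if (self.omega < 0).any():
            raise ArgumentError("omega weights must be non-negative")


@dataclass
class CostMatrix:
    """Conversion costs sc[c→k] in [0, 1]; zero diagonal; 1 = forbidden."""

    sc: np.ndarray

    def __post_init__(self) -> None:
        self.sc = np.asarray(self.sc, dtype=float)
        if self.sc.shape != (N_CLASSES, N_CLASSES):
            raise ArgumentError("cost matrix must be 6×6")
        if (self.sc < 0).any() or (self.sc > 1).any():
            raise ArgumentError("costs must lie in [0, 1]")
        if not np.allclose(np.diag(self.sc), 0.0):
            raise ArgumentError("staying in a class must cost 0 (zero diagonal)")

    @classmethod
    def uniform(cls, off_diagonal: float = 0.5) -> "CostMatrix":
        sc = np.full((N_CLASSES, N_CLASSES), float(off_diagonal))
        np.fill_diagonal(sc, 0.0)
        return cls(sc)

    def forbid_from(self, classes: list[int]) -> "CostMatrix":
        """Return a copy where conversion *out of* the given classes is forbidden."""
        sc = self.sc.copy()
        for c in classes:
            sc[c - 1, :] = 1.0
            sc[c - 1, c - 1] = 0.0
        return CostMatrix(sc)


@dataclass
class InertiaState:
    """Per-class inertia coefficients and the last two demand gaps.

    Gaps are demand − current count: positive means the class is under
    demand (needs cells), negative over demand.
    """

    inertia: np.ndarray = field(default_factory=lambda: np.ones(N_CLASSES))
    gap_t1: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES))
    gap_t2: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES))

    def __post_init__(self) -> None:
        self.inertia = np.asarray(self.inertia, dtype=float)
        self.gap_t1 = np.asarray(self.gap_t1, dtype=float)
        self.gap_t2 = np.asarray(self.gap_t2, dtype=float)


def update_inertia(state: InertiaState) -> InertiaState:
    """Adapt the inertia coefficients from successive demand gaps.

    Per class: unchanged while the gap is not worsening (|D^{t-1}| ≤
    |D^{t-2}|); a worsening overshoot (both gaps < 0) multiplies by
    D^{t-2}/D^{t-1} < 1; a worsening undershoot (both gaps > 0)
    multiplies by D^{t-1}/D^{t-2} > 1.  Results are clamped to
    [1e-3, 1e3]; a zero previous gap leaves the coefficient unchanged.
    """
    g1, g2 = state.gap_t1, state.gap_t2
    inertia = state.inertia.copy()
    worsening = np.abs(g1) > np.abs(g2)
    both_neg = worsening & (g1 < 0) & (g2 < 0)
    both_pos = worsening & (g1 > 0) & (g2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_neg = np.where(g1 != 0, g2 / g1, 1.0)
        ratio_pos = np.where(g2 != 0, g1 / g2, 1.0)
    inertia[both_neg] *= ratio_neg[both_neg]
    inertia[both_pos] *= ratio_pos[both_pos]
    inertia = np.clip(inertia, INERTIA_MIN, INERTIA_MAX)
    return replace(state, inertia=inertia)


_MOORE_KERNEL = np.array([[1.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 1.0]])


def neighborhood_effect(
    lum: LandUseMap, k: int, w: NeighborhoodWeights
) -> np.ndarray:
    """Moore-neighborhood effect field for class k (3×3 window).

    Per cell: (number of class-k cells among the 8 neighbors) / 8 · ω_k;
    out-of-bounds and nodata neighbors count zero.
    """
    if k not in CLASSES:
        raise ArgumentError(f"unknown class code {k}")
    is_k = (lum.classes == k).astype(float)
    counts = ndimage.convolve(is_k, _MOORE_KERNEL, mode="constant", cval=0.0)
    return counts / 8.0 * w.omega[k - 1]


def combined_probability(
    sp: SuitabilityCube,
    omega_field: np.ndarray,
    state: InertiaState,
    cost: CostMatrix,
    current: LandUseMap,
) -> np.ndarray:
    """Total conversion probability TProb, shape (6, rows, cols).

    TProb(p,k) = sp(p,k) · Ω(p,k) · Inertia_k · (1 − sc[current(p), k]);
    the zero cost diagonal makes staying in class free.  Nodata cells
    are zero everywhere.
    """
    if omega_field.shape != sp.probs.shape:
        raise ArgumentError("omega_field must be a (6, rows, cols) stack")
    active = current.active
    cur = np.where(active, current.classes, 1) - 1
    cost_factor = 1.0 - cost.sc[cur]  # (rows, cols, 6)
    tprob = (
        np.nan_to_num(sp.probs)
        * omega_field
        * state.inertia[:, None, None]
        * np.moveaxis(cost_factor, -1, 0)
    )
    tprob[:, ~active] = 0.0
    return tprob


def roulette_select(scores: np.ndarray, rng: np.random.Generator, current: int) -> int:
    """Draw a class with probability proportional to its score.

    All-zero scores keep the current class; negative scores are a
    programming error.
    """
    if (scores < 0).any():
        raise ArgumentError("roulette scores must be non-negative")
    total = scores.sum()
    if total <= 0:
        return current
    u = rng.random() * total
    return int(np.searchsorted(np.cumsum(scores), u, side="right")) + 1


def _check_feasibility(
    lum: LandUseMap, demand: DemandVector, mask: ConstraintMask
) -> None:
    frozen = mask.frozen & lum.active
    frozen_counts = np.array(
        [int(((lum.classes == c) & frozen).sum()) for c in CLASSES]
    )
    convertible = lum.n_active - frozen.sum()
    for i, c in enumerate(CLASSES):
        if demand.counts[i] < frozen_counts[i]:
            raise SimulationError(
                f"demand for {CLASS_NAMES[c]} ({demand.counts[i]}) is below its "
                f"frozen cell count ({frozen_counts[i]})"
            )
        if demand.counts[i] > frozen_counts[i] + convertible:
            raise SimulationError(
                f"demand for {CLASS_NAMES[c]} ({demand.counts[i]}) exceeds the "
                "convertible cells available"
            )


def run_simulation(
    map_t0: LandUseMap,
    cube: SuitabilityCube,
    demand: DemandVector,
    cost: CostMatrix | None = None,
    mask: ConstraintMask | None = None,
    w: NeighborhoodWeights | None = None,
    max_iter: int = 200,
    tol: int | None = None,
    seed: int = 0,
    log: list | None = None,
) -> LandUseMap:
    """Allocate land until per-class counts meet demand within ``tol`` cells.

    Frozen cells (mask = 0) and nodata never change.  ``log``, if given,
    collects one dict per iteration with the per-class gaps and inertia
    (the CSV iteration log of a pipeline run).
    """
    if map_t0.shape != cube.shape:
        raise ArgumentError("map and suitability cube must share a shape")
    if demand.total != map_t0.n_active:
        raise ArgumentError(
            f"demand total {demand.total} must equal active cells {map_t0.n_active}"
        )
    if max_iter < 1:
        raise ArgumentError("max_iter must be ≥ 1")
    cost = cost or CostMatrix.uniform(0.0)
    mask = mask or ConstraintMask(np.ones(map_t0.shape, dtype=np.uint8))
    w = w or NeighborhoodWeights()
    if tol is None:
        tol = max(0, int(round(0.001 * map_t0.n_active)))
    _check_feasibility(map_t0, demand, mask)

    rng = np.random.default_rng(seed)
    current = map_t0.copy()
    counts = current.class_counts().astype(np.int64)
    target = demand.counts.astype(np.int64)
    state = InertiaState(gap_t1=target - counts, gap_t2=target - counts)
    mutable = current.active & (mask.mask == 1)
    mutable_idx = np.flatnonzero(mutable)
    ncols = current.shape[1]

    for iteration in range(max_iter):
        gaps = target - counts
        if log is not None:
            entry = {"iteration": iteration}
            for i, c in enumerate(CLASSES):
                entry[f"gap_{CLASS_NAMES[c]}"] = int(gaps[i])
                entry[f"inertia_{CLASS_NAMES[c]}"] = float(state.inertia[i])
            log.append(entry)
        if np.abs(gaps).max() <= tol:
            break
        state = replace(state, gap_t2=state.gap_t1, gap_t1=gaps.astype(float))
        state = update_inertia(state)

        omega = np.stack(
            [neighborhood_effect(current, k, w) for k in CLASSES]
        )
        tprob = combined_probability(
            cube, np.maximum(omega, OMEGA_FLOOR), state, cost, current
        )
        tflat = tprob.reshape(N_CLASSES, -1)
        order = rng.permutation(mutable_idx)
        for p in order:
            c = int(current.classes.ravel()[p])
            src = c - 1
            if counts[src] - target[src] <= 0:
                continue  # source not over demand: no change allowed
            # candidates are the under-demand classes; all-zero candidate
            # scores keep the current class
            scores = tflat[:, p].copy()
            under = (target - counts) > 0
            scores[~under] = 0.0
            k = roulette_select(scores, rng, c)
            if k != c:
                current.classes[p // ncols, p % ncols] = k
                counts[src] -= 1
                counts[k - 1] += 1
                if counts[src] - target[src] <= 0 and not (target - counts).any():
                    break
    else:
        gaps = target - counts
        if np.abs(gaps).max() > tol:
            worst = int(np.abs(gaps).argmax())
            raise SimulationError(
                f"did not converge in {max_iter} iterations; worst class "
                f"{CLASS_NAMES[worst + 1]} gap {int(gaps[worst])} (tol {tol})"
            )
    return current


def iteration_log_frame(log: list[dict]) -> pd.DataFrame:
    """Iteration log entries as a tidy DataFrame (for the CSV log)."""
    return pd.DataFrame(log)
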
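"""Seeded synthetic landscapes with known ground truth.

Every downstream stage of the pipeline (demand estimation, suitability
training, CA allocation, valuation, trade-off mapping) is exercised on
synthetic rasters whose generating process is known, so statistical
recovery can be tested:

* driver layers are spatially autocorrelated random fields (white noise
  smoothed with a Gaussian kernel of width ``corr_length``), a DEM-like
  surface with slope/aspect derived by finite differences, and
  Euclidean-distance-to-random-point layers mimicking accessibility
  drivers;
* the initial land-use map follows a planted multinomial logit on the
  normalized drivers (optionally contagion-smoothed), so a suitability
  model has a recoverable signal;
* the second-date map evolves each cell independently through a known
  row-stochastic class-transition matrix, the ground truth for the
  Markov demand stage.

Class codes are fixed package-wide: 1=cultivated, 2=woodland,
3=grassland, 4=water, 5=built, 6=unused, 0=nodata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import ArgumentError
from .grids import CLASSES, DEFAULT_CELL_SIZE, N_CLASSES, NODATA, ConstraintMask, DriverStack, LandUseMap
from .valuation import CropTable

SCENARIOS = ("natural_evolution", "cultivated_protection", "ecological_protection")


@dataclass
class SyntheticTruth:
    """Ground truth planted into a synthetic landscape.

    ``logit_weights`` is the 6 × n_drivers coefficient matrix of the
    multinomial logit that assigns class membership from normalized
    drivers; ``true_transition`` the 6×6 row-stochastic matrix evolving
    the map between dates.
    """

    logit_weights: np.ndarray
    true_transition: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.logit_weights = np.asarray(self.logit_weights, dtype=float)
        self.true_transition = np.asarray(self.true_transition, dtype=float)
        if self.logit_weights.shape[0] != N_CLASSES:
            raise ArgumentError("logit_weights must have 6 rows (one per class)")
        # +inf is tolerated (degenerate certainty); NaN is not
        if np.isnan(self.logit_weights).any():
            raise ArgumentError("logit_weights must not contain NaN")
        if self.true_transition.shape != (N_CLASSES, N_CLASSES):
            raise ArgumentError("true_transition must be 6×6")
        rows = self.true_transition.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-12):
            raise ArgumentError("true_transition rows must sum to 1")
        if (self.true_transition < 0).any():
            raise ArgumentError("true_transition entries must be non-negative")


#: default class-transition matrix: strong persistence with a drift toward
#: built land, the typical signature of a rapidly urbanising region.
DEFAULT_TRANSITION = np.array(
    [
        # cult   wood   grass  water  built  unused
        [0.880, 0.010, 0.010, 0.005, 0.090, 0.005],  # cultivated
        [0.030, 0.920, 0.020, 0.005, 0.020, 0.005],  # woodland
        [0.040, 0.030, 0.880, 0.005, 0.040, 0.005],  # grassland
        [0.010, 0.005, 0.005, 0.960, 0.015, 0.005],  # water
        [0.005, 0.003, 0.002, 0.000, 0.990, 0.000],  # built
        [0.050, 0.020, 0.020, 0.010, 0.050, 0.850],  # unused
    ]
)


def default_truth(n_drivers: int, seed: int = 0, weight_scale: float = 6.0) -> SyntheticTruth:
    """A reproducible ground truth with recoverable class–driver signal.

    Logit weights are drawn N(0, weight_scale²); the scale is large
    relative to the [0,1] driver range so planted class structure is
    strong enough for a suitability model to recover.
    """
    rng = np.random.default_rng(seed)
    w = rng.normal(0.0, weight_scale, size=(N_CLASSES, n_drivers))
    # zero row sums keep expected logits equal across classes (drivers are
    # min–max scaled, mean ≈ 0.5), so no class swallows the landscape
    w -= w.mean(axis=1, keepdims=True)
    return SyntheticTruth(w, DEFAULT_TRANSITION.copy(), seed=seed)


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], corr_length: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    return ndimage.gaussian_filter(noise, sigma=corr_length, mode="reflect")


def gen_drivers(
    shape: tuple[int, int],
    n_point_sources: int = 3,
    corr_length: float = 6.0,
    seed: int = 0,
    cell_size: float = DEFAULT_CELL_SIZE,
) -> DriverStack:
    """Generate a synthetic driver stack.

    Layers: ``dem`` (smooth Gaussian random field), ``slope`` and
    ``aspect`` (finite differences of the DEM), ``gdp`` and ``population``
    (independent smooth fields), and four distance layers (``dist_town``,
    ``dist_highway``, ``dist_railway``, ``dist_water``), each the
    Euclidean distance to ``n_point_sources`` random source cells.
    """
    rows, cols = shape
    if rows < 8 or cols < 8:
        raise ArgumentError("driver grids must be at least 8×8")
    if corr_length < 1:
        raise ArgumentError("corr_length must be ≥ 1 cell")
    if n_point_sources < 1:
        raise ArgumentError("n_point_sources must be ≥ 1")
    rng = np.random.default_rng(seed)

    dem = _smooth_field(rng, shape, corr_length)
    gy, gx = np.gradient(dem)
    slope = np.hypot(gx, gy)
    aspect = np.arctan2(-gy, gx)  # radians, flat cells → 0 by arctan2(0,0)

    gdp = _smooth_field(rng, shape, corr_length)
    population = _smooth_field(rng, shape, corr_length)

    layers = {
        "dem": dem,
        "slope": slope,
        "aspect": aspect,
        "gdp": gdp,
        "population": population,
    }
    for name in ("dist_town", "dist_highway", "dist_railway", "dist_water"):
        sources = np.zeros(shape, dtype=bool)
        idx = rng.choice(rows * cols, size=n_point_sources, replace=False)
        sources.ravel()[idx] = True
        # EDT measures distance to the nearest zero of its input
        layers[name] = ndimage.distance_transform_edt(~sources)
    return DriverStack(layers, cell_size=cell_size)


# ---------------------------------------------------------------------------
# land-use maps
# ---------------------------------------------------------------------------


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax tolerating +inf entries (degenerate certainty)."""
    out = np.empty_like(logits, dtype=float)
    inf_mask = np.isposinf(logits)
    has_inf = inf_mask.any(axis=1)
    if has_inf.any():
        rows = inf_mask[has_inf]
        out[has_inf] = rows / rows.sum(axis=1, keepdims=True)
    fin = ~has_inf
    if fin.any():
        z = logits[fin] - logits[fin].max(axis=1, keepdims=True)
        e = np.exp(z)
        out[fin] = e / e.sum(axis=1, keepdims=True)
    return out


def planted_probabilities(drivers: DriverStack, truth: SyntheticTruth) -> np.ndarray:
    """Per-cell planted class probabilities, shape (6, rows, cols)."""
    if truth.logit_weights.shape[1] != len(drivers.names):
        raise ArgumentError(
            f"logit_weights expect {truth.logit_weights.shape[1]} drivers, "
            f"stack has {len(drivers.names)}"
        )
    X = drivers.design_matrix()  # over all non-NaN cells
    # ±inf weights express degenerate certainty; clip to a huge finite
    # value so 0·inf cells do not turn into NaN logits
    W = np.clip(truth.logit_weights, -1e12, 1e12)
    probs = _softmax_rows(X @ W.T)
    rows, cols = drivers.shape
    cube = np.zeros((N_CLASSES, rows, cols))
    cube[:, ~drivers.nodata_mask] = probs.T
    return cube


def _majority_smooth(classes: np.ndarray, passes: int) -> np.ndarray:
    kernel = np.ones((3, 3))
    out = classes.copy()
    for _ in range(passes):
        counts = np.stack(
            [
                ndimage.convolve((out == c).astype(float), kernel, mode="constant", cval=0.0)
                for c in CLASSES
            ]
        )
        new = np.argmax(counts, axis=0).astype(np.int16) + 1
        new[classes == NODATA] = NODATA
        out = new
    return out


def gen_initial_map(
    drivers: DriverStack,
    truth: SyntheticTruth,
    smoothing_passes: int = 1,
) -> LandUseMap:
    """Draw a land-use map from the planted driver-dependent multinomial.

    Each cell's class is sampled from softmax(W·x); ``smoothing_passes``
    rounds of 3×3 majority filtering then add neighborhood contagion.
    Sampling uses ``truth.seed`` so the map is a pure function of
    (drivers, truth).
    """
    cube = planted_probabilities(drivers, truth)
    rng = np.random.default_rng(truth.seed)
    rows, cols = drivers.shape
    active = ~drivers.nodata_mask
    p = cube[:, active].T  # (n_active, 6)
    u = rng.random(p.shape[0])
    draws = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)  # 0..5
    classes = np.full((rows, cols), NODATA, dtype=np.int16)
    classes[active] = draws.astype(np.int16) + 1
    if smoothing_passes:
        classes = _majority_smooth(classes, smoothing_passes)
    return LandUseMap(classes, drivers.cell_size)


def evolve_map(map_t0: LandUseMap, truth: SyntheticTruth, seed: int = 0) -> LandUseMap:
    """Evolve each cell independently through ``truth.true_transition``."""
    rng = np.random.default_rng(seed)
    classes = map_t0.classes
    out = classes.copy()
    for c in CLASSES:
        cells = classes == c
        n = int(cells.sum())
        if n == 0:
            continue
        row = truth.true_transition[c - 1]
        u = rng.random(n)
        draws = (row.cumsum() < u[:, None]).sum(axis=1)  # 0..5
        out[cells] = draws.astype(np.int16) + 1
    return LandUseMap(out, map_t0.cell_size)


# ---------------------------------------------------------------------------
# constraint masks & crop tables
# ---------------------------------------------------------------------------


def _grow_contiguous(
    eligible: np.ndarray, target: int, rng: np.random.Generator
) -> np.ndarray:
    """Select ~target eligible cells as contiguous random patches (8-conn)."""
    chosen = np.zeros_like(eligible, dtype=bool)
    remaining = eligible.copy()
    n_chosen = 0
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    nrows, ncols = eligible.shape
    while n_chosen < target and remaining.any():
        seeds = np.flatnonzero(remaining)
        start = seeds[rng.integers(seeds.size)]
        frontier = [divmod(int(start), ncols)]
        while frontier and n_chosen < target:
            i = rng.integers(len(frontier))
            r, c = frontier.pop(int(i))
            if not remaining[r, c]:
                continue
            chosen[r, c] = True
            remaining[r, c] = False
            n_chosen += 1
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrows and 0 <= cc < ncols and remaining[rr, cc]:
                    frontier.append((rr, cc))
    return chosen


def gen_constraint_masks(
    lum: LandUseMap, scenario: str, fraction: float = 0.5, seed: int = 0
) -> ConstraintMask:
    """Freeze a contiguous random subset of protected cells per scenario.

    ``cultivated_protection`` freezes a fraction of cultivated cells (the
    basic-farmland analogue); ``ecological_protection`` freezes fractions
    of woodland and water (the ecological-reserve analogue);
    ``natural_evolution`` freezes nothing.
    """
    if scenario not in SCENARIOS:
        raise ArgumentError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if not 0.0 <= fraction <= 1.0:
        raise ArgumentError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    frozen = np.zeros(lum.shape, dtype=bool)
    if scenario == "cultivated_protection":
        protected_classes = [1]
    elif scenario == "ecological_protection":
        protected_classes = [2, 4]
    else:
        protected_classes = []
    for c in protected_classes:
        eligible = lum.classes == c
        target = int(round(fraction * eligible.sum()))
        if target:
            frozen |= _grow_contiguous(eligible, target, rng)
    return ConstraintMask((~frozen).astype(np.uint8))


def gen_crop_table(n_crops: int = 6, seed: int = 0) -> CropTable:
    """Random but realistic regional crop statistics (areas, yields, prices)."""
    if n_crops < 1:
        raise ArgumentError("n_crops must be ≥ 1")
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "crop": [f"crop_{i}" for i in range(1, n_crops + 1)],
            "sown_area_hm2": rng.uniform(500.0, 3.2e5, n_crops),
            "yield_t_per_hm2": rng.uniform(1.0, 8.0, n_crops),
            "price_yuan_per_t": rng.uniform(1500.0, 4000.0, n_crops),
        }
    )
    return CropTable(df)
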
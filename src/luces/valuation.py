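"""Equivalent-factor ecosystem-service valuation.

The equivalent-factor method prices the services a land mosaic provides by
multiplying per-class unit-value coefficients (an 11-service × 6-class
table, units of 100 yuan·hm⁻²·yr⁻¹) by class areas:

    ESV = Σ_k A_k · V_ck            (per service c)

The regional anchor of such tables is the food-production unit value

    E = (1/7) · Σ_i m_i p_i q_i / M

where m_i, p_i, q_i are sown area (hm²), national average price (yuan/t)
and per-area yield (t/hm²) of grain crop i, M = Σ m_i, and the 1/7 factor
expresses that an unmanaged ecosystem yields one seventh of the economic
value of cultivated food production.

For spatially explicit comparison the raster is aggregated to an analysis
grid (default 1 km × 1 km); each grid cell carries UESV = ESV / S with S
its *actual* member area, so irregular edge grids are comparable to
interior ones.  UESV surfaces are classed into five levels by Jenks
natural breaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ArgumentError, FormatError
from .grids import CLASS_NAMES, N_CLASSES, NODATA, LandUseMap

SERVICES = (
    "food production",
    "raw materials",
    "water supply",
    "gas regulation",
    "climate regulation",
    "environment purification",
    "hydrology regulation",
    "soil maintenance",
    "nutrient circulation",
    "biodiversity",
    "aesthetic landscape",
)
CATEGORIES = ("provisioning", "regulating", "supporting", "cultural")
LAND_CLASS_COLUMNS = tuple(CLASS_NAMES[c] for c in range(1, N_CLASSES + 1))


@dataclass
class CropTable:
    """Per-crop sown area (hm²), yield (t/hm²) and price (yuan/t)."""

    table: pd.DataFrame  # columns: crop, sown_area_hm2, yield_t_per_hm2, price_yuan_per_t

    def __post_init__(self) -> None:
        required = {"crop", "sown_area_hm2", "yield_t_per_hm2", "price_yuan_per_t"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"crop table missing columns: {sorted(missing)}")
        num = self.table[["sown_area_hm2", "yield_t_per_hm2", "price_yuan_per_t"]]
        if not (num.to_numpy() > 0).all():
            raise ArgumentError("crop areas, yields and prices must be positive")

    @property
    def total_sown_area(self) -> float:
        return float(self.table["sown_area_hm2"].sum())


@dataclass
class ESVCoefficientTable:
    """Service × land-class unit values in 100 yuan·hm⁻²·yr⁻¹.

    Rows are the 11 ecosystem services, columns the 6 land classes.
    Negative entries (built land) are net disservices and are retained.
    """

    values: pd.DataFrame  # index: service, columns: land classes
    category: dict[str, str] = field(default_factory=dict)  # service -> category

    def __post_init__(self) -> None:
        if set(self.values.index) != set(SERVICES):
            raise FormatError(
                "coefficient table must contain exactly the 11 standard services; "
                f"got {sorted(self.values.index)}"
            )
        if set(self.values.columns) != set(LAND_CLASS_COLUMNS):
            raise FormatError(
                f"coefficient table must have columns {LAND_CLASS_COLUMNS}"
            )
        if self.values.isna().any().any():
            raise FormatError("coefficient table has missing cells")
        # canonical ordering
        self.values = self.values.loc[list(SERVICES), list(LAND_CLASS_COLUMNS)]
        unknown = set(self.category.values()) - set(CATEGORIES)
        if unknown:
            raise FormatError(f"unknown service categories: {sorted(unknown)}")

    def matrix(self) -> np.ndarray:
        """(11, 6) coefficient array ordered like SERVICES × class codes 1..6."""
        return self.values.to_numpy(dtype=float)

    def services_in(self, category: str) -> list[str]:
        return [s for s in SERVICES if self.category.get(s) == category]

    def rescaled(self, base_equivalents: pd.DataFrame, unit_value: float) -> "ESVCoefficientTable":
        """Build a table from dimensionless base equivalents × a regional E.

        ``base_equivalents`` has the same shape as ``values``; entries are
        multiples of the food-production unit value ``unit_value``
        (yuan/hm²).  Output stays in 100-yuan units.
        """
        tab = ESVCoefficientTable(base_equivalents.copy(), dict(self.category))
        tab.values = tab.values * (unit_value / 100.0)
        return tab


def derive_unit_value(ct: CropTable) -> float:
    """Regional food-production unit value E in yuan/hm².

    E = (1/7)·Σ m_i p_i q_i / M — the area-weighted mean market value of
    grain output per hectare, scaled by the natural-contribution factor 1/7.
    """
    m = ct.table["sown_area_hm2"].to_numpy(dtype=float)
    p = ct.table["price_yuan_per_t"].to_numpy(dtype=float)
    q = ct.table["yield_t_per_hm2"].to_numpy(dtype=float)
    M = m.sum()
    if M <= 0:
        raise ArgumentError("total sown area must be positive")
    return float((m * p * q).sum() / M / 7.0)


def load_crop_table(path: str | Path | None = None) -> CropTable:
    """Load a crop-statistics CSV (default: the packaged regional table)."""
    if path is None:
        with resources.files("luces.data").joinpath("crop_stats.csv").open() as fh:
            df = pd.read_csv(fh, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    return CropTable(df)


def load_coefficients(path: str | Path | None = None) -> ESVCoefficientTable:
    """Load a service × class coefficient CSV (default: packaged table).

    The CSV has columns ``service, category, cultivated, woodland,
    grassland, water, built, unused``; values in 100 yuan/hm²/yr.
    """
    if path is None:
        with resources.files("luces.data").joinpath("esv_coefficients.csv").open() as fh:
            df = pd.read_csv(fh, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    if "service" not in df.columns or "category" not in df.columns:
        raise FormatError("coefficient CSV needs 'service' and 'category' columns")
    category = dict(zip(df["service"], df["category"]))
    values = df.set_index("service").drop(columns="category")
    return ESVCoefficientTable(values, category)


def compute_esv(
    lum: LandUseMap,
    table: ESVCoefficientTable,
    services: list[str] | None = None,
) -> pd.Series:
    """Ecosystem-service value of a whole map, per service, in 100 yuan/yr.

    ESV_c = Σ_k area_k(hm²) · V[c, k]; the returned Series also carries a
    ``"total"`` entry.  ``services`` restricts the computation to a subset.
    """
    counts = lum.class_counts().astype(float)
    areas = counts * lum.cell_area_hm2  # hm² per class, codes 1..6
    V = table.matrix()
    chosen = list(SERVICES) if services is None else list(services)
    unknown = set(chosen) - set(SERVICES)
    if unknown:
        raise ArgumentError(f"unknown services: {sorted(unknown)}")
    rows = [SERVICES.index(s) for s in chosen]
    esv = V[rows] @ areas
    out = pd.Series(esv, index=chosen, name="esv_100yuan")
    out["total"] = float(esv.sum())
    return out


def esv_by_category(esv: pd.Series, table: ESVCoefficientTable) -> pd.Series:
    """Aggregate a per-service ESV Series into the four service categories."""
    out = {}
    for cat in CATEGORIES:
        members = [s for s in table.services_in(cat) if s in esv.index]
        out[cat] = float(esv[members].sum())
    out["total"] = float(sum(out[c] for c in CATEGORIES))
    return pd.Series(out, name="esv_100yuan")


@dataclass
class ESVGrid:
    """Per-analysis-grid ESV aggregates.

    Arrays have the analysis-grid shape (gr, gc).  ``per_service`` is a
    (11, gr, gc) stack in SERVICES order; ``area_hm2`` the active member
    area of each grid cell (0 where the grid holds only nodata); ``uesv``
    total ESV per unit area (NaN where area is 0), units 100 yuan/hm²/yr.
    """

    per_service: np.ndarray
    area_hm2: np.ndarray
    grid_size: float
    table: ESVCoefficientTable

    @property
    def shape(self) -> tuple[int, int]:
        return self.area_hm2.shape

    @property
    def active(self) -> np.ndarray:
        return self.area_hm2 > 0

    @property
    def total(self) -> np.ndarray:
        return self.per_service.sum(axis=0)

    @property
    def uesv(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.active, self.total / self.area_hm2, np.nan)

    def category_esv(self, category: str) -> np.ndarray:
        rows = [SERVICES.index(s) for s in self.table.services_in(category)]
        return self.per_service[rows].sum(axis=0)

    def category_uesv(self, category: str) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.active, self.category_esv(category) / self.area_hm2, np.nan)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-grid table (one row per active grid cell)."""
        gr, gc = self.shape
        rows, cols = np.nonzero(self.active)
        df = pd.DataFrame({"grid_row": rows, "grid_col": cols})
        df["area_hm2"] = self.area_hm2[rows, cols]
        for i, s in enumerate(SERVICES):
            df[s] = self.per_service[i, rows, cols]
        df["total"] = self.total[rows, cols]
        df["uesv"] = self.uesv[rows, cols]
        for cat in CATEGORIES:
            df[f"uesv_{cat}"] = self.category_uesv(cat)[rows, cols]
        return df


def compute_uesv_grid(
    lum: LandUseMap,
    table: ESVCoefficientTable,
    grid_size: float = 1000.0,
) -> ESVGrid:
    """Aggregate per-cell ESV to square analysis grids of ``grid_size`` m.

    Cells belong to the grid square containing their centre; edge grids may
    be smaller than interior ones, which UESV normalises away.
    """
    if grid_size < lum.cell_size:
        raise ArgumentError("grid_size must be at least the raster cell size")
    block = max(1, int(round(grid_size / lum.cell_size)))
    nrows, ncols = lum.shape
    gr = -(-nrows // block)
    gc = -(-ncols // block)
    V = table.matrix()  # (11, 6)

    per_service = np.zeros((len(SERVICES), gr, gc))
    area = np.zeros((gr, gc))
    cell_area = lum.cell_area_hm2
    for gi in range(gr):
        for gj in range(gc):
            tile = lum.classes[gi * block : (gi + 1) * block, gj * block : (gj + 1) * block]
            counts = np.bincount(tile.ravel(), minlength=N_CLASSES + 1)[1:]
            n_act = counts.sum()
            if n_act == 0:
                continue
            areas_k = counts * cell_area
            per_service[:, gi, gj] = V @ areas_k
            area[gi, gj] = n_act * cell_area
    return ESVGrid(per_service, area, grid_size, table)


# ---------------------------------------------------------------------------
# Jenks natural breaks (Fisher's optimal 1-D classification)
# ---------------------------------------------------------------------------


def _jenks_breaks_dp(sorted_vals: np.ndarray, k: int) -> list[int]:
    """Optimal split indices minimising within-class sum of squared deviations.

    Dynamic programme over prefix sums; returns the start index of each of
    the k classes in the sorted array (first is always 0).
    """
    n = sorted_vals.size
    pre = np.concatenate([[0.0], np.cumsum(sorted_vals)])
    pre2 = np.concatenate([[0.0], np.cumsum(sorted_vals**2)])

    def ssd(i: int, j: int) -> float:
        # within-class SSD of sorted_vals[i:j]
        m = j - i
        s = pre[j] - pre[i]
        return (pre2[j] - pre2[i]) - s * s / m

    INF = float("inf")
    cost = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = INF, 0
            for i in range(c - 1, j):
                v = cost[c - 1, i] + ssd(i, j)
                if v < best:
                    best, arg = v, i
            cost[c, j] = best
            back[c, j] = arg
    # recover class start indices
    starts = []
    j = n
    for c in range(k, 0, -1):
        i = back[c, j]
        starts.append(i)
        j = i
    return starts[::-1]


def classify_levels(values: np.ndarray, k: int = 5) -> np.ndarray:
    """Jenks natural-breaks classification into levels 1..k (NaN → 0).

    Larger values get higher levels.  With fewer distinct values than
    classes, degenerate classes are collapsed and a warning is issued.
    """
    values = np.asarray(values, dtype=float)
    flat = values.ravel()
    finite = np.isfinite(flat)
    vals = flat[finite]
    levels = np.zeros(flat.size, dtype=int)
    if vals.size == 0:
        return levels.reshape(values.shape)
    distinct = np.unique(vals)
    k_eff = k
    if distinct.size < k:
        warnings.warn(
            f"only {distinct.size} distinct values; collapsing to {distinct.size} levels",
            stacklevel=2,
        )
        k_eff = distinct.size
    order = np.argsort(vals, kind="stable")
    sorted_vals = vals[order]
    starts = _jenks_breaks_dp(sorted_vals, k_eff)
    lab_sorted = np.zeros(vals.size, dtype=int)
    edges = starts + [vals.size]
    for level, (lo, hi) in enumerate(zip(edges[:-1], edges[1:]), start=1):
        lab_sorted[lo:hi] = level
    lab = np.empty_like(lab_sorted)
    lab[order] = lab_sorted
    levels[finite] = lab
    return levels.reshape(values.shape)
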
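"""Core raster containers and plain-text raster I/O.

Land-use rasters are small categorical grids with six classes plus a
nodata code.  The fixed class coding used everywhere in the package is

    0 = nodata, 1 = cultivated, 2 = woodland, 3 = grassland,
    4 = water,  5 = built,      6 = unused

Rasters are read and written as ESRI ASCII grids (``.asc``): a plain-text
format that carries the cell size and nodata value in its header, so
categorical maps, driver layers and masks round-trip losslessly through
ordinary text files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ArgumentError, FormatError

NODATA = 0
CLASS_NAMES = {
    1: "cultivated",
    2: "woodland",
    3: "grassland",
    4: "water",
    5: "built",
    6: "unused",
}
CLASS_CODES = {name: code for code, name in CLASS_NAMES.items()}
CLASSES = tuple(CLASS_NAMES)  # (1, 2, 3, 4, 5, 6)
N_CLASSES = len(CLASSES)

#: default cell edge length in metres (30 m Landsat-style grid)
DEFAULT_CELL_SIZE = 30.0


@dataclass
class LandUseMap:
    """A categorical land-use raster.

    Parameters
    ----------
    classes
        2-D integer array of class codes; 0 marks nodata.
    cell_size
        Cell edge length in metres (cells are square).
    """

    classes: np.ndarray
    cell_size: float = DEFAULT_CELL_SIZE

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.int16)
        if self.classes.ndim != 2:
            raise ArgumentError("land-use map must be a 2-D array")
        valid = np.isin(self.classes, (NODATA,) + CLASSES)
        if not valid.all():
            bad = np.unique(self.classes[~valid])
            raise ArgumentError(f"unknown class codes in map: {bad.tolist()}")
        if self.cell_size <= 0:
            raise ArgumentError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape

    @property
    def active(self) -> np.ndarray:
        """Boolean mask of non-nodata cells."""
        return self.classes != NODATA

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    @property
    def cell_area_hm2(self) -> float:
        """Area of one cell in hectares."""
        return self.cell_size * self.cell_size / 1e4

    def class_counts(self) -> np.ndarray:
        """Cell counts for classes 1..6 as a length-6 vector."""
        return np.bincount(self.classes.ravel(), minlength=N_CLASSES + 1)[1:]

    def copy(self) -> "LandUseMap":
        return LandUseMap(self.classes.copy(), self.cell_size)


@dataclass
class DriverStack:
    """A stack of continuous spatial driver layers sharing one grid.

    ``layers`` maps a driver name to its 2-D float field (raw units).
    ``normalization_bounds`` holds the per-layer (min, max) used to
    rescale values into [0, 1]; layers whose min equals max normalize to
    zero.  Nodata is carried as NaN and must coincide across layers.
    """

    layers: dict[str, np.ndarray]
    cell_size: float = DEFAULT_CELL_SIZE
    normalization_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ArgumentError("driver stack needs at least one layer")
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) != 1:
            raise ArgumentError(f"driver layers have mismatched shapes: {shapes}")
        self.layers = {k: np.asarray(v, dtype=float) for k, v in self.layers.items()}
        nan_masks = [np.isnan(a) for a in self.layers.values()]
        for m in nan_masks[1:]:
            if not np.array_equal(m, nan_masks[0]):
                raise ArgumentError("nodata (NaN) cells must coincide across layers")
        if not self.normalization_bounds:
            self.normalization_bounds = {
                k: (float(np.nanmin(v)), float(np.nanmax(v)))
                for k, v in self.layers.items()
            }

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def nodata_mask(self) -> np.ndarray:
        return np.isnan(next(iter(self.layers.values())))

    def normalized(self) -> dict[str, np.ndarray]:
        """Min–max rescaled layers; every finite value lies in [0, 1]."""
        out = {}
        for name, arr in self.layers.items():
            lo, hi = self.normalization_bounds[name]
            if hi > lo:
                out[name] = np.clip((arr - lo) / (hi - lo), 0.0, 1.0)
            else:
                out[name] = np.zeros_like(arr)
        return out

    def design_matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Normalized driver values as an (n_cells, n_drivers) matrix.

        ``mask`` selects cells (default: all non-NaN cells), in row-major
        order.
        """
        norm = self.normalized()
        if mask is None:
            mask = ~self.nodata_mask
        return np.column_stack([norm[name][mask] for name in self.names])


@dataclass
class ConstraintMask:
    """Binary conversion mask: 1 = convertible, 0 = frozen at current class."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.mask.ndim != 2:
            raise ArgumentError("constraint mask must be 2-D")
        if not np.isin(self.mask, (0, 1)).all():
            raise ArgumentError("constraint mask must be binary")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def frozen(self) -> np.ndarray:
        return self.mask == 0


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def write_ascii_grid(
    path: str | Path,
    array: np.ndarray,
    cell_size: float,
    nodata: float = -9999,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
) -> None:
    """Write a 2-D array as an ESRI ASCII grid; NaN is stored as nodata."""
    arr = np.asarray(array, dtype=float)
    if arr.ndim != 2:
        raise ArgumentError("only 2-D arrays can be written as ASCII grids")
    arr = np.where(np.isnan(arr), float(nodata), arr)
    path = Path(path)
    header = (
        f"ncols {arr.shape[1]}\n"
        f"nrows {arr.shape[0]}\n"
        f"xllcorner {xllcorner!r}\n"
        f"yllcorner {yllcorner!r}\n"
        f"cellsize {cell_size!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, arr, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float, float]:
    """Read an ESRI ASCII grid.

    Returns ``(array, cell_size, nodata_value)``; nodata cells are left at
    the nodata value (callers decide whether to NaN them).
    """
    path = Path(path)
    meta: dict[str, float] = {}
    with path.open() as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
                meta[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        data = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in meta:
            raise FormatError(f"ASCII grid {path} is missing header key {key!r}")
    if data.shape != (int(meta["nrows"]), int(meta["ncols"])):
        raise FormatError(
            f"ASCII grid {path}: data shape {data.shape} does not match header"
        )
    return data, meta["cellsize"], meta.get("nodata_value", -9999.0)


def write_landuse(path: str | Path, lum: LandUseMap) -> None:
    """Write a land-use map as an ASCII grid (nodata code 0)."""
    write_ascii_grid(path, lum.classes.astype(float), lum.cell_size, nodata=NODATA)


def read_landuse(path: str | Path) -> LandUseMap:
    """Read a land-use map written by :func:`write_landuse`."""
    data, cell_size, nodata = read_ascii_grid(path)
    classes = np.asarray(np.rint(data), dtype=np.int16)
    classes[data == nodata] = NODATA
    return LandUseMap(classes, cell_size)


def write_drivers(directory: str | Path, drivers: DriverStack) -> list[Path]:
    """Write each driver layer as ``<directory>/<name>.asc``; NaN → nodata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, arr in drivers.layers.items():
        p = directory / f"{name}.asc"
        write_ascii_grid(p, arr, drivers.cell_size, nodata=-9999)
        paths.append(p)
    return paths


def read_drivers(paths: list[str | Path]) -> DriverStack:
    """Assemble a driver stack from ASCII-grid layer files (name = stem)."""
    layers: dict[str, np.ndarray] = {}
    cell_sizes = set()
    for p in paths:
        p = Path(p)
        data, cs, nodata = read_ascii_grid(p)
        data = np.where(data == nodata, np.nan, data)
        layers[p.stem] = data
        cell_sizes.add(cs)
    if len(cell_sizes) > 1:
        raise FormatError(f"driver layers disagree on cell size: {cell_sizes}")
    return DriverStack(layers, cell_size=cell_sizes.pop())
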
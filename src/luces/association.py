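"""Bivariate spatial association between ecosystem-service surfaces.

Trade-offs and synergies between service categories are read from the
sign and clustering of the bivariate Moran statistic.  With population
z-scores z^m, z^z of the two variables and row-standardized contiguity
weights W:

    global  I   = (1/n) Σ_i z_i^m (W z^z)_i
    local   I_i =        z_i^m (W z^z)_i

so the mean of the local statistics equals the global one exactly.
Significance uses GeoDa-style conditional permutation (the focal value
is held fixed, neighbor values are drawn from the rest of the map),
and significant cells are labelled HH / LL (synergy) or HL / LH
(trade-off) from the signs of z_i^m and the spatial lag.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import sparse

from .exceptions import ArgumentError
from .valuation import CATEGORIES, ESVGrid

LISA_LABELS = ("NS", "HH", "LL", "LH", "HL")
LISA_CODES = {lab: i for i, lab in enumerate(LISA_LABELS)}  # NS=0 … HL=4


@dataclass
class SpatialWeights:
    """Row-standardized contiguity weights on a rectangular analysis grid."""

    W: sparse.csr_matrix
    scheme: str
    islands: np.ndarray  # indices of cells with no neighbors

    @property
    def n(self) -> int:
        return self.W.shape[0]

    def lag(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(self.W @ z)

    def neighbor_lists(self) -> list[np.ndarray]:
        """Per-row neighbor index arrays (for conditional permutation)."""
        return [
            self.W.indices[self.W.indptr[i] : self.W.indptr[i + 1]]
            for i in range(self.n)
        ]


def build_weights(
    grid_shape: tuple[int, int],
    scheme: str = "queen",
    mask: np.ndarray | None = None,
) -> SpatialWeights:
    """Queen or rook contiguity weights for a (masked) rectangular grid.

    ``mask`` (boolean, grid-shaped) restricts the graph to active grid
    cells; ordering follows row-major order of the retained cells.
    Weights are row-standardized; cells without neighbors are flagged
    as islands and keep an all-zero row.
    """
    r, c = grid_shape
    if r * c < 2:
        raise ArgumentError("grid must contain at least 2 cells")
    if scheme not in ("queen", "rook"):
        raise ArgumentError(f"unknown contiguity scheme {scheme!r}")
    if mask is None:
        mask = np.ones(grid_shape, dtype=bool)
    idx = np.full(grid_shape, -1, dtype=np.int64)
    cells = np.nonzero(mask)
    n = cells[0].size
    idx[cells] = np.arange(n)
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if scheme == "queen":
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    rows, cols = [], []
    for dr, dc in offsets:
        for i, j in zip(*cells):
            ii, jj = i + dr, j + dc
            if 0 <= ii < r and 0 <= jj < c and mask[ii, jj]:
                rows.append(idx[i, j])
                cols.append(idx[ii, jj])
    B = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    deg = np.asarray(B.sum(axis=1)).ravel()
    islands = np.flatnonzero(deg == 0)
    inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)
    W = sparse.diags(inv) @ B
    return SpatialWeights(W.tocsr(), scheme, islands)


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    s = x.std()  # population (1/n) standard deviation
    if s == 0:
        raise ArgumentError("variable has zero variance")
    return (x - x.mean()) / s


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ArgumentError("x and y must be equal-length vectors of size ≥ 3")
    if x.std() == 0 or y.std() == 0:
        raise ArgumentError("correlation undefined for zero-variance input")
    return float(np.corrcoef(x, y)[0, 1])


def bivariate_local_moran(
    x: np.ndarray, y: np.ndarray, W: SpatialWeights
) -> np.ndarray:
    """Local bivariate Moran statistics I_i = z_i^x · (W z^y)_i."""
    zx = _zscore(x)
    zy = _zscore(y)
    if zx.size != W.n or zy.size != W.n:
        raise ArgumentError("variables must align with the weights matrix")
    return zx * W.lag(zy)


def bivariate_global_moran(x: np.ndarray, y: np.ndarray, W: SpatialWeights) -> float:
    """Global bivariate Moran's I (mean of the local statistics)."""
    return float(bivariate_local_moran(x, y, W).mean())


def permutation_significance(
    x: np.ndarray,
    y: np.ndarray,
    W: SpatialWeights,
    n_perm: int = 999,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell pseudo p-values by conditional permutation.

    For each cell the focal z_i^x is kept fixed while its neighbors'
    z^y values are replaced by draws from all other locations; the
    two-sided pseudo p is (#{|I_perm| ≥ |I_obs|} + 1)/(n_perm + 1).
    """
    if n_perm < 99:
        raise ArgumentError("n_perm must be ≥ 99")
    zx = _zscore(x)
    zy = _zscore(y)
    obs = zx * W.lag(zy)
    rng = np.random.default_rng(seed)
    n = W.n
    pvals = np.ones(n)
    neighbors = W.neighbor_lists()
    degrees = np.array([nb.size for nb in neighbors])
    max_d = int(degrees.max(initial=0))
    if max_d == 0:
        return pvals
    # shared permutation indices into each cell's "all other locations"
    # array: one truncated permutation of n-1 ids per replicate
    rids = np.empty((n_perm, max_d), dtype=np.int64)
    for r in range(n_perm):
        rids[r] = rng.permutation(n - 1)[:max_d]
    others = np.arange(n)
    for i in range(n):
        d = int(degrees[i])
        if d == 0:
            continue
        pool = np.delete(others, i)
        lag_perm = zy[pool[rids[:, :d]]].mean(axis=1)
        i_perm = zx[i] * lag_perm
        pvals[i] = (np.count_nonzero(np.abs(i_perm) >= abs(obs[i])) + 1) / (n_perm + 1)
    return pvals


@dataclass
class LISAResult:
    """Local-association labels for one pair of surfaces."""

    local_i: np.ndarray
    p_values: np.ndarray
    labels: np.ndarray  # strings from LISA_LABELS
    alpha: float

    def counts(self) -> dict[str, int]:
        return {lab: int((self.labels == lab).sum()) for lab in LISA_LABELS}

    @property
    def codes(self) -> np.ndarray:
        return np.vectorize(LISA_CODES.get)(self.labels)


def lisa_classify(
    x: np.ndarray,
    y: np.ndarray,
    W: SpatialWeights,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> LISAResult:
    """Label each cell HH/LL (synergy) or HL/LH (trade-off), else NS."""
    zx = _zscore(x)
    lag = W.lag(_zscore(y))
    local = zx * lag
    pvals = permutation_significance(x, y, W, n_perm=n_perm, seed=seed)
    labels = np.full(W.n, "NS", dtype=object)
    sig = pvals < alpha
    labels[sig & (zx > 0) & (lag > 0)] = "HH"
    labels[sig & (zx < 0) & (lag < 0)] = "LL"
    labels[sig & (zx > 0) & (lag < 0)] = "HL"
    labels[sig & (zx < 0) & (lag > 0)] = "LH"
    return LISAResult(local, pvals, labels.astype(str), alpha)


def service_pair_report(
    esv_grid: ESVGrid,
    pairs: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    scheme: str = "queen",
) -> pd.DataFrame:
    """Pearson r, global Moran's I and LISA counts per category pair.

    One row per unordered pair of the four service categories (six rows
    by default); synergy = HH + LL grids, trade-off = HL + LH grids.
    """
    if pairs is None:
        pairs = list(combinations(CATEGORIES, 2))
    mask = esv_grid.active
    W = build_weights(esv_grid.shape, scheme=scheme, mask=mask)
    surfaces = {cat: esv_grid.category_uesv(cat)[mask] for cat in CATEGORIES}
    rows = []
    for a, b in pairs:
        if a not in surfaces or b not in surfaces:
            raise ArgumentError(f"unknown category pair ({a}, {b})")
        x, y = surfaces[a], surfaces[b]
        res = lisa_classify(x, y, W, alpha=alpha, n_perm=n_perm, seed=seed)
        counts = res.counts()
        rows.append(
            {
                "pair": f"{a[0]}-{b[0]}",
                "category_a": a,
                "category_b": b,
                "pearson_r": pearson(x, y),
                "global_moran_i": bivariate_global_moran(x, y, W),
                **{f"n_{lab}": counts[lab] for lab in LISA_LABELS},
                "n_synergy": counts["HH"] + counts["LL"],
                "n_tradeoff": counts["HL"] + counts["LH"],
            }
        )
    return pd.DataFrame(rows)
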
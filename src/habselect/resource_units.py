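"""Resource-unit construction and screening statistics.

Eco-geographical variables (EGVs) arrive as co-registered fine-resolution
rasters (typically 30 m).  Analysis happens at the resource-unit (RU) scale,
a coarser cell (typically 90 m, aggregation factor 3) chosen so that spatial
autocorrelation among EGVs is minimal.  Continuous layers are block-averaged;
the categorical land-cover layer becomes one proportion layer per class.
This module also provides the screening statistics run before any selection
analysis: pairwise Pearson correlation, PCA of the EGV table, global Moran's
I spatial autocorrelation, and the kappa accuracy statistic for a classified
land-cover map.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.decomposition import PCA

logger = logging.getLogger("habselect")

#: default nodata sentinel written to ASCII grids
DEFAULT_NODATA = -9999.0


# ---------------------------------------------------------------------------
# RasterGrid
# ---------------------------------------------------------------------------

@dataclass
class RasterGrid:
    """A rectangular grid of cell values in a projected (metre) CRS.

    Row 0 is the northernmost row.  The cell ``(r, c)`` has its centre at
    ``(x_min + (c + 0.5) * cell_size, y_max - (r + 0.5) * cell_size)``.
    Cells are half-open: a point exactly on a shared boundary belongs to the
    cell to the east (x boundaries) or south (y boundaries).
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)  # (x_min, y_max)
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def x_min(self) -> float:
        return self.origin[0]

    @property
    def y_max(self) -> float:
        return self.origin[1]

    def valid_mask(self) -> np.ndarray:
        v = self.values.astype(float)
        return ~(np.isnan(v) | (v == self.nodata))

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) centre coordinate arrays of shape (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.x_min + (cols + 0.5) * self.cell_size
        y = self.y_max - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def point_to_cell(self, x: float, y: float) -> tuple[int, int]:
        """Map a projected point to its (row, col).

        Half-open cells: a point on a vertical boundary falls in the eastern
        cell, on a horizontal boundary in the southern cell.  Raises
        ``ValueError`` for points outside the grid extent.
        """
        col = int(np.floor((x - self.x_min) / self.cell_size))
        row = int(np.floor((self.y_max - y) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({x}, {y}) lies outside the grid extent")
        return row, col

    def same_geometry(self, other: "RasterGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and self.cell_size == other.cell_size
            and self.origin == other.origin
        )


def write_ascii_grid(grid: RasterGrid, path) -> None:
    """Write a raster as an ESRI ASCII grid (plain-text, one band)."""
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.x_min!r}\n")
        fh.write(f"yllcorner {grid.y_max - grid.n_rows * grid.cell_size!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        vals = np.where(grid.valid_mask(), grid.values.astype(float), grid.nodata)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path) -> RasterGrid:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nrows, ncols):
        raise ValueError(f"grid shape {values.shape} does not match header")
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    return RasterGrid(values, cell, origin, nodata=header["nodata_value"])


# ---------------------------------------------------------------------------
# Aggregation to resource units
# ---------------------------------------------------------------------------

@dataclass
class RUStack:
    """Coarse (RU-scale) rasters produced by :func:`aggregate_to_ru`."""

    table: pd.DataFrame
    grids: dict[str, RasterGrid] = field(default_factory=dict)
    cover_classes: list[int] = field(default_factory=list)


def _block_view(a: np.ndarray, factor: int) -> np.ndarray:
    """Reshape (R*f, C*f) -> (R, C, f, f); trailing partial blocks dropped."""
    r = (a.shape[0] // factor) * factor
    c = (a.shape[1] // factor) * factor
    if (r, c) != a.shape:
        logger.warning(
            "grid %s not divisible by factor %d; dropping trailing cells",
            a.shape, factor,
        )
    a = a[:r, :c]
    return a.reshape(r // factor, factor, c // factor, factor).swapaxes(1, 2)


def aggregate_to_ru(
    cover: RasterGrid,
    continuous: dict[str, RasterGrid],
    factor: int = 3,
    nodata_frac: float = 0.5,
) -> RUStack:
    """Aggregate fine rasters to the resource-unit scale.

    ``cover`` is the categorical land-cover raster: each of its classes yields
    a proportion-in-RU layer (``prop_<class>``).  ``continuous`` layers are
    block-averaged over valid fine cells.  An RU whose fine block is more than
    ``nodata_frac`` nodata is dropped from the table (and nodata in the coarse
    grids).  Returns an :class:`RUStack` with a tidy one-row-per-RU table and
    the coarse grids.
    """
    if factor < 1:
        raise ValueError("aggregation factor must be a positive integer")
    for name, g in continuous.items():
        if g.cell_size != cover.cell_size:
            raise ValueError(f"mixed cell sizes: layer {name!r}")
        if not g.same_geometry(cover):
            raise ValueError(f"layer {name!r} is not co-registered with cover")

    cov_blocks = _block_view(cover.values, factor)            # (R,C,f,f)
    cov_valid = _block_view(cover.valid_mask(), factor)
    n_fine = factor * factor
    valid_counts = cov_valid.sum(axis=(2, 3))
    keep = valid_counts > nodata_frac * n_fine

    classes = sorted(
        int(c) for c in np.unique(cover.values[cover.valid_mask()])
    )
    coarse_cell = cover.cell_size * factor
    coarse_origin = cover.origin
    grids: dict[str, RasterGrid] = {}

    R, C = keep.shape
    nodata = DEFAULT_NODATA

    # determine final RU validity across all layers before filling any grid
    cont_blocks: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, g in continuous.items():
        blocks = _block_view(g.values.astype(float), factor)
        vmask = _block_view(g.valid_mask(), factor)
        cont_blocks[name] = (blocks, vmask)
        keep &= vmask.sum(axis=(2, 3)) > nodata_frac * n_fine

    prop = {}
    for cls in classes:
        hits = ((cov_blocks == cls) & cov_valid).sum(axis=(2, 3))
        p = np.where(keep, hits / np.maximum(valid_counts, 1), nodata)
        prop[cls] = p
        grids[f"prop_{cls}"] = RasterGrid(p, coarse_cell, coarse_origin, nodata)

    for name, (blocks, vmask) in cont_blocks.items():
        s = np.where(vmask, blocks, 0.0).sum(axis=(2, 3))
        cnt = vmask.sum(axis=(2, 3))
        mean = np.where(keep, s / np.maximum(cnt, 1), nodata)
        grids[name] = RasterGrid(mean, coarse_cell, coarse_origin, nodata)

    rows, cols = np.nonzero(keep)
    x = coarse_origin[0] + (cols + 0.5) * coarse_cell
    y = coarse_origin[1] - (rows + 0.5) * coarse_cell
    data = {"ru_id": rows * C + cols, "x": x, "y": y}
    for cls in classes:
        data[f"prop_{cls}"] = prop[cls][rows, cols]
    for name in continuous:
        data[name] = grids[name].values[rows, cols]
    table = pd.DataFrame(data)
    return RUStack(table=table, grids=grids, cover_classes=classes)


def dominant_class(table: pd.DataFrame, classes: list[int]) -> np.ndarray:
    """Dominant cover class per RU: max proportion, ties to smallest code."""
    props = table[[f"prop_{c}" for c in classes]].to_numpy()
    # argmax takes the first maximum; columns are sorted by class code
    return np.asarray(classes)[np.argmax(props, axis=1)]


# ---------------------------------------------------------------------------
# Distance layers
# ---------------------------------------------------------------------------

def distance_layer(feature_mask: RasterGrid) -> RasterGrid:
    """Euclidean distance (m) from each cell centre to the nearest feature cell.

    ``feature_mask`` is a 0/1 raster; the result is 0 on feature cells.
    """
    mask = feature_mask.values.astype(bool)
    if not mask.any():
        raise ValueError("feature mask contains no feature cells")
    dist = ndimage.distance_transform_edt(
        ~mask, sampling=feature_mask.cell_size
    )
    return RasterGrid(
        dist, feature_mask.cell_size, feature_mask.origin, feature_mask.nodata
    )


# ---------------------------------------------------------------------------
# Screening statistics
# ---------------------------------------------------------------------------

def pearson_screen(
    rut: pd.DataFrame,
    threshold: float = 0.7,
    columns: list[str] | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Pairwise Pearson correlations among EGV columns.

    Constant columns are excluded with a warning rather than producing NaN.
    Returns the correlation matrix and the list of pairs with |r| >= threshold.
    """
    if columns is None:
        columns = [c for c in rut.columns if c not in ("ru_id", "x", "y", "zone")]
    if len(rut) < 3:
        raise ValueError("need at least 3 resource units")
    data = rut[columns].to_numpy(dtype=float)
    sd = data.std(axis=0)
    const = sd == 0
    if const.any():
        dropped = [c for c, k in zip(columns, const) if k]
        warnings.warn(f"constant EGV columns excluded from correlation: {dropped}")
        columns = [c for c, k in zip(columns, const) if not k]
        data = data[:, ~const]
    if not columns:
        raise ValueError("no non-constant EGV columns")
    corr = np.corrcoef(data, rowvar=False)
    corr = np.atleast_2d(corr)
    mat = pd.DataFrame(corr, index=columns, columns=columns)
    flagged = [
        (columns[i], columns[j], float(corr[i, j]))
        for i in range(len(columns))
        for j in range(i + 1, len(columns))
        if abs(corr[i, j]) >= threshold
    ]
    return mat, flagged


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    loadings: pd.DataFrame        # EGV x component, unit-norm columns
    percent_variance: np.ndarray  # sums to 100
    scores: np.ndarray            # RU x component


def pca_egv(rut: pd.DataFrame, columns: list[str] | None = None) -> PCAResult:
    """Centred, scaled PCA of the EGV table (correlation-matrix PCA)."""
    if columns is None:
        columns = [c for c in rut.columns if c not in ("ru_id", "x", "y", "zone")]
    data = rut[columns].to_numpy(dtype=float)
    sd = data.std(axis=0, ddof=1)
    nonconst = sd > 0
    if nonconst.sum() < 2:
        raise ValueError("need at least 2 non-constant EGV columns for PCA")
    if not nonconst.all():
        warnings.warn("constant columns dropped from PCA")
        columns = [c for c, k in zip(columns, nonconst) if k]
        data, sd = data[:, nonconst], sd[nonconst]
    z = (data - data.mean(axis=0)) / sd
    pca = PCA()
    scores = pca.fit_transform(z)
    eig = pca.explained_variance_
    pct = 100.0 * eig / eig.sum()
    loadings = pd.DataFrame(
        pca.components_.T,
        index=columns,
        columns=[f"PC{i + 1}" for i in range(len(eig))],
    )
    return PCAResult(eig, loadings, pct, scores)


def morans_i(raster: RasterGrid, contiguity: str = "rook") -> float:
    """Global Moran's I with row-standardized contiguity weights.

    ``contiguity`` is ``"rook"`` (4-neighbour) or ``"queen"`` (8-neighbour).
    Nodata cells are excluded from both the statistic and the weights.
    """
    if contiguity not in ("rook", "queen"):
        raise ValueError("contiguity must be 'rook' or 'queen'")
    v = raster.values.astype(float)
    valid = raster.valid_mask()
    if valid.sum() < 2 or min(raster.n_rows, raster.n_cols) < 2:
        raise ValueError("need at least a 2x2 grid of valid cells")
    mean = v[valid].mean()
    z = np.where(valid, v - mean, 0.0)
    var = (z[valid] ** 2).sum()
    if var == 0:
        raise ValueError("constant raster: Moran's I undefined (zero variance)")

    shifts = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if contiguity == "queen":
        shifts += [(-1, -1), (-1, 1), (1, -1), (1, 1)]

    lag_sum = np.zeros_like(z)
    nbr_cnt = np.zeros_like(z)
    for dr, dc in shifts:
        zs = np.zeros_like(z)
        ms = np.zeros_like(z, dtype=bool)
        r0, r1 = max(dr, 0), min(dr, 0) or None
        c0, c1 = max(dc, 0), min(dc, 0) or None
        sr0, sr1 = max(-dr, 0), min(-dr, 0) or None
        sc0, sc1 = max(-dc, 0), min(-dc, 0) or None
        zs[r0:r1, c0:c1] = z[sr0:sr1, sc0:sc1]
        ms[r0:r1, c0:c1] = valid[sr0:sr1, sc0:sc1]
        lag_sum += np.where(ms, zs, 0.0)
        nbr_cnt += ms

    ok = valid & (nbr_cnt > 0)
    lag = np.where(ok, lag_sum / np.maximum(nbr_cnt, 1), 0.0)
    # row-standardized weights: sum of all weights = number of cells with
    # neighbours, so I = sum_i z_i * lag_i / variance * (n / W)
    n = valid.sum()
    W = ok.sum()
    return float(n / W * (z[ok] * lag[ok]).sum() / var)


def kappa_accuracy(cm: np.ndarray) -> tuple[float, float]:
    """Overall accuracy and Cohen's kappa from a confusion matrix.

    Rows are reference classes, columns mapped classes.
    """
    cm = np.asarray(cm, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any():
        raise ValueError("confusion matrix counts must be non-negative")
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    po = np.trace(cm) / total
    pe = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / total**2
    if pe >= 1.0:
        raise ValueError("chance agreement is 1 (single class): kappa undefined")
    kappa = (po - pe) / (1.0 - pe)
    return float(po), float(kappa)
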
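"""Raster stacks, presence records and covariate screening.

Rasters live on a single planar grid of square cells. Cells are half-open
squares ``[x0, x0+s) x [y0, y0+s)``; row 0 is the southernmost row (rows
index south to north), so ESRI ASCII grids -- which store rows north to
south -- are flipped on read and write. A cell masked (nodata) in any layer
is masked in every analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RasterStack",
    "PresenceRecords",
    "CovariateSpec",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_raster_stack",
    "write_raster_stack",
    "read_presences",
    "bin_to_cells",
    "filter_correlated",
    "standardize",
]


class RasterFormatError(ValueError):
    """Malformed or mutually inconsistent raster inputs."""


@dataclass
class RasterStack:
    """Named covariate layers sharing one rectangular cell grid.

    Attributes
    ----------
    layers
        Mapping of covariate name to a 2D float array of shape
        ``(n_rows, n_cols)``, row 0 south.
    cell_size_km
        Side length of a (square) cell, in km.
    origin
        ``(x, y)`` of the *lower-left cell centre*.
    nodata_mask
        Boolean array, True where a cell carries no data (in any layer).
    """

    layers: dict[str, np.ndarray]
    cell_size_km: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) > 1:
            raise RasterFormatError(f"layers have differing shapes: {shapes}")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.shape:
            raise RasterFormatError("nodata_mask shape differs from layers")

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.layers.values()))
        return first.shape

    @property
    def n_rows(self) -> int:
        return self.shape[0]

    @property
    def n_cols(self) -> int:
        return self.shape[1]

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_unmasked(self) -> int:
        return int((~self.nodata_mask).sum())

    # lower-left corner of the grid (edge, not centre)
    @property
    def ll_corner(self) -> tuple[float, float]:
        s = self.cell_size_km
        return (self.origin[0] - s / 2.0, self.origin[1] - s / 2.0)

    def point_to_cell(self, x: float | np.ndarray, y: float | np.ndarray):
        """Map point coordinates to (row, col) under the half-open convention.

        Returns integer arrays; callers must check :meth:`in_extent` first
        for points that may fall outside.
        """
        x0, y0 = self.ll_corner
        col = np.floor((np.asarray(x) - x0) / self.cell_size_km).astype(int)
        row = np.floor((np.asarray(y) - y0) / self.cell_size_km).astype(int)
        return row, col

    def in_extent(self, x, y) -> np.ndarray:
        x0, y0 = self.ll_corner
        s = self.cell_size_km
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= x0)
            & (x < x0 + s * self.n_cols)
            & (y >= y0)
            & (y < y0 + s * self.n_rows)
        )

    def cell_centres(self):
        """(xs, ys) 1D coordinate arrays of column / row cell centres."""
        x0, y0 = self.origin
        s = self.cell_size_km
        return x0 + s * np.arange(self.n_cols), y0 + s * np.arange(self.n_rows)

    def values(self, name: str) -> np.ndarray:
        """Layer values at unmasked cells, flattened (row-major)."""
        return self.layers[name][~self.nodata_mask]

    def copy(self) -> "RasterStack":
        return RasterStack(
            {k: v.copy() for k, v in self.layers.items()},
            self.cell_size_km,
            self.origin,
            self.nodata_mask.copy(),
        )

    def subset(self, names) -> "RasterStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return RasterStack(
            {n: self.layers[n] for n in names},
            self.cell_size_km,
            self.origin,
            self.nodata_mask.copy(),
        )

    def design_matrix(self, names) -> np.ndarray:
        """(n_unmasked, len(names)) matrix of covariate values."""
        return np.column_stack([self.values(n) for n in names])


@dataclass
class PresenceRecords:
    """Point records of species presence.

    ``source`` distinguishes incidental sightings (atlas-style records with
    a stated location precision) from designed field-survey detections.
    """

    x: np.ndarray
    y: np.ndarray
    source: np.ndarray = field(default=None)  # type: ignore[assignment]
    precision_m: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.x)
        if self.source is None:
            self.source = np.array(["incidental"] * n, dtype=object)
        else:
            self.source = np.asarray(self.source, dtype=object)
        if self.precision_m is None:
            self.precision_m = np.zeros(n)
        else:
            self.precision_m = np.asarray(self.precision_m, dtype=float)
        if not (len(self.y) == len(self.source) == len(self.precision_m) == n):
            raise ValueError("field lengths differ")

    def __len__(self) -> int:
        return len(self.x)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.x, "y": self.y, "precision_m": self.precision_m,
             "source": self.source}
        )

    @staticmethod
    def concat(parts: list["PresenceRecords"]) -> "PresenceRecords":
        return PresenceRecords(
            np.concatenate([p.x for p in parts]),
            np.concatenate([p.y for p in parts]),
            np.concatenate([p.source for p in parts]),
            np.concatenate([p.precision_m for p in parts]),
        )


@dataclass
class CovariateSpec:
    """Standardization constants, stored so the same affine map can be
    re-applied to prediction grids (no re-centering on new data)."""

    names: list[str]
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if np.any(self.sds <= 0):
            raise ValueError("standardization sds must be positive")


# ---------------------------------------------------------------- raster IO

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    """Read one ESRI ASCII grid; returns (values row-0-south, header dict).

    Nodata cells are returned as NaN.
    """
    path = Path(path)
    header: dict[str, float] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
                header[parts[0].lower()] = float(parts[1])
                n_header += 1
            else:
                break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise RasterFormatError(f"{path}: missing header keys {missing}")
    data = np.loadtxt(path, skiprows=n_header, ndmin=2)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise RasterFormatError(
            f"{path}: data shape {data.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    return data[::-1], header  # file stores north-first; flip to south-first


def write_ascii_grid(path, values: np.ndarray, cell_size: float,
                     ll_corner: tuple[float, float] = (0.0, 0.0),
                     nodata_value: float = -9999.0, fmt: str = "%.10g") -> None:
    values = np.asarray(values, dtype=float)
    out = np.where(np.isnan(values), nodata_value, values)
    with open(path, "w") as fh:
        fh.write(f"ncols {values.shape[1]}\n")
        fh.write(f"nrows {values.shape[0]}\n")
        fh.write(f"xllcorner {ll_corner[0]:.10g}\n")
        fh.write(f"yllcorner {ll_corner[1]:.10g}\n")
        fh.write(f"cellsize {cell_size:.10g}\n")
        fh.write(f"NODATA_value {nodata_value:.10g}\n")
        np.savetxt(fh, out[::-1], fmt=fmt)


def read_raster_stack(paths) -> RasterStack:
    """Read several ASCII grids into one stack, keyed by file stem.

    All files must agree on the grid header; any cell that is nodata in one
    layer is masked in the whole stack.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no raster paths given")
    layers: dict[str, np.ndarray] = {}
    ref_header: dict | None = None
    mask = None
    for p in paths:
        data, header = read_ascii_grid(p)
        key = {k: header[k] for k in _HEADER_KEYS}
        if ref_header is None:
            ref_header = key
        elif key != ref_header:
            raise RasterFormatError(
                f"{p}: grid header {key} differs from {ref_header}"
            )
        layers[p.stem] = data
        m = np.isnan(data)
        mask = m if mask is None else (mask | m)
    s = ref_header["cellsize"]
    origin = (ref_header["xllcorner"] + s / 2, ref_header["yllcorner"] + s / 2)
    for k in layers:  # propagate the union mask into every layer
        layers[k] = np.where(mask, np.nan, layers[k])
    return RasterStack(layers, cell_size_km=s, origin=origin, nodata_mask=mask)


def write_raster_stack(stack: RasterStack, directory, fmt: str = "%.10g") -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for name, vals in stack.layers.items():
        vals = np.where(stack.nodata_mask, np.nan, vals)
        p = directory / f"{name}.asc"
        write_ascii_grid(p, vals, stack.cell_size_km, stack.ll_corner, fmt=fmt)
        out.append(p)
    return out


# ------------------------------------------------------------- point data

def read_presences(path, max_precision_m: float = 1000.0) -> PresenceRecords:
    """Read presence points from CSV, dropping imprecise incidental records.

    Records whose stated location precision is ``max_precision_m`` or worse
    are discarded (atlas sightings are only usable when they can be placed
    in a single cell). Survey records carry precision 0 by convention.
    """
    df = pd.read_csv(path)
    required = {"x", "y", "precision_m"}
    missing = required - set(df.columns)
    if missing:
        raise RasterFormatError(f"{path}: missing columns {sorted(missing)}")
    if "source" not in df.columns:
        df["source"] = "incidental"
    if df.empty:
        warnings.warn(f"{path}: no presence records")
        return PresenceRecords(np.empty(0), np.empty(0),
                               np.empty(0, object), np.empty(0))
    keep = df["precision_m"].to_numpy(float) < max_precision_m
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropped %d of %d records with precision >= %g m",
                    n_drop, len(df), max_precision_m)
    df = df[keep]
    return PresenceRecords(
        df["x"].to_numpy(float), df["y"].to_numpy(float),
        df["source"].to_numpy(object), df["precision_m"].to_numpy(float),
    )


def write_presences(records: PresenceRecords, path) -> None:
    records.to_frame().to_csv(path, index=False)


def bin_to_cells(records: PresenceRecords, grid: RasterStack):
    """Bin presence points into grid cells.

    Returns ``(indicator, counts)``: a boolean per-cell presence indicator
    (multiple points in one cell count once) and the per-cell point counts.
    Points outside the grid extent are skipped with a warning.
    """
    counts = np.zeros(grid.shape, dtype=int)
    if len(records) == 0:
        return counts > 0, counts
    inside = grid.in_extent(records.x, records.y)
    if not inside.all():
        outside = np.flatnonzero(~inside)
        warnings.warn(
            f"{outside.size} point(s) outside grid extent skipped "
            f"(indices {outside[:10].tolist()}...)"
        )
    row, col = grid.point_to_cell(records.x[inside], records.y[inside])
    np.add.at(counts, (row, col), 1)
    return counts > 0, counts


# ------------------------------------------------- covariate screening

def filter_correlated(grid: RasterStack, r_threshold: float = 0.7,
                      names=None) -> list[str]:
    """Greedily remove covariates until no retained pair has |r_p| above
    ``r_threshold`` (Pearson, over unmasked cells).

    Among the worst-correlated pair, the member with the larger mean
    absolute correlation to the other retained covariates is dropped; ties
    keep the alphabetically first name. Constant layers are excluded up
    front (their correlation is undefined).
    """
    names = list(names) if names is not None else grid.names
    usable = []
    for n in names:
        v = grid.values(n)
        if np.std(v) == 0:
            warnings.warn(f"layer {n!r} is constant; excluded from screening")
        else:
            usable.append(n)
    if not usable:
        return []
    X = grid.design_matrix(usable)
    with np.errstate(invalid="ignore"):
        corr = np.abs(np.corrcoef(X, rowvar=False))
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 0.0)
    retained = list(range(len(usable)))
    while True:
        sub = corr[np.ix_(retained, retained)]
        if sub.size == 0 or sub.max() <= r_threshold:
            break
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        a, b = retained[i], retained[j]
        mean_a = corr[a, retained].sum() / max(len(retained) - 1, 1)
        mean_b = corr[b, retained].sum() / max(len(retained) - 1, 1)
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:  # tie: keep the alphabetically first name
            drop = max(a, b, key=lambda k: usable[k])
        retained.remove(drop)
    return [usable[k] for k in retained]


def standardize(grid: RasterStack, names=None,
                spec: CovariateSpec | None = None):
    """Standardize named layers to mean 0, sd 1 over unmasked cells.

    With ``spec`` given, its stored constants are applied instead (the
    contract for projecting a fitted model onto new rasters: no
    re-centering). Sample (n-1) standard deviation throughout.

    Returns ``(standardized RasterStack, CovariateSpec)``.
    """
    if spec is not None:
        names = spec.names
        means, sds = spec.means, spec.sds
    else:
        names = list(names) if names is not None else grid.names
        means = np.empty(len(names))
        sds = np.empty(len(names))
        for k, n in enumerate(names):
            v = grid.values(n)
            means[k] = v.mean()
            sds[k] = v.std(ddof=1) if v.size > 1 else 0.0
            if sds[k] == 0:
                raise ValueError(f"layer {n!r} has zero variance")
        spec = CovariateSpec(names, means, sds)
    unmasked = ~grid.nodata_mask
    layers = {}
    for k, n in enumerate(names):
        out = np.full(grid.shape, np.nan)
        out[unmasked] = (grid.layers[n][unmasked] - means[k]) / sds[k]
        layers[n] = out
    return (
        RasterStack(layers, grid.cell_size_km, grid.origin,
                    grid.nodata_mask.copy()),
        spec,
    )
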
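"""Suitability-stratified survey design.

Survey cells are chosen in two strata: a weighted stratum in which a cell
proposed uniformly at random is *retained with probability equal to its
habitat suitability index*, and a simple-random stratum drawn without
replacement from the remaining cells. Every selected cell receives faecal
pellet transects and one sign survey; a random subset additionally gets
camera traps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import RasterStack

__all__ = ["SurveyDesign", "select_cells", "assign_methods"]

_MAX_PROPOSALS = 10**6


@dataclass
class SurveyDesign:
    """Selected survey cells with stratum labels and per-method effort.

    ``cell_ids`` are flat row-major indices into the grid; ``stratum`` is
    ``"hsi-weighted"`` or ``"srs"`` per cell.
    """

    cell_ids: np.ndarray
    stratum: np.ndarray
    grid_shape: tuple[int, int]
    n_pellet: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_sign: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_camera: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=int)
        self.stratum = np.asarray(self.stratum, dtype=object)
        if len(np.unique(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cells in design")
        n = len(self.cell_ids)
        for name in ("n_pellet", "n_sign", "n_camera"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(n, dtype=int))
            else:
                setattr(self, name, np.asarray(getattr(self, name), dtype=int))

    def __len__(self) -> int:
        return len(self.cell_ids)

    def rows_cols(self):
        return np.unravel_index(self.cell_ids, self.grid_shape)

    def to_frame(self, grid: RasterStack | None = None) -> pd.DataFrame:
        rows, cols = self.rows_cols()
        df = pd.DataFrame(
            {"cell_id": self.cell_ids, "row": rows, "col": cols,
             "stratum": self.stratum, "n_pellet": self.n_pellet,
             "n_sign": self.n_sign, "n_camera": self.n_camera}
        )
        if grid is not None:
            xs, ys = grid.cell_centres()
            df.insert(3, "x", xs[cols])
            df.insert(4, "y", ys[rows])
        return df


def select_cells(hsi, n_weighted: int = 60, n_random: int = 20,
                 seed=None, nodata_mask=None) -> SurveyDesign:
    """Select survey cells: ``n_weighted`` by HSI-rejection sampling plus
    ``n_random`` by simple random sampling.

    The weighted stratum repeatedly proposes a uniformly random unselected
    cell and retains it with probability equal to its HSI, so the marginal
    inclusion probability is proportional to suitability. The SRS stratum
    is drawn without replacement from the cells not already selected.

    Parameters
    ----------
    hsi
        2D suitability map with values in [0, 1] (NaN = masked).
    """
    rng = np.random.default_rng(seed)
    hsi = np.asarray(hsi, dtype=float)
    flat = hsi.ravel()
    valid = np.isfinite(flat)
    if nodata_mask is not None:
        valid &= ~np.asarray(nodata_mask, dtype=bool).ravel()
    if np.nanmin(flat[valid]) < 0 or np.nanmax(flat[valid]) > 1:
        raise ValueError("HSI values must lie in [0, 1]")
    candidates = np.flatnonzero(valid)
    if int((flat[candidates] > 0).sum()) < n_weighted:
        raise ValueError(
            f"fewer than {n_weighted} cells with positive suitability"
        )
    selected: list[int] = []
    chosen = set()
    proposals = 0
    while len(selected) < n_weighted:
        proposals += 1
        if proposals > _MAX_PROPOSALS:
            raise RuntimeError("rejection sampling exceeded proposal budget")
        c = int(candidates[rng.integers(len(candidates))])
        if c in chosen:
            continue
        if rng.random() < flat[c]:
            selected.append(c)
            chosen.add(c)
    remaining = np.array([c for c in candidates if c not in chosen])
    srs = rng.choice(remaining, size=n_random, replace=False) if n_random else np.empty(0, int)
    cell_ids = np.concatenate([np.array(selected, int), np.asarray(srs, int)])
    stratum = np.array(["hsi-weighted"] * n_weighted + ["srs"] * n_random,
                       dtype=object)
    return SurveyDesign(cell_ids, stratum, hsi.shape)


def assign_methods(design: SurveyDesign, n_camera_cells: int = 40,
                   pellet_transects: int = 3, cameras: int = 2,
                   seed=None) -> SurveyDesign:
    """Assign survey effort: every cell gets ``pellet_transects`` faecal
    pellet transects and one sign survey; a simple random subset of
    ``n_camera_cells`` cells gets ``cameras`` camera traps."""
    n = len(design)
    if n_camera_cells > n:
        raise ValueError("more camera cells requested than cells in design")
    rng = np.random.default_rng(seed)
    n_camera = np.zeros(n, dtype=int)
    if n_camera_cells:
        idx = rng.choice(n, size=n_camera_cells, replace=False)
        n_camera[idx] = cameras
    return SurveyDesign(
        design.cell_ids.copy(), design.stratum.copy(), design.grid_shape,
        n_pellet=np.full(n, pellet_transects),
        n_sign=np.ones(n, dtype=int),
        n_camera=n_camera,
    )
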
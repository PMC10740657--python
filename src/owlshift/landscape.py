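"""Gridded landscape, habitat masks, buffering and patch statistics.

The spatial substrate is a regular raster of square cells.  Each cell
carries one ERU id, one model-zone id and an elevation.  Habitat maps are
boolean masks over that grid; "dissolved polygons" of a vector GIS workflow
correspond here to connected components of true cells.

Coordinates are planar metres.  Cell (0, 0) is the top-left cell and its
centre is the coordinate origin; x grows with column index, y grows with
row index (row-major).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .taxonomy import Taxonomy

__all__ = [
    "Landscape",
    "HabitatMap",
    "PatchStats",
    "buffer_mask",
    "patch_statistics",
    "extent_ha",
]

_ROOK = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_QUEEN = np.ones((3, 3), dtype=bool)


@dataclass
class Landscape:
    """Regular grid of cells with ERU, model zone and elevation layers.

    Parameters
    ----------
    eru : (nrows, ncols) array of str
        Per-cell ERU id.
    zone : (nrows, ncols) array of str
        Per-cell model-zone id (biogeographic constraint region).
    elevation : (nrows, ncols) array of float
        Per-cell elevation, metres.
    cell_size : float
        Cell edge length, metres (square cells).
    """

    eru: np.ndarray
    zone: np.ndarray
    elevation: np.ndarray
    cell_size: float

    def __post_init__(self) -> None:
        self.eru = np.asarray(self.eru)
        self.zone = np.asarray(self.zone)
        self.elevation = np.asarray(self.elevation, dtype=float)
        if not (self.eru.shape == self.zone.shape == self.elevation.shape):
            raise ValueError("eru, zone and elevation layers must share a shape")
        if self.eru.ndim != 2:
            raise ValueError("landscape layers must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.eru.shape

    @property
    def n_cells(self) -> int:
        return self.eru.size

    @property
    def cell_area_ha(self) -> float:
        """Cell area in hectares: (cell size in m)^2 / 10,000."""
        return self.cell_size ** 2 / 10_000.0

    @property
    def total_extent_ha(self) -> float:
        return self.n_cells * self.cell_area_ha

    def eru_ids_present(self) -> list[str]:
        return sorted(np.unique(self.eru).tolist())

    def zone_ids_present(self) -> list[str]:
        return sorted(np.unique(self.zone).tolist())

    def eru_mask(self, eru_ids) -> np.ndarray:
        """Boolean mask of cells whose ERU is in ``eru_ids``."""
        return np.isin(self.eru, list(eru_ids))

    def zone_mask(self, zone_ids) -> np.ndarray:
        return np.isin(self.zone, list(zone_ids))

    def cell_of_point(self, x: float, y: float) -> tuple[int, int] | None:
        """Cell index containing a point, or None if off the landscape.

        A point belongs to the cell whose centre is nearest (cells are
        squares centred on (j*cs, i*cs)).
        """
        cs = self.cell_size
        i = int(np.floor(y / cs + 0.5))
        j = int(np.floor(x / cs + 0.5))
        nr, nc = self.shape
        if 0 <= i < nr and 0 <= j < nc:
            return i, j
        return None

    def validate_against(self, taxonomy: Taxonomy) -> None:
        unknown = [e for e in self.eru_ids_present() if e not in taxonomy]
        if unknown:
            raise ValueError(f"landscape contains ERUs not in taxonomy: {unknown}")


@dataclass
class HabitatMap:
    """Boolean habitat mask over a landscape.

    ``provenance`` records whether the mask renders current (2017-style) or
    projected (2090) habitat; ``buffered`` whether a spatial uncertainty
    buffer has been applied.
    """

    landscape: Landscape
    mask: np.ndarray
    provenance: str = "current"  # {"current", "projected"}
    buffered: bool = False
    buffer_distance: float = 0.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.landscape.shape:
            raise ValueError("mask shape must match landscape shape")
        if self.provenance not in {"current", "projected"}:
            raise ValueError(f"unknown provenance {self.provenance!r}")


@dataclass(frozen=True)
class PatchStats:
    """Summary of the connected habitat patches of one mask.

    ``min_ha``/``max_ha``/``mean_ha``/``sd_ha`` are ``None`` (absent, not
    zero) when the mask is empty.  ``sd_ha`` is the sample SD (n-1) and 0.0
    for a single patch.
    """

    count: int
    areas_ha: tuple[float, ...]
    connectivity: str

    @property
    def min_ha(self) -> float | None:
        return min(self.areas_ha) if self.areas_ha else None

    @property
    def max_ha(self) -> float | None:
        return max(self.areas_ha) if self.areas_ha else None

    @property
    def mean_ha(self) -> float | None:
        return float(np.mean(self.areas_ha)) if self.areas_ha else None

    @property
    def sd_ha(self) -> float | None:
        if not self.areas_ha:
            return None
        if len(self.areas_ha) == 1:
            return 0.0
        return float(np.std(self.areas_ha, ddof=1))

    @property
    def total_ha(self) -> float:
        return float(sum(self.areas_ha))


def _disc_footprint(distance: float, cell_size: float) -> np.ndarray:
    """Disc of cell offsets whose centre-to-centre distance is <= distance.

    Membership is decided on squared distances, so cells at exactly the
    buffer distance are included without floating-point ambiguity.
    """
    r = int(distance // cell_size) + 1
    di, dj = np.mgrid[-r:r + 1, -r:r + 1]
    return (di * di + dj * dj) * (cell_size * cell_size) <= distance * distance


def buffer_mask(habitat: HabitatMap, distance: float) -> HabitatMap:
    """Buffer a habitat mask by a Euclidean distance (metres).

    A cell of the output is true iff its centre lies within ``distance`` of
    the centre of any true input cell (boundary included).  Used with the
    1 km default to absorb spatial uncertainty in both habitat mapping and
    occurrence records.
    """
    if distance < 0:
        raise ValueError("buffer distance must be >= 0")
    if habitat.buffered:
        raise ValueError("mask is already buffered")
    if distance == 0 or not habitat.mask.any():
        out = habitat.mask.copy()
    else:
        fp = _disc_footprint(distance, habitat.landscape.cell_size)
        out = ndimage.binary_dilation(habitat.mask, structure=fp)
    return HabitatMap(habitat.landscape, out, provenance=habitat.provenance,
                      buffered=True, buffer_distance=float(distance))


def patch_statistics(habitat: HabitatMap, connectivity: str = "rook") -> PatchStats:
    """Connected-component patch statistics of a habitat mask.

    ``connectivity`` is ``"rook"`` (shared edges, the analogue of polygon
    dissolve) or ``"queen"`` (edges or corners).  Areas are hectares.
    """
    if connectivity == "rook":
        structure = _ROOK
    elif connectivity == "queen":
        structure = _QUEEN
    else:
        raise ValueError(f"connectivity must be 'rook' or 'queen', got {connectivity!r}")
    labels, n = ndimage.label(habitat.mask, structure=structure)
    if n == 0:
        return PatchStats(0, (), connectivity)
    sizes = np.bincount(labels.ravel())[1:]  # skip background
    areas = tuple(float(s) * habitat.landscape.cell_area_ha for s in sizes)
    return PatchStats(int(n), areas, connectivity)


def extent_ha(habitat: HabitatMap) -> float:
    """Total habitat extent in hectares: true cells x cell area."""
    return float(habitat.mask.sum()) * habitat.landscape.cell_area_ha
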
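"""Subcellular region partitions and localization enrichment.

A cell footprint is split into three disjoint regions — membrane (a boundary
band), nucleoid (DNA-stained area) and cytoplasm (everything else) — and the
occupancy of single-molecule localizations is compared against region area:

    enrichment(region) = (n_region / n_cell) / (area_region / area_cell)

so a value of 1 means uniform occupancy, >1 means over-representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

REGIONS = ("membrane", "nucleoid", "cytoplasm")


@dataclass
class RegionMasks:
    """Pixelwise partition of a cell into membrane, nucleoid and cytoplasm.

    The three sub-region masks are pairwise disjoint and their union equals
    the cell mask exactly; this is validated at construction.
    """

    cell: np.ndarray
    nucleoid: np.ndarray
    membrane: np.ndarray
    cytoplasm: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        for name in ("cell",) + REGIONS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        shapes = {getattr(self, n).shape for n in ("cell",) + REGIONS}
        if len(shapes) != 1:
            raise ValueError("all masks must share one grid")
        union = self.membrane | self.nucleoid | self.cytoplasm
        if not np.array_equal(union, self.cell):
            raise ValueError("membrane ∪ nucleoid ∪ cytoplasm must equal cell")
        overlap = (
            (self.membrane & self.nucleoid)
            | (self.membrane & self.cytoplasm)
            | (self.nucleoid & self.cytoplasm)
        )
        if overlap.any():
            raise ValueError("region masks must be pairwise disjoint")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    def region(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def area_px(self, name: str) -> int:
        return int(self.region(name).sum())

    def area_um2(self, name: str) -> float:
        return self.area_px(name) * self.pixel_size**2


@dataclass
class EnrichmentResult:
    """Per-region localization counts, areas, enrichments and osd speeds."""

    counts: dict[str, int]
    areas_um2: dict[str, float]
    enrichment: dict[str, float | None]
    mean_osd_speed: dict[str, float | None]
    n_total_in_cell: int
    n_dropped_outside: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in REGIONS:
            rows.append(
                {
                    "region": r,
                    "count": self.counts[r],
                    "area_um2": self.areas_um2[r],
                    "enrichment": self.enrichment[r],
                    "mean_osd_speed_um_s": self.mean_osd_speed[r],
                }
            )
        return pd.DataFrame(rows)


def derive_regions(
    cell_mask: np.ndarray,
    nucleoid: np.ndarray | None,
    band_px: int = 1,
    pixel_size: float = 0.173,
) -> RegionMasks:
    """Build the membrane/nucleoid/cytoplasm partition from a cell mask.

    Parameters
    ----------
    cell_mask : bool array
        Footprint of the cell (e.g. segmented from a DIC image).
    nucleoid : array or None
        Either a boolean nucleoid mask, or a grayscale DNA-stain image that
        is Otsu-thresholded within the cell, or None for no nucleoid.
    band_px : int
        Membrane band thickness in pixels; the membrane is the cell minus
        its erosion by this many pixels.
    """
    cell = np.asarray(cell_mask, dtype=bool)
    if band_px < 1:
        warnings.warn("membrane band thinner than one pixel; widened to 1 px")
        band_px = 1
    interior = ndimage.binary_erosion(
        cell, structure=np.ones((3, 3), bool), iterations=band_px
    )
    membrane = cell & ~interior

    if nucleoid is None:
        nuc = np.zeros_like(cell)
    else:
        nucleoid = np.asarray(nucleoid)
        if nucleoid.shape != cell.shape:
            raise ValueError("nucleoid image must match the cell-mask grid")
        if nucleoid.dtype == bool:
            nuc = nucleoid.copy()
        else:
            inside = nucleoid[cell]
            if inside.size and inside.max() > inside.min():
                thr = threshold_otsu(inside)
                nuc = nucleoid > thr
            else:
                nuc = np.zeros_like(cell)
        if not (nuc & cell).any() and nuc.any():
            warnings.warn("nucleoid stain does not overlap the cell; empty nucleoid")
        nuc = nuc & interior
    cytoplasm = cell & ~membrane & ~nuc
    return RegionMasks(
        cell=cell,
        nucleoid=nuc,
        membrane=membrane,
        cytoplasm=cytoplasm,
        pixel_size=pixel_size,
    )


def _points_to_pixels(xy_um: np.ndarray, pixel_size: float, shape: tuple[int, int]):
    """Map (x, y) µm positions to (row, col) pixel indices; x → col, y → row."""
    xy = np.asarray(xy_um, dtype=float)
    col = np.floor(xy[:, 0] / pixel_size).astype(int)
    row = np.floor(xy[:, 1] / pixel_size).astype(int)
    ok = (row >= 0) & (row < shape[0]) & (col >= 0) & (col < shape[1])
    return row, col, ok


def compute_enrichment(
    localizations: pd.DataFrame | np.ndarray,
    masks: RegionMasks,
    steps: pd.DataFrame | None = None,
) -> EnrichmentResult:
    """Region enrichment of localizations, optionally with osd-speed means.

    Parameters
    ----------
    localizations : DataFrame with x_um/y_um columns, or (N, 2) array in µm.
    masks : RegionMasks
    steps : optional step table with x_mid/y_mid and speed_um_s columns;
        each step is assigned to the region containing its midpoint.

    Localizations falling outside the cell mask are dropped and counted in
    ``n_dropped_outside``.  A zero-area region has undefined enrichment,
    reported as None.
    """
    if isinstance(localizations, pd.DataFrame):
        xy = localizations[["x_um", "y_um"]].to_numpy()
    else:
        xy = np.asarray(localizations, dtype=float)
    row, col, ok = _points_to_pixels(xy, masks.pixel_size, masks.cell.shape)
    in_cell = np.zeros(len(xy), dtype=bool)
    in_cell[ok] = masks.cell[row[ok], col[ok]]
    n_total = int(in_cell.sum())
    n_dropped = len(xy) - n_total

    counts: dict[str, int] = {}
    areas: dict[str, float] = {}
    enr: dict[str, float | None] = {}
    cell_area = masks.area_px("cell")
    for r in REGIONS:
        m = masks.region(r)
        c = int(m[row[in_cell], col[in_cell]].sum())
        counts[r] = c
        areas[r] = masks.area_um2(r)
        a = masks.area_px(r)
        if a == 0 or n_total == 0:
            enr[r] = None
        else:
            enr[r] = (c / n_total) / (a / cell_area)

    speeds: dict[str, float | None] = {r: None for r in REGIONS}
    if steps is not None and len(steps):
        mid = steps[["x_mid", "y_mid"]].to_numpy()
        srow, scol, sok = _points_to_pixels(mid, masks.pixel_size, masks.cell.shape)
        v = steps["speed_um_s"].to_numpy()
        for r in REGIONS:
            m = masks.region(r)
            sel = sok.copy()
            sel[sok] = m[srow[sok], scol[sok]]
            speeds[r] = float(v[sel].mean()) if sel.any() else None

    return EnrichmentResult(
        counts=counts,
        areas_um2=areas,
        enrichment=enr,
        mean_osd_speed=speeds,
        n_total_in_cell=n_total,
        n_dropped_outside=n_dropped,
    )
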
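"""Histology-side spatial quantification mirroring the PET statistic.

Tissue sections are segmented upstream (e.g. in QuPath) into a tumor-core
mask; this module derives the *invasive margin* as the exterior band of a
stated physical width (100 μm by default) surrounding the core, assigns
phenotype-labelled cell centroids to regions, and computes per-region
densities, high-power-field (HPF) means, DAPI-nuclei-normalised
fractions, the regulatory-T-cell fraction, and the density-based
core-to-margin score that makes histology directly comparable to the PET
ratio.

When the staining panel lacks a direct CD4 marker, CD3+CD8- cells serve
as the CD4+ T cell proxy; the proxy is considered valid when
double-negative (CD3+CD4-CD8-) cells are under 10% of all T cells, and
samples failing that check are flagged, not dropped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import numpy as np
from scipy import ndimage

from .errors import (
    EmptyRegionError,
    InconsistentCountsError,
    InvalidParameterError,
)
from .spatial import CoreMarginScore, RegionMask, core_margin_ratio

#: Default invasive-margin width in μm.
MARGIN_WIDTH_UM = 100.0

#: Default high-power-field area in mm² (standard 40x field).
HPF_AREA_MM2 = 0.237

Marker = Literal["CD3", "CD8", "CD4", "FoxP3", "CD103", "CD20"]
RegionName = Literal["core", "margin", "outside"]


@dataclass(frozen=True)
class CellRecord:
    """A phenotype-labelled cell centroid in μm coordinates."""

    x: float
    y: float
    phenotype: frozenset[str]

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InvalidParameterError("cell coordinates must be finite")
        if not self.phenotype:
            raise InvalidParameterError("counted cells must have a phenotype")
        object.__setattr__(self, "phenotype", frozenset(self.phenotype))


@dataclass
class TissueRegions:
    """Tumor core and its surrounding invasive-margin band.

    Both masks share one pixel grid; ``pixel_size`` is the edge length of
    a pixel in μm. Row index maps to y, column index to x, with pixel
    centers at ``index * pixel_size``.
    """

    core: RegionMask
    invasive_margin: RegionMask
    pixel_size: float

    def __post_init__(self):
        if self.core.grid.shape != self.invasive_margin.grid.shape:
            raise InvalidParameterError("core and margin grids must match")
        if np.any(self.core.grid & self.invasive_margin.grid):
            raise InvalidParameterError("core and invasive margin must be disjoint")


@dataclass
class RegionCounts:
    """Phenotype tallies for one tissue region.

    ``counts`` maps a phenotype-class key (e.g. ``"CD3+CD8-"``) to a cell
    count; ``area`` is in mm². ``hpf_count`` and ``dapi_nuclei`` are
    optional extra normalisers.
    """

    region: str
    counts: dict[str, int] = field(default_factory=dict)
    area: Optional[float] = None
    hpf_count: Optional[int] = None
    dapi_nuclei: Optional[int] = None

    def __post_init__(self):
        if any(v < 0 for v in self.counts.values()):
            raise InvalidParameterError("counts must be >= 0")

    def total(self, key: str) -> int:
        return int(self.counts.get(key, 0))


@dataclass(frozen=True)
class CD4ProxyResult:
    """CD3+CD8- proxy CD4 count with the double-negative QC verdict."""

    cd4_proxy_count: int
    dn_fraction: Optional[float]
    qc: Literal["pass", "fail", "indeterminate"]


def build_tissue_regions(
    core_mask: RegionMask,
    margin_width: float = MARGIN_WIDTH_UM,
    pixel_size: Optional[float] = None,
) -> TissueRegions:
    """Derive the invasive margin as an exterior band around the core.

    The margin is the core dilated by ``margin_width`` in physical units
    minus the core itself: every margin pixel lies within ``margin_width``
    (μm) of the core boundary, measured by Euclidean distance between
    pixel centers.
    """
    if not core_mask:
        raise EmptyRegionError("core mask is empty")
    if margin_width < 0:
        raise InvalidParameterError(f"margin_width must be >= 0, got {margin_width}")
    if core_mask.grid.ndim != 2:
        raise InvalidParameterError("tissue regions are 2D")
    if pixel_size is None:
        if len(set(core_mask.spacing)) != 1:
            raise InvalidParameterError(
                "anisotropic pixels need an explicit pixel_size"
            )
        pixel_size = core_mask.spacing[0]
    if 0 < margin_width < pixel_size:
        warnings.warn(
            f"margin_width ({margin_width} um) is below the pixel size "
            f"({pixel_size} um); the margin band may be empty",
            stacklevel=2,
        )
    if margin_width == 0:
        margin_grid = np.zeros_like(core_mask.grid)
    else:
        dist = ndimage.distance_transform_edt(
            ~core_mask.grid, sampling=core_mask.spacing
        )
        margin_grid = (dist <= margin_width) & ~core_mask.grid
    margin = RegionMask(margin_grid, label="margin", spacing=core_mask.spacing)
    return TissueRegions(
        core=RegionMask(core_mask.grid, label="core", spacing=core_mask.spacing),
        invasive_margin=margin,
        pixel_size=float(pixel_size),
    )


def _phenotype_key(phenotype: frozenset[str]) -> str:
    """Canonical class key for a phenotype set, e.g. ``CD3+CD8-`` T helper."""
    if "CD3" in phenotype:
        if "CD8" in phenotype:
            return "CD3+CD8+"
        return "CD3+CD8-"
    if "CD20" in phenotype:
        return "CD20+"
    return "+".join(sorted(phenotype)) + "+"


def assign_cells(
    cells: Iterable[CellRecord], regions: TissueRegions
) -> dict[RegionName, RegionCounts]:
    """Assign cell centroids to core, margin, or outside; tally phenotypes.

    Membership uses pixel-center containment: a centroid belongs to the
    region of its nearest pixel center. Centroids on a shared boundary
    resolve to the core (the nearest-pixel rounding is deterministic and
    the core is tested first). Cells outside the image bounds are counted
    as outside with a warning.
    """
    shape = regions.core.grid.shape
    sy, sx = regions.core.spacing
    result: dict[RegionName, RegionCounts] = {
        "core": RegionCounts(region="core", area=regions.core.physical_size / 1e6),
        "margin": RegionCounts(
            region="margin", area=regions.invasive_margin.physical_size / 1e6
        ),
        "outside": RegionCounts(region="outside"),
    }
    n_out_of_bounds = 0
    for cell in cells:
        i = int(round(cell.y / sy))
        j = int(round(cell.x / sx))
        if not (0 <= i < shape[0] and 0 <= j < shape[1]):
            n_out_of_bounds += 1
            where: RegionName = "outside"
        elif regions.core.grid[i, j]:
            where = "core"
        elif regions.invasive_margin.grid[i, j]:
            where = "margin"
        else:
            where = "outside"
        tallies = result[where].counts
        key = _phenotype_key(cell.phenotype)
        tallies[key] = tallies.get(key, 0) + 1
        # marker-level tallies for downstream fractions
        for marker in cell.phenotype:
            mkey = f"{marker}+"
            tallies[mkey] = tallies.get(mkey, 0) + 1
        if cell.phenotype >= {"CD3", "FoxP3"}:
            tallies["CD3+FoxP3+"] = tallies.get("CD3+FoxP3+", 0) + 1
        if cell.phenotype >= {"CD4", "FoxP3"}:
            tallies["CD4+FoxP3+"] = tallies.get("CD4+FoxP3+", 0) + 1
        if cell.phenotype >= {"CD3", "CD4"}:
            tallies["CD3+CD4+"] = tallies.get("CD3+CD4+", 0) + 1
        if "CD3" in cell.phenotype and not cell.phenotype & {"CD4", "CD8"}:
            tallies["CD3+CD4-CD8-"] = tallies.get("CD3+CD4-CD8-", 0) + 1
    if n_out_of_bounds:
        warnings.warn(
            f"{n_out_of_bounds} cell(s) outside image bounds counted as outside",
            stacklevel=2,
        )
    return result


def cd4_proxy_counts(counts: RegionCounts) -> CD4ProxyResult:
    """CD4+ T cell count via the CD3+CD8- proxy, with the <10% DN check.

    The proxy count is the CD3+CD8- tally. QC passes when double-negative
    cells (CD3+ but neither CD4+ nor CD8+) are under 10% of all CD3+
    cells; with no CD3+ cells the QC is indeterminate. A failing sample
    is flagged, never dropped.
    """
    cd3 = counts.total("CD3+")
    proxy = counts.total("CD3+CD8-")
    if cd3 == 0:
        return CD4ProxyResult(cd4_proxy_count=proxy, dn_fraction=None, qc="indeterminate")
    dn = counts.counts.get("CD3+CD4-CD8-")
    if dn is None:
        # derive from marker tallies: CD3+ cells carrying neither CD4 nor CD8
        cd3cd8 = counts.total("CD3+CD8+")
        cd3cd4 = counts.total("CD3+CD4+")
        if "CD3+CD4+" not in counts.counts:
            # no direct CD4 channel: count CD3 singletons if recorded,
            # otherwise the DN fraction cannot be derived
            raise InvalidParameterError(
                "counts lack a double-negative tally ('CD3+CD4-CD8-') and a "
                "direct CD4 channel; cannot evaluate the QC rule"
            )
        dn = cd3 - cd3cd8 - cd3cd4
    dn_fraction = dn / cd3
    return CD4ProxyResult(
        cd4_proxy_count=proxy,
        dn_fraction=dn_fraction,
        qc="pass" if dn_fraction < 0.10 else "fail",
    )


def region_density(counts: RegionCounts, phenotype: str = "CD3+CD8-") -> dict:
    """Cell density for one phenotype class: cells/mm², and cells/HPF.

    Returns a dict with ``cells_per_mm2`` (requires ``area``) and, when
    ``hpf_count`` is present, ``cells_per_hpf``. Counting fewer than 10
    HPFs triggers a warning (the conventional minimum).
    """
    n = counts.total(phenotype)
    out: dict[str, float] = {"count": n}
    if counts.area is not None:
        if not counts.area > 0:
            raise InvalidParameterError(f"area must be > 0, got {counts.area}")
        out["cells_per_mm2"] = n / counts.area
    if counts.hpf_count is not None:
        if counts.hpf_count <= 0:
            raise InvalidParameterError("hpf_count must be > 0")
        if counts.hpf_count < 10:
            warnings.warn(
                f"only {counts.hpf_count} HPFs counted (convention is >= 10)",
                stacklevel=2,
            )
        out["cells_per_hpf"] = n / counts.hpf_count
    if "cells_per_mm2" not in out and "cells_per_hpf" not in out:
        raise InvalidParameterError(
            "RegionCounts has neither area nor hpf_count; no density computable"
        )
    return out


def normalize_to_nuclei(count: int, dapi_nuclei: int) -> float:
    """Fraction of positive cells among DAPI-counted nuclei."""
    if dapi_nuclei <= 0:
        raise InvalidParameterError(f"dapi_nuclei must be > 0, got {dapi_nuclei}")
    return count / dapi_nuclei


def treg_fraction(cd4_foxp3: int, cd4: int) -> float:
    """Fraction of CD4+FoxP3+ regulatory T cells among CD4+ cells.

    Returns NaN when there are no CD4+ cells (undefined, flagged by the
    caller via ``math.isnan``).
    """
    if cd4_foxp3 < 0 or cd4 < 0:
        raise InvalidParameterError("counts must be >= 0")
    if cd4_foxp3 > cd4:
        raise InconsistentCountsError(
            f"CD4+FoxP3+ count ({cd4_foxp3}) exceeds CD4+ count ({cd4})"
        )
    if cd4 == 0:
        return math.nan
    return cd4_foxp3 / cd4


def density_core_margin_score(
    core: RegionCounts, margin: RegionCounts, phenotype: str = "CD3+CD8-"
) -> CoreMarginScore:
    """Core-to-margin score on cell densities, comparable to the PET ratio."""
    core_density = region_density(core, phenotype)["cells_per_mm2"]
    margin_density = region_density(margin, phenotype)["cells_per_mm2"]
    return core_margin_ratio(core_density, margin_density, analysis_mode="slice2d")
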
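"""VOI geometry and the core-to-margin spatial uptake statistic.

The central spatial statistic of the pipeline: a tumor region of interest
is contracted about its centroid to 50% of its diameter to define the
*tumor core*; the remainder of the tumor is the *margin*. Mean tracer
uptake (%ID/ml) is computed per region and summarised as the
core-to-margin ratio, which separates "T cell-enriched" tumors (signal in
the core) from "excluded" (signal at the periphery) and "deserted"
(globally low) ones.

Geometry conventions
--------------------
* Masks are voxel-center based: a voxel belongs to a region iff its
  center does. Voxel centers sit at ``index * spacing`` in physical mm.
* "50% of the diameter" is an affine contraction of the tumor contour
  about its centroid by ``scale`` per axis, rasterized by the pull-back
  rule: voxel center ``x`` is in the core iff
  ``centroid + (x - centroid) / scale`` falls inside the original tumor
  mask (nearest-voxel lookup). This is exact for any star-shaped region
  and gives a core area of ``scale**2`` (2D) of the tumor for convex
  shapes.
* Contraction happens in physical coordinates, so anisotropic voxels do
  not bias the core shape.
* The default analysis mode is a single centered axial slice
  (``slice2d``), matching quantification on a centered cross section of
  the image; full-volume contraction (``volume3d``) is also provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateCoreError,
    EmptyRegionError,
    InvalidParameterError,
)
from .radiometrics import (
    ActivityVolume,
    InjectionContext,
    decay_correct,
    hours_between,
    percent_id_per_ml,
)

AnalysisMode = Literal["slice2d", "volume3d"]

#: Axis along which axial slices are taken for 3D grids.
SLICE_AXIS = 0


@dataclass
class RegionMask:
    """A boolean mask aligned to a parent volume or tissue image.

    Parameters
    ----------
    grid : ndarray of bool, 2D or 3D
        True where the voxel/pixel belongs to the region.
    label : str
        One of ``tumor``, ``core``, ``margin``, ``organ`` (free-form
        labels are accepted for organ names).
    spacing : tuple of float
        Per-axis voxel size in mm (or other consistent physical unit),
        same order as the array axes.
    """

    grid: np.ndarray
    label: str = "tumor"
    spacing: tuple[float, ...] = ()

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=bool)
        if not self.spacing:
            self.spacing = (1.0,) * self.grid.ndim
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.grid.ndim:
            raise InvalidParameterError(
                f"spacing has {len(self.spacing)} entries for a "
                f"{self.grid.ndim}-D mask"
            )
        if any(s <= 0 for s in self.spacing):
            raise InvalidParameterError(f"all spacing must be > 0, got {self.spacing}")

    @property
    def size(self) -> int:
        """Number of member voxels."""
        return int(self.grid.sum())

    @property
    def voxel_volume(self) -> float:
        """Physical volume (or area, in 2D) of a single voxel."""
        return float(np.prod(self.spacing))

    @property
    def physical_size(self) -> float:
        """Total physical volume/area of the region."""
        return self.size * self.voxel_volume

    def __bool__(self) -> bool:
        return self.size > 0


@dataclass
class CoreMarginScore:
    """Paired core/margin mean uptakes and their ratio.

    ``ratio`` is ``core_mean / margin_mean``; when the margin mean is zero
    the ratio is NaN and ``undefined_ratio`` is set instead of raising, so
    batch processing can carry the flag into reports.
    """

    core_mean: float
    margin_mean: float
    ratio: float
    analysis_mode: AnalysisMode = "slice2d"
    slice_index: Optional[int] = None
    undefined_ratio: bool = False


def mask_centroid(mask: RegionMask) -> np.ndarray:
    """Spacing-weighted center of mass of the mask, in physical mm."""
    if not mask:
        raise EmptyRegionError(f"mask {mask.label!r} is empty")
    com = ndimage.center_of_mass(mask.grid)
    return np.asarray(com) * np.asarray(mask.spacing)


def central_axial_slice(mask: RegionMask, axis: int = SLICE_AXIS) -> int:
    """Axial index nearest the mask's center of mass along ``axis``.

    Equivalent to per-slice area weighting: the returned index is
    ``round(sum(k * area_k) / sum(area_k))``.
    """
    if not mask:
        raise EmptyRegionError(f"mask {mask.label!r} is empty")
    com = ndimage.center_of_mass(mask.grid)
    return int(round(com[axis]))


def _pullback_core(
    grid: np.ndarray, spacing: tuple[float, ...], scale: float
) -> np.ndarray:
    """Contract a binary mask about its centroid by ``scale`` per axis.

    Each voxel center x maps to ``c + (x - c) / scale``; the voxel is in
    the contracted region iff the mapped point (nearest voxel) lies in the
    original mask. Operates on whatever dimensionality ``grid`` has.
    """
    com_idx = np.asarray(ndimage.center_of_mass(grid))  # index units
    idx = np.indices(grid.shape, dtype=float)
    # physical pull-back reduces to index space because spacing cancels:
    # (i*s - c*s)/scale / s = (i - c)/scale
    mapped = [com_idx[a] + (idx[a] - com_idx[a]) / scale for a in range(grid.ndim)]
    mapped_idx = [np.rint(m).astype(int) for m in mapped]
    inside = np.ones(grid.shape, dtype=bool)
    for a, m in enumerate(mapped_idx):
        inside &= (m >= 0) & (m < grid.shape[a])
    core = np.zeros(grid.shape, dtype=bool)
    sel = tuple(np.clip(m, 0, grid.shape[a] - 1) for a, m in enumerate(mapped_idx))
    core[inside] = grid[sel][inside]
    return core


def derive_core_margin(
    tumor: RegionMask,
    scale: float = 0.5,
    mode: AnalysisMode = "slice2d",
) -> tuple[RegionMask, RegionMask]:
    """Split a tumor mask into a centered core and the margin remainder.

    The core is the tumor contour affinely contracted about its centroid
    by ``scale`` per in-plane axis — both in-plane axes in ``slice2d``
    mode (on the centered axial slice), all axes in ``volume3d`` mode.
    The margin is the set difference tumor minus core, restricted to the
    analysis slice in ``slice2d`` mode, so core and margin partition the
    analysed tumor region.

    Returns ``(core, margin)`` as :class:`RegionMask` objects on the same
    grid as the input.
    """
    if not tumor:
        raise EmptyRegionError("tumor mask is empty")
    if not (0 < scale < 1):
        raise InvalidParameterError(f"scale must be in (0, 1), got {scale}")
    grid = tumor.grid
    if grid.ndim == 2 or mode == "volume3d":
        core_grid = _pullback_core(grid, tumor.spacing, scale)
        analysed = grid
        slice_index = None
    elif mode == "slice2d":
        k = central_axial_slice(tumor)
        plane = grid[k]
        if not plane.any():
            raise EmptyRegionError(f"tumor is empty on its central slice {k}")
        spacing2d = tuple(s for a, s in enumerate(tumor.spacing) if a != SLICE_AXIS)
        core_plane = _pullback_core(plane, spacing2d, scale)
        core_grid = np.zeros_like(grid)
        core_grid[k] = core_plane
        analysed = np.zeros_like(grid)
        analysed[k] = plane
        slice_index = k
    else:
        raise InvalidParameterError(f"unknown analysis mode {mode!r}")
    if not core_grid.any():
        raise DegenerateCoreError(
            f"core emptied after contraction by {scale} "
            f"(tumor has {int(grid.sum())} voxels on the analysis region); "
            "the tumor is too small for the grid resolution"
        )
    margin_grid = analysed & ~core_grid
    core = RegionMask(core_grid, label="core", spacing=tumor.spacing)
    margin = RegionMask(margin_grid, label="margin", spacing=tumor.spacing)
    if slice_index is not None:
        core.slice_index = slice_index  # type: ignore[attr-defined]
        margin.slice_index = slice_index  # type: ignore[attr-defined]
    return core, margin


def region_mean_uptake(
    volume: ActivityVolume, region: RegionMask, ctx: InjectionContext
) -> float:
    """Decay-corrected mean region uptake in %ID/ml.

    Averages the activity concentration over the region, back-corrects it
    to injection time, and normalises to the injected dose.
    """
    if not region:
        raise EmptyRegionError(f"region {region.label!r} is empty")
    if region.grid.shape != volume.voxels.shape:
        raise InvalidParameterError(
            f"region shape {region.grid.shape} does not match volume "
            f"shape {volume.voxels.shape}"
        )
    mean_conc = float(volume.voxels[region.grid].mean())
    elapsed = hours_between(volume.scan_time, ctx.injection_time)
    corrected = decay_correct(mean_conc, elapsed, ctx.isotope_half_life)
    return percent_id_per_ml(corrected, ctx)


def core_margin_ratio(
    core_mean: float,
    margin_mean: float,
    analysis_mode: AnalysisMode = "slice2d",
    slice_index: Optional[int] = None,
) -> CoreMarginScore:
    """Build a :class:`CoreMarginScore` from paired region means.

    A zero margin mean yields a NaN ratio with the ``undefined_ratio``
    flag set rather than an exception.
    """
    if core_mean < 0 or margin_mean < 0:
        raise InvalidParameterError(
            f"region means must be >= 0, got core={core_mean}, margin={margin_mean}"
        )
    if margin_mean == 0:
        return CoreMarginScore(
            core_mean=core_mean,
            margin_mean=margin_mean,
            ratio=math.nan,
            analysis_mode=analysis_mode,
            slice_index=slice_index,
            undefined_ratio=True,
        )
    return CoreMarginScore(
        core_mean=core_mean,
        margin_mean=margin_mean,
        ratio=core_mean / margin_mean,
        analysis_mode=analysis_mode,
        slice_index=slice_index,
    )


def score_volume(
    volume: ActivityVolume,
    tumor: RegionMask,
    ctx: InjectionContext,
    scale: float = 0.5,
    mode: AnalysisMode = "slice2d",
) -> CoreMarginScore:
    """Convenience composition: derive regions, measure, and score."""
    core, margin = derive_core_margin(tumor, scale=scale, mode=mode)
    slice_index = getattr(core, "slice_index", None)
    core_mean = region_mean_uptake(volume, core, ctx)
    margin_mean = (
        region_mean_uptake(volume, margin, ctx) if margin else 0.0
    )
    return core_margin_ratio(core_mean, margin_mean, mode, slice_index)
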
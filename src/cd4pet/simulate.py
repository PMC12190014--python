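"""Synthetic-data generators for every input the pipeline consumes.

Each generator returns its ground truth alongside the data so that every
downstream stage has a parameter-recovery test: PET tumor phantoms with
enriched/excluded/deserted uptake patterns under Gaussian PSF blur and
Poisson counting noise, gamma-counter biodistribution records built
around a dose standard, core/margin cell point patterns with a
regulatory-T-cell subfraction, responder/nonresponder tumor-growth
cohorts, and a full PET-guided adaptive-trial cohort with latent truth.

Reproducibility: every generator is a pure function of its seed. A
single root seed can drive an end-to-end run through :func:`stage_seed`,
which derives per-stage seeds as ``root + stage offset`` so stages stay
independently re-runnable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InvalidParameterError
from .histology import CellRecord, TissueRegions, build_tissue_regions
from .radiometrics import (
    CU64_HALF_LIFE_H,
    ActivityVolume,
    GammaRecord,
    InjectionContext,
)
from .spatial import RegionMask, _pullback_core

PatternName = Literal["uniform", "enriched", "excluded", "deserted"]

#: Per-stage seed offsets added to a root seed (kept below 2**31 by the
#: caller; offsets are small).
STAGE_OFFSETS = {
    "phantom": 11,
    "gamma": 23,
    "cells": 37,
    "growth": 51,
    "trial": 67,
}


def stage_seed(root_seed: int, stage: str) -> int:
    """Derive a per-stage seed from a root seed (documented offsets)."""
    if stage not in STAGE_OFFSETS:
        raise InvalidParameterError(f"unknown stage {stage!r}")
    return (int(root_seed) + STAGE_OFFSETS[stage]) % (2**31)


# canonical uptake levels (%ID/ml-equivalent) per spatial pattern,
# anchored to the observed range of tumor uptakes (~0.2-0.6 %ID/ml)
_PATTERN_UPTAKES: dict[str, tuple[float, float]] = {
    "uniform": (0.40, 0.40),
    "enriched": (0.60, 0.30),
    "excluded": (0.20, 0.50),
    "deserted": (0.10, 0.10),
}


@dataclass
class PhantomSpec:
    """Specification of a spherical-tumor PET phantom.

    ``core_uptake``/``margin_uptake`` default to canonical levels for the
    chosen pattern; ``noise_scale`` is the expected Poisson counts per
    voxel at a concentration of 1 %ID/ml-equivalent (0 disables noise).
    """

    pattern: PatternName = "uniform"
    tumor_radius: float = 4.0  # mm
    core_uptake: Optional[float] = None  # %ID/ml-equivalent
    margin_uptake: Optional[float] = None
    background_uptake: float = 0.05
    psf_sigma: float = 0.0  # mm; 0 disables blur
    noise_scale: float = 0.0  # expected counts/voxel per %ID/ml
    seed: int = 0
    # odd grid: the sphere is voxel-centered, so the scale-0.5 pull-back
    # maps voxel centers to exact voxel centers and the core geometry is
    # rasterization-exact
    grid_shape: tuple[int, int, int] = (49, 49, 49)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    core_scale: float = 0.5
    injected_activity: float = 1.0e7  # Bq
    scan_delay_h: float = 3.0  # scan time after injection

    def __post_init__(self):
        if self.pattern not in _PATTERN_UPTAKES:
            raise InvalidParameterError(f"unknown pattern {self.pattern!r}")
        default_core, default_margin = _PATTERN_UPTAKES[self.pattern]
        if self.core_uptake is None:
            self.core_uptake = default_core
        if self.margin_uptake is None:
            self.margin_uptake = default_margin
        for name in (
            "tumor_radius",
            "core_uptake",
            "margin_uptake",
            "background_uptake",
            "psf_sigma",
            "noise_scale",
        ):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        half_extent = min(
            n * s / 2.0 for n, s in zip(self.grid_shape, self.spacing)
        )
        if self.tumor_radius >= half_extent:
            raise InvalidParameterError(
                f"tumor radius {self.tumor_radius} mm does not fit the "
                f"{self.grid_shape} grid at spacing {self.spacing}"
            )


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    core_uptake: float
    margin_uptake: float
    background_uptake: float
    expected_ratio: float
    true_core: RegionMask
    ctx: InjectionContext


def make_phantom(
    spec: PhantomSpec,
) -> tuple[ActivityVolume, RegionMask, PhantomTruth]:
    """Generate a spherical-tumor activity volume with known truth.

    The tumor is a sphere centered on the grid; voxels within
    ``core_scale * tumor_radius`` of the center carry the core
    concentration, the rest of the tumor the margin concentration, and
    everything outside the background. The concentration field is
    optionally blurred with an isotropic Gaussian PSF and degraded with
    Poisson counting noise, then expressed in Bq/ml decayed to the scan
    time so the quantification chain (decay correction + dose
    normalisation) round-trips the %ID/ml-equivalent truth.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    spacing = np.asarray(spec.spacing)
    center = (np.asarray(shape) - 1) / 2.0 * spacing
    idx = np.indices(shape, dtype=float)
    coords = [idx[a] * spacing[a] - center[a] for a in range(3)]
    r = np.sqrt(sum(c**2 for c in coords))
    tumor_grid = r <= spec.tumor_radius
    # the true core uses the same centroid pull-back geometry as the
    # analysis, so noiseless recovery of the core:margin contrast is exact
    core_grid = _pullback_core(tumor_grid, spec.spacing, spec.core_scale)

    conc = np.full(shape, spec.background_uptake, dtype=float)  # %ID/ml units
    conc[tumor_grid] = spec.margin_uptake
    conc[core_grid] = spec.core_uptake

    if spec.psf_sigma > 0:
        conc = ndimage.gaussian_filter(conc, sigma=spec.psf_sigma / spacing)
    if spec.noise_scale > 0:
        expected = np.clip(conc, 0, None) * spec.noise_scale
        conc = rng.poisson(expected).astype(float) / spec.noise_scale

    ctx = InjectionContext(
        injected_activity=spec.injected_activity, injection_time=0.0
    )
    decay_factor = 2.0 ** (-spec.scan_delay_h / ctx.isotope_half_life)
    voxels = conc / 100.0 * spec.injected_activity * decay_factor
    volume = ActivityVolume(
        voxels=voxels, spacing=tuple(spacing), scan_time=spec.scan_delay_h
    )
    tumor = RegionMask(tumor_grid, label="tumor", spacing=tuple(spacing))
    truth = PhantomTruth(
        core_uptake=spec.core_uptake,
        margin_uptake=spec.margin_uptake,
        background_uptake=spec.background_uptake,
        expected_ratio=(
            spec.core_uptake / spec.margin_uptake
            if spec.margin_uptake > 0
            else math.inf
        ),
        true_core=RegionMask(core_grid, label="core", spacing=tuple(spacing)),
        ctx=ctx,
    )
    return volume, tumor, truth


@dataclass
class GrowthCohort:
    """Simulated tumor-growth curves with latent responder labels."""

    volumes: dict[str, dict[float, float]]
    responder_truth: dict[str, bool]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subject_id": sid, "day": day, "volume_mm3": v}
            for sid, curve in self.volumes.items()
            for day, v in sorted(curve.items())
        ]
        return pd.DataFrame(rows)


def make_growth_cohort(
    n: int = 13,
    responder_fraction: float = 7 / 13,
    k_responder: float = -0.05,  # per day; V7/V0 = exp(7k) ~ 0.70
    k_nonresponder: float = 0.08,  # V7/V0 ~ 1.75
    noise_sigma: float = 0.10,  # lognormal measurement noise
    v0_mm3: float = 100.0,
    days: tuple[float, ...] = (0.0, 3.0, 7.0),
    seed: int = 0,
) -> GrowthCohort:
    """Simulate responder/nonresponder exponential tumor growth.

    Each subject is a responder with probability ``responder_fraction``;
    responders regress and nonresponders grow exponentially, with
    multiplicative lognormal measurement noise per timepoint. Defaults
    mirror a small checkpoint-therapy cohort (13 mice, 7 responders in
    expectation).
    """
    if not (0 <= responder_fraction <= 1):
        raise InvalidParameterError("responder_fraction must be in [0, 1]")
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    volumes: dict[str, dict[float, float]] = {}
    truth: dict[str, bool] = {}
    for i in range(n):
        sid = f"S{i + 1:03d}"
        is_resp = bool(rng.random() < responder_fraction)
        k = k_responder if is_resp else k_nonresponder
        v0 = v0_mm3 * math.exp(rng.normal(0.0, 0.2))
        curve = {}
        for day in days:
            noise = math.exp(rng.normal(0.0, noise_sigma)) if noise_sigma > 0 else 1.0
            curve[day] = v0 * math.exp(k * day) * noise
        volumes[sid] = curve
        truth[sid] = is_resp
    return GrowthCohort(volumes=volumes, responder_truth=truth)


#: Default per-region phenotype densities in cells/mm², loosely matching
#: an inflamed-margin tumor section.
DEFAULT_CELL_DENSITIES: dict[str, dict[str, float]] = {
    "core": {"CD4": 150.0, "CD8": 100.0, "DN": 10.0},
    "margin": {"CD4": 300.0, "CD8": 150.0, "DN": 15.0},
}

_PHENOTYPES: dict[str, frozenset[str]] = {
    "CD4": frozenset({"CD3", "CD4"}),
    "CD8": frozenset({"CD3", "CD8"}),
    "DN": frozenset({"CD3"}),
    "B": frozenset({"CD20"}),
}


def make_cell_pattern(
    core_radius_um: float = 500.0,
    margin_width_um: float = 100.0,
    pixel_size_um: float = 10.0,
    densities: Optional[dict[str, dict[str, float]]] = None,
    treg_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list[CellRecord], TissueRegions, dict]:
    """Poisson cell point patterns on a disk core with an exterior margin.

    Cells of each phenotype class are placed as a homogeneous Poisson
    process per region at the stated densities (cells/mm²); FoxP3 is
    assigned to CD4 cells by Bernoulli thinning at ``treg_fraction``.
    Returns the cell list, the tissue-region geometry, and the ground
    truth (requested densities and treg fraction).
    """
    if densities is None:
        densities = DEFAULT_CELL_DENSITIES
    if not (0 <= treg_fraction <= 1):
        raise InvalidParameterError("treg_fraction must be in [0, 1]")
    for region, dd in densities.items():
        for phen, d in dd.items():
            if d < 0:
                raise InvalidParameterError(
                    f"density for {phen} in {region} must be >= 0"
                )
            if phen not in _PHENOTYPES:
                raise InvalidParameterError(f"unknown phenotype class {phen!r}")
    rng = np.random.default_rng(seed)

    pad = 2 * pixel_size_um
    extent = 2 * (core_radius_um + margin_width_um + pad)
    npix = int(math.ceil(extent / pixel_size_um))
    c = (npix - 1) / 2.0 * pixel_size_um
    ii, jj = np.indices((npix, npix), dtype=float)
    rr = np.hypot(ii * pixel_size_um - c, jj * pixel_size_um - c)
    core_mask = RegionMask(
        rr <= core_radius_um, label="core",
        spacing=(pixel_size_um, pixel_size_um),
    )
    regions = build_tissue_regions(
        core_mask, margin_width=margin_width_um, pixel_size=pixel_size_um
    )

    cells: list[CellRecord] = []
    for region_name, mask in (
        ("core", regions.core),
        ("margin", regions.invasive_margin),
    ):
        area_mm2 = mask.physical_size / 1e6
        member = np.argwhere(mask.grid)
        for phen, density in densities.get(region_name, {}).items():
            n = rng.poisson(density * area_mm2)
            if n == 0 or member.size == 0:
                continue
            picks = member[rng.integers(0, len(member), size=n)]
            # uniform offset within the pixel keeps the nearest-center
            # assignment consistent with the construction region
            offsets = rng.uniform(-0.499, 0.499, size=(n, 2))
            ys = (picks[:, 0] + offsets[:, 0]) * pixel_size_um
            xs = (picks[:, 1] + offsets[:, 1]) * pixel_size_um
            base = _PHENOTYPES[phen]
            for x, y in zip(xs, ys):
                markers = set(base)
                if phen == "CD4" and rng.random() < treg_fraction:
                    markers.add("FoxP3")
                cells.append(CellRecord(x=float(x), y=float(y),
                                        phenotype=frozenset(markers)))
    truth = {"densities": densities, "treg_fraction": treg_fraction}
    return cells, regions, truth


def make_gamma_dataset(
    organ_fractions: dict[str, float],
    masses: dict[str, float],
    injected_activity: float = 1.0e7,
    half_life: float = CU64_HALF_LIFE_H,
    count_delay_h: float = 24.0,
    standard_fraction: float = 0.01,
    counts_per_bq: float = 0.05,  # counter efficiency, cpm per Bq
    poisson_noise: bool = False,
    seed: int = 0,
) -> tuple[list[GammaRecord], InjectionContext, dict[str, float]]:
    """Gamma-counter biodistribution records with exact %ID/g truth.

    Each organ holds a stated fraction of the injected dose; counts are
    constructed so that %ID/g recovers ``100 * fraction / mass`` exactly
    at zero noise regardless of the counting delay (organ and dose
    standard decay identically). Optional Poisson noise perturbs the
    counts.
    """
    if sum(organ_fractions.values()) > 1 + 1e-12:
        raise InvalidParameterError("organ fractions must sum to <= 1")
    if set(organ_fractions) != set(masses):
        raise InvalidParameterError("organ_fractions and masses must share keys")
    rng = np.random.default_rng(seed)
    ctx = InjectionContext(
        injected_activity=injected_activity,
        injection_time=0.0,
        isotope_half_life=half_life,
    )
    decay = 2.0 ** (-count_delay_h / half_life)
    dose_counts = injected_activity * decay * counts_per_bq
    std_counts = dose_counts * standard_fraction
    records: list[GammaRecord] = []
    truth: dict[str, float] = {}
    for organ, frac in organ_fractions.items():
        net = dose_counts * frac
        std = std_counts
        if poisson_noise:
            net = float(rng.poisson(net))
            std = float(max(rng.poisson(std), 1))
        records.append(
            GammaRecord(
                organ_label=organ,
                net_counts=net,
                count_time=count_delay_h,
                mass=masses[organ],
                standard_counts=std,
                standard_fraction=standard_fraction,
            )
        )
        truth[organ] = 100.0 * frac / masses[organ]
    return records, ctx, truth


@dataclass
class TrialSpec:
    """Specification of a simulated PET-guided adaptive trial.

    Latent responders draw their day-5 core-to-margin ratio from a
    lognormal centered above the stratification threshold, latent
    nonresponders from one centered below; combination therapy rescues a
    stratified nonresponder with probability ``rescue_probability``.
    Defaults mirror a 21-animal guided cohort with ~40% responder
    prevalence and near-perfect separation of the latent classes.
    """

    n_subjects: int = 21
    responder_prevalence: float = 0.4
    ratio_median_responder: float = 1.8
    ratio_median_nonresponder: float = 0.9
    ratio_sigma: float = 0.25  # lognormal scale (log-space SD)
    threshold: float = 1.3
    rescue_probability: float = 0.7
    k_responder: float = -0.05
    k_nonresponder: float = 0.08
    growth_noise_sigma: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.responder_prevalence <= 1):
            raise InvalidParameterError("responder_prevalence must be in [0, 1]")
        if self.n_subjects < 1:
            raise InvalidParameterError("n_subjects must be >= 1")
        if not (0 <= self.rescue_probability <= 1):
            raise InvalidParameterError("rescue_probability must be in [0, 1]")

    @property
    def sensitivity(self) -> float:
        """P(ratio > threshold | latent responder), in closed form."""
        from scipy.stats import norm

        z = (math.log(self.threshold) - math.log(self.ratio_median_responder))
        return float(norm.sf(z / self.ratio_sigma))

    @property
    def specificity(self) -> float:
        """P(ratio <= threshold | latent nonresponder), in closed form."""
        from scipy.stats import norm

        z = (math.log(self.threshold) - math.log(self.ratio_median_nonresponder))
        return float(norm.cdf(z / self.ratio_sigma))


def make_guided_trial(spec: TrialSpec) -> pd.DataFrame:
    """Simulate one PET-guided adaptive-trial cohort.

    Per subject: a latent responder class is drawn at the stated
    prevalence; a day-5 core-to-margin ratio is sampled from the class's
    lognormal; the threshold rule assigns the arm; growth is simulated
    under the assigned arm, where added combination therapy rescues a
    latent nonresponder with probability ``rescue_probability`` (latent
    responders respond under either arm). Returns a per-subject table
    with the observables (ratio, arm, day-0/7 volumes, responder call)
    and the latent truth columns (``latent_responder``, ``rescued``).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for i in range(spec.n_subjects):
        latent = bool(rng.random() < spec.responder_prevalence)
        median = (
            spec.ratio_median_responder if latent else spec.ratio_median_nonresponder
        )
        ratio = float(
            math.exp(rng.normal(math.log(median), spec.ratio_sigma))
        )
        arm = "continue_mono" if ratio > spec.threshold else "add_combo"
        rescued = bool(
            (not latent) and arm == "add_combo"
            and rng.random() < spec.rescue_probability
        )
        responds = latent or rescued
        k = spec.k_responder if responds else spec.k_nonresponder
        v0 = 100.0 * math.exp(rng.normal(0.0, 0.2))
        noise = (
            math.exp(rng.normal(0.0, spec.growth_noise_sigma))
            if spec.growth_noise_sigma > 0
            else 1.0
        )
        v7 = v0 * math.exp(7.0 * k) * noise
        rows.append(
            {
                "subject_id": f"T{i + 1:03d}",
                "latent_responder": latent,
                "ratio": ratio,
                "arm": arm,
                "rescued": rescued,
                "volume_d0": v0,
                "volume_d7": v7,
                "responder": v7 / v0 < 1.0,
            }
        )
    return pd.DataFrame(rows)
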
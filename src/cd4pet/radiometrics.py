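"""Activity bookkeeping for immuno-PET studies.

Covers the radiometric arithmetic behind tracer quantification with a
short-lived positron emitter (copper-64 by default): radioactive decay
correction, image-based percent injected dose per milliliter (%ID/ml),
gamma-counter-based percent injected dose per gram (%ID/g), the
magnetic-bead immunoreactivity assay, and subtraction of nonspecific
background uptake measured in antigen-negative (wild-type) animals.

Conventions
-----------
* All activities are stored in Bq; percent scales appear only in outputs.
* The decay reference time is the injection time: measured activities are
  back-corrected to injection before normalisation, so %ID is a conserved
  fraction of the dose actually administered.
* Timestamps may be given either as plain numbers (hours) or as
  datetime-like objects; elapsed times are computed in hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import NamedTuple

import numpy as np

from .errors import InvalidParameterError, UndefinedRatioError

#: Physical half-life of copper-64 in hours.
CU64_HALF_LIFE_H = 12.7


def _as_hours(t) -> float:
    """Interpret a timestamp as hours on a common axis.

    Numbers pass through; datetimes are converted to hours since the epoch
    so differences between two datetimes are correct.
    """
    if isinstance(t, datetime):
        return t.timestamp() / 3600.0
    if isinstance(t, timedelta):
        return t.total_seconds() / 3600.0
    return float(t)


def hours_between(later, earlier) -> float:
    """Elapsed time ``later - earlier`` in hours (may be negative)."""
    return _as_hours(later) - _as_hours(earlier)


@dataclass(frozen=True)
class InjectionContext:
    """Injected dose and timing shared by all measurements of one subject.

    Parameters
    ----------
    injected_activity : float
        Activity administered at injection time, in Bq. Must be positive.
    injection_time : float or datetime
        Timestamp of injection; the decay reference time.
    isotope_half_life : float
        Isotope half-life in hours. Defaults to copper-64 (12.7 h).
    """

    injected_activity: float
    injection_time: float | datetime = 0.0
    isotope_half_life: float = CU64_HALF_LIFE_H

    def __post_init__(self):
        if not self.injected_activity > 0:
            raise InvalidParameterError(
                f"injected_activity must be > 0, got {self.injected_activity}"
            )
        if not self.isotope_half_life > 0:
            raise InvalidParameterError(
                f"isotope_half_life must be > 0, got {self.isotope_half_life}"
            )


@dataclass
class ActivityVolume:
    """A 3D activity-concentration image in Bq/ml.

    ``voxels`` is indexed (slice, row, col); ``spacing`` gives per-axis
    voxel size in mm in the same order.
    """

    voxels: np.ndarray
    spacing: tuple[float, ...] = (1.0, 1.0, 1.0)
    scan_time: float | datetime = 0.0

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.voxels.ndim:
            raise InvalidParameterError(
                f"spacing has {len(self.spacing)} entries for a "
                f"{self.voxels.ndim}-D volume"
            )
        if any(s <= 0 for s in self.spacing):
            raise InvalidParameterError(f"all spacing must be > 0, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise InvalidParameterError("voxel values must be finite")


@dataclass(frozen=True)
class GammaRecord:
    """One gamma-counter measurement of a harvested organ.

    The dose standard is modelled as a known fraction of the injected dose
    ("standardized aliquots"): ``standard_counts`` is the count rate of an
    aliquot containing ``standard_fraction`` of the dose, counted at the
    same reference conditions as the organ.
    """

    organ_label: str
    net_counts: float
    count_time: float | datetime
    mass: float
    standard_counts: float
    standard_fraction: float

    def __post_init__(self):
        if not self.mass > 0:
            raise InvalidParameterError(f"mass must be > 0, got {self.mass}")
        if not self.standard_counts > 0:
            raise InvalidParameterError(
                f"standard_counts must be > 0, got {self.standard_counts}"
            )
        if not (0 < self.standard_fraction <= 1):
            raise InvalidParameterError(
                f"standard_fraction must be in (0, 1], got {self.standard_fraction}"
            )


@dataclass(frozen=True)
class BeadAssayRecord:
    """Counts from the magnetic-bead immunoreactivity assay.

    ``bs_counts`` is the beads-plus-half-supernatant tube (BS),
    ``s_counts`` the half-supernatant-only tube (S).
    """

    bs_counts: float
    s_counts: float

    def __post_init__(self):
        if self.bs_counts < 0 or self.s_counts < 0:
            raise InvalidParameterError("bead assay counts must be >= 0")
        if self.bs_counts + self.s_counts <= 0:
            raise InvalidParameterError("bead assay total counts must be > 0")


class BackgroundCorrected(NamedTuple):
    """Background-subtracted uptake with a below-background flag."""

    value: float
    below_background: bool


def decay_correct(activity: float, elapsed: float, half_life: float) -> float:
    """Correct a measured activity for radioactive decay.

    Returns ``activity * 2**(elapsed / half_life)``: an activity measured
    ``elapsed`` hours after the reference time is scaled up to what it was
    at the reference. A negative ``elapsed`` back-corrects in the other
    direction, making the operation its own inverse.
    """
    if not half_life > 0:
        raise InvalidParameterError(f"half_life must be > 0, got {half_life}")
    return activity * 2.0 ** (elapsed / half_life)


def percent_id_per_ml(mean_conc: float, ctx: InjectionContext) -> float:
    """Image-based uptake as percent injected dose per milliliter.

    ``mean_conc`` is a decay-corrected mean activity concentration in
    Bq/ml; the result is ``100 * mean_conc / injected_activity``.
    """
    if not ctx.injected_activity > 0:  # defensive; ctx validates on build
        raise InvalidParameterError("injected_activity must be > 0")
    return 100.0 * mean_conc / ctx.injected_activity


def percent_id_per_g(
    rec: GammaRecord, ctx: InjectionContext, *, reference: str = "injection"
) -> float:
    """Gamma-count-based uptake as percent injected dose per gram.

    Both the organ counts and the dose standard are decay-corrected to a
    common reference time before the ratio; because the standard is an
    aliquot of the injected dose it decays identically, so the choice of
    reference cancels. ``reference`` may be ``"injection"`` (default) or
    ``"count_time"``.

    Returns ``100 * (net / (standard / standard_fraction)) / mass``.
    """
    if reference not in ("injection", "count_time"):
        raise InvalidParameterError(f"unknown decay reference {reference!r}")
    if reference == "injection":
        elapsed = hours_between(rec.count_time, ctx.injection_time)
    else:
        elapsed = 0.0
    net = decay_correct(rec.net_counts, elapsed, ctx.isotope_half_life)
    std = decay_correct(rec.standard_counts, elapsed, ctx.isotope_half_life)
    dose_equivalent_counts = std / rec.standard_fraction
    return 100.0 * (net / dose_equivalent_counts) / rec.mass


def immunoreactive_fraction(rec: BeadAssayRecord) -> float:
    """Immunoreactive fraction from the bead assay: (BS - S) / (BS + S).

    Lies in [-1, 1]; equals 1 when all activity is bead-associated.
    """
    total = rec.bs_counts + rec.s_counts
    if total == 0:
        raise UndefinedRatioError("BS + S = 0: immunoreactive fraction undefined")
    return (rec.bs_counts - rec.s_counts) / total


def background_correct(uptake: float, wt_reference: float) -> BackgroundCorrected:
    """Subtract nonspecific uptake measured in antigen-negative animals.

    The result is not floored at zero: uptake below the wild-type
    background is returned as a negative value with ``below_background``
    set, so downstream correlations remain unbiased.
    """
    if uptake < 0 or wt_reference < 0:
        raise InvalidParameterError("uptake and wt_reference must be >= 0")
    value = uptake - wt_reference
    return BackgroundCorrected(value=value, below_background=value < 0)
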
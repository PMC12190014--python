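"""Classification and therapy-guidance rules.

Implements the decision layer of the PET-guided adaptive workflow:

* spatial pattern calls (enriched / excluded / deserted) from paired
  core/margin signal, applicable to PET uptake (%ID/ml) or histology
  cell densities (cells/mm²) alike;
* the core-to-margin stratification rule — a ratio strictly above 1.3 at
  the on-treatment scan keeps the subject on checkpoint monotherapy,
  otherwise a costimulatory antibody is added;
* the growth-based responder rule — tumor volume at day 7 relative to
  day 0 below 1 defines a responder;
* cohort bookkeeping: per-arm and pooled response rates for the adaptive
  workflow.

Reported percentages are rounded half-away-from-zero to integer percent,
matching how response rates are conventionally printed; exact fractions
are always retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional

import pandas as pd

from .errors import (
    ConfigurationError,
    EmptyCohortError,
    InvalidParameterError,
    MissingTimepointError,
    UnassignableError,
)
from .spatial import CoreMarginScore

Arm = Literal["continue_mono", "add_combo"]
Pattern = Literal["enriched", "excluded", "deserted", "indeterminate"]

#: Default core-to-margin stratification threshold (strict inequality).
STRATIFICATION_THRESHOLD = 1.3


def round_half_away(x: float) -> int:
    """Round half away from zero (so 0.5 -> 1), unlike banker's rounding."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class RuleCheck:
    """One threshold evaluation recorded in a pattern call's audit trail."""

    name: str
    value: float
    passed: bool


@dataclass
class PatternCall:
    """A spatial-pattern classification with its full rule trace."""

    call: Pattern
    rule_trace: list[RuleCheck]


@dataclass
class SubjectOutcome:
    """Per-subject record in the adaptive-workflow cohort."""

    subject_id: str
    ratio: float
    arm: Arm
    responder: Optional[bool] = None
    volumes: Optional[Mapping[float, float]] = None


def classify_pattern(
    core_mean: float,
    margin_mean: float,
    thresholds: Mapping[str, float],
) -> PatternCall:
    """Classify the spatial signal pattern of a tumor.

    Parameters
    ----------
    core_mean, margin_mean : float
        Mean signal per region — %ID/ml for PET, cells/mm² for
        histology; the rule only requires that both share units.
    thresholds : mapping
        Requires ``u_min`` (signal floor below which a region counts as
        empty), ``r_hi`` (ratio above which a core-dominant tumor is
        "enriched") and ``r_lo`` (ratio below which a margin-dominant
        tumor is "excluded").

    Rules, in order: *deserted* if both regions are below the floor;
    *enriched* if the core is above the floor and the ratio exceeds
    ``r_hi``; *excluded* if the margin is above the floor and the ratio
    is below ``r_lo``; otherwise *indeterminate*. Every threshold
    comparison is recorded in the returned ``rule_trace``.
    """
    missing = {"u_min", "r_hi", "r_lo"} - set(thresholds)
    if missing:
        raise ConfigurationError(f"missing pattern thresholds: {sorted(missing)}")
    u_min, r_hi, r_lo = thresholds["u_min"], thresholds["r_hi"], thresholds["r_lo"]
    if r_lo > r_hi:
        raise ConfigurationError(f"r_lo ({r_lo}) must not exceed r_hi ({r_hi})")
    if core_mean < 0 or margin_mean < 0:
        raise InvalidParameterError("region means must be >= 0")

    ratio = core_mean / margin_mean if margin_mean > 0 else math.inf
    trace = [
        RuleCheck("core_below_floor", core_mean, core_mean < u_min),
        RuleCheck("margin_below_floor", margin_mean, margin_mean < u_min),
        RuleCheck("ratio_above_r_hi", ratio, ratio > r_hi),
        RuleCheck("ratio_below_r_lo", ratio, ratio < r_lo),
    ]
    if core_mean < u_min and margin_mean < u_min:
        call: Pattern = "deserted"
    elif core_mean >= u_min and ratio > r_hi:
        call = "enriched"
    elif margin_mean >= u_min and ratio < r_lo:
        call = "excluded"
    else:
        call = "indeterminate"
    return PatternCall(call=call, rule_trace=trace)


def stratify_therapy(
    score: CoreMarginScore, threshold: float = STRATIFICATION_THRESHOLD
) -> Arm:
    """Assign the therapy arm from the on-treatment core-to-margin ratio.

    Strictly above ``threshold`` continues checkpoint monotherapy;
    at or below it (including exactly at the threshold) the
    costimulatory antibody is added.
    """
    if score.undefined_ratio or not math.isfinite(score.ratio):
        raise UnassignableError(
            "cannot stratify a subject with an undefined core-to-margin ratio"
        )
    return "continue_mono" if score.ratio > threshold else "add_combo"


def growth_responder(volumes: Mapping[float, float]) -> bool:
    """Responder call from the tumor-volume ratio day 7 over day 0.

    True iff ``V(7)/V(0) < 1``. A ratio of exactly 1 is called
    nonresponder: the defining predicates (< 1 responder, > 1
    nonresponder) leave the boundary open and the conservative
    assignment is used.
    """
    for day in (0, 7):
        if day not in volumes:
            raise MissingTimepointError(f"growth curve lacks day {day}")
    v0, v7 = volumes[0], volumes[7]
    if not (v0 > 0 and v7 > 0):
        raise InvalidParameterError("tumor volumes must be > 0")
    return v7 / v0 < 1.0


@dataclass
class ResponseRate:
    """Responder count, total, and percent (exact and printed)."""

    responders: int
    total: int

    @property
    def fraction(self) -> float:
        return self.responders / self.total

    @property
    def rate(self) -> int:
        """Integer percent, rounded half away from zero."""
        return round_half_away(100.0 * self.fraction)


def cohort_response_rate(
    outcomes: Iterable[SubjectOutcome], arm_filter: Optional[Arm] = None
) -> ResponseRate:
    """Response rate of a cohort, optionally restricted to one arm."""
    selected = [
        o for o in outcomes if arm_filter is None or o.arm == arm_filter
    ]
    if not selected:
        raise EmptyCohortError(
            f"no subjects in cohort (arm_filter={arm_filter!r})"
        )
    undetermined = [o.subject_id for o in selected if o.responder is None]
    if undetermined:
        raise InvalidParameterError(
            f"subjects without responder status: {undetermined}"
        )
    responders = sum(bool(o.responder) for o in selected)
    return ResponseRate(responders=responders, total=len(selected))


@dataclass
class WorkflowSummary:
    """Per-arm and pooled accounting of the adaptive workflow."""

    per_arm: dict[str, ResponseRate]
    pooled: ResponseRate
    continue_mono_fraction: float
    empty_arms: list[str] = field(default_factory=list)

    @property
    def continue_mono_percent(self) -> int:
        return round_half_away(100.0 * self.continue_mono_fraction)

    def to_dict(self) -> dict:
        return {
            "per_arm": {
                arm: {
                    "responders": rr.responders,
                    "total": rr.total,
                    "rate_percent": rr.rate,
                    "fraction": rr.fraction,
                }
                for arm, rr in self.per_arm.items()
            },
            "pooled": {
                "responders": self.pooled.responders,
                "total": self.pooled.total,
                "rate_percent": self.pooled.rate,
                "fraction": self.pooled.fraction,
            },
            "continue_mono_fraction": self.continue_mono_fraction,
            "continue_mono_percent": self.continue_mono_percent,
            "empty_arms": self.empty_arms,
        }


def adaptive_workflow(
    cohort: pd.DataFrame | Iterable[SubjectOutcome],
    threshold: float = STRATIFICATION_THRESHOLD,
) -> WorkflowSummary:
    """Run the full stratify-then-tabulate adaptive workflow.

    ``cohort`` is either an iterable of :class:`SubjectOutcome` (their
    pre-assigned arms are ignored and re-derived from the ratio) or a
    DataFrame with columns ``subject_id``, ``ratio`` and ``responder``.
    Every subject is stratified by the threshold rule, then arm sizes,
    per-arm and pooled response rates, and the fraction stratified to
    continued monotherapy are tabulated. Arms left empty by the
    stratification are flagged in ``empty_arms``.
    """
    if isinstance(cohort, pd.DataFrame):
        outcomes = [
            SubjectOutcome(
                subject_id=str(row.subject_id),
                ratio=float(row.ratio),
                arm="continue_mono",  # placeholder, re-derived below
                responder=bool(row.responder),
            )
            for row in cohort.itertuples(index=False)
        ]
    else:
        outcomes = list(cohort)
    if not outcomes:
        raise EmptyCohortError("empty cohort")
    for o in outcomes:
        score = CoreMarginScore(
            core_mean=math.nan, margin_mean=math.nan, ratio=o.ratio,
            undefined_ratio=not math.isfinite(o.ratio),
        )
        o.arm = stratify_therapy(score, threshold)

    per_arm: dict[str, ResponseRate] = {}
    empty_arms: list[str] = []
    for arm in ("continue_mono", "add_combo"):
        members = [o for o in outcomes if o.arm == arm]
        if members:
            per_arm[arm] = cohort_response_rate(members)
        else:
            empty_arms.append(arm)
    pooled = cohort_response_rate(outcomes)
    n_mono = sum(o.arm == "continue_mono" for o in outcomes)
    return WorkflowSummary(
        per_arm=per_arm,
        pooled=pooled,
        continue_mono_fraction=n_mono / len(outcomes),
        empty_arms=empty_arms,
    )
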
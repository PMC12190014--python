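"""Group comparisons, correlation, and Holm-Sidak multiplicity control.

The reporting layer used across the pipeline: two-sample t tests (Welch
by default for unpaired comparisons, since group sizes typically differ),
paired t tests, Pearson correlation, and the Holm-Sidak step-down
adjustment that controls the family-wise error rate across a panel of
pairwise comparisons. Adjusted p values map onto the conventional star
notation (* <= 0.05, ** <= 0.01, *** <= 0.001).

t tests and correlation are delegated to scipy; the Holm-Sidak step-down
is implemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import InsufficientSampleError, InvalidParameterError

Stars = Literal["ns", "*", "**", "***"]

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> Stars:
    """Star notation for a p value: *** <= 0.001, ** <= 0.01, * <= 0.05."""
    for cutoff, label in STAR_THRESHOLDS:
        if p <= cutoff:
            return label  # type: ignore[return-value]
    return "ns"


@dataclass
class ComparisonResult:
    """A test statistic with raw and (optionally) adjusted p values."""

    statistic: float
    raw_p: float
    adjusted_p: Optional[float] = None
    degenerate: bool = False

    @property
    def stars(self) -> Stars:
        p = self.adjusted_p if self.adjusted_p is not None else self.raw_p
        return significance_stars(p)


def holm_sidak_adjust(pvals: Sequence[float]) -> list[float]:
    """Holm-Sidak step-down adjusted p values, returned in input order.

    With the raw p values sorted ascending, the i-th (1-based) adjusted
    value is the running maximum over j <= i of
    ``min(1, 1 - (1 - p_(j)) ** (m - j + 1))`` where m is the family
    size; the running maximum enforces monotonicity of the step-down
    procedure. A single test is returned unchanged.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise InvalidParameterError("pvals must be a flat sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidParameterError("all p values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return []
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    exponents = m - np.arange(m)  # m, m-1, ..., 1
    stepwise = np.minimum(1.0, 1.0 - (1.0 - sorted_p) ** exponents)
    adjusted_sorted = np.maximum.accumulate(stepwise)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted.tolist()


def two_sample_compare(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool = False,
    equal_var: bool = False,
) -> ComparisonResult:
    """Two-sided t comparison of two samples.

    Unpaired comparisons default to the Welch (unequal-variance) form;
    set ``equal_var=True`` for the pooled-variance Student form. Paired
    comparisons require equal lengths. Samples with zero variance in
    both groups yield a degenerate result (statistic NaN or infinite)
    flagged via ``degenerate`` rather than an exception.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientSampleError("each sample needs n >= 2")
    if paired:
        if a.size != b.size:
            raise InsufficientSampleError("paired comparison needs equal lengths")
        res = sps.ttest_rel(a, b)
    else:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
    statistic = float(res.statistic)
    raw_p = float(res.pvalue)
    degenerate = not math.isfinite(statistic) or math.isnan(raw_p)
    if degenerate:
        raw_p = math.nan
    return ComparisonResult(statistic=statistic, raw_p=raw_p, degenerate=degenerate)


def correlate(x: Sequence[float], y: Sequence[float]) -> ComparisonResult:
    """Pearson correlation with its two-sided p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InsufficientSampleError("samples must have equal length")
    if x.size < 3:
        raise InsufficientSampleError("correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InvalidParameterError(
            "correlation undefined for a zero-variance sample"
        )
    res = sps.pearsonr(x, y)
    return ComparisonResult(statistic=float(res.statistic), raw_p=float(res.pvalue))


def compare_panel(
    samples: dict[str, tuple[Sequence[float], Sequence[float]]],
    paired: bool = False,
    equal_var: bool = False,
) -> dict[str, ComparisonResult]:
    """Run a family of pairwise comparisons with Holm-Sidak adjustment.

    ``samples`` maps a comparison label to an ``(a, b)`` pair. All raw p
    values are adjusted as one family; degenerate comparisons are
    excluded from the family and keep a NaN adjusted p.
    """
    results = {
        name: two_sample_compare(a, b, paired=paired, equal_var=equal_var)
        for name, (a, b) in samples.items()
    }
    valid = [n for n, r in results.items() if not r.degenerate]
    adjusted = holm_sidak_adjust([results[n].raw_p for n in valid])
    for name, adj in zip(valid, adjusted):
        results[name].adjusted_p = adj
    for name in set(results) - set(valid):
        results[name].adjusted_p = math.nan
    return results
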
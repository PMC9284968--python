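"""VAF accumulation, proportion confidence intervals, time-to-support,
and the binomial sensitivity/specificity operating-point calculation.

Support counts only TARGET reads whose per-read consensus is the
wildtype or a declared mutant allele; anything else (DEL, undeclared
substitutions) is tallied as other-allele and excluded from VAF.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from scipy import stats

from .assay import LampAssay
from .classify import ReadClass, ReadDiagnosis
from .consensus import NOCALL

DEFAULT_SUPPORT_TARGET = 250
DEFAULT_CONFIDENCE = 0.95

logger = logging.getLogger(__name__)

__all__ = [
    "VafReport",
    "SupportTimeline",
    "NOT_REACHED",
    "accumulate",
    "proportion_ci",
    "time_to_support",
    "detection_power",
]

#: sentinel for time_to_support when the threshold is never met
NOT_REACHED = math.inf


@dataclass(frozen=True)
class VafReport:
    n_mut: int
    n_wt: int
    n_other: int
    ci: tuple[float, float] | None
    confidence: float

    @property
    def support(self) -> int:
        return self.n_mut + self.n_wt

    @property
    def vaf(self) -> float | None:
        if self.support == 0:
            return None
        return self.n_mut / self.support

    @property
    def call(self) -> str:
        return NOCALL if self.support == 0 else f"VAF={self.vaf:.4f}"


@dataclass
class SupportTimeline:
    """(start_time, cumulative_support, running_vaf) triples, time-sorted."""

    points: list[tuple[float, int, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)


def proportion_ci(
    k: int, n: int, cl: float = DEFAULT_CONFIDENCE, method: str = "wald"
) -> tuple[float, float]:
    """Two-sided CI for a population proportion, clamped to [0, 1].

    ``method`` is "wald" (normal approximation, default) or "wilson".
    """
    if n < 1:
        raise ValueError("proportion_ci undefined for n == 0")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    if not 0 < cl < 1:
        raise ValueError("confidence level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + cl / 2)
    p = k / n
    if method == "wald":
        half = z * math.sqrt(p * (1 - p) / n)
        lo, hi = p - half, p + half
    elif method == "wilson":
        denom = 1 + z * z / n
        center = (p + z * z / (2 * n)) / denom
        half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
        lo, hi = center - half, center + half
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return (max(0.0, lo), min(1.0, hi))


def accumulate(
    diagnoses,
    assay: LampAssay,
    cl: float = DEFAULT_CONFIDENCE,
    ci_method: str = "wald",
) -> tuple[VafReport, SupportTimeline]:
    """Fold a stream of read diagnoses into a VAF report and timeline.

    Reads without a start_time are counted in the totals but excluded
    from the timeline (with a logged warning).
    """
    n_mut = n_wt = n_other = 0
    supporting: list[tuple[float, bool]] = []  # (time, is_mutant)
    n_untimed = 0
    for d in diagnoses:
        if d.read_class is not ReadClass.TARGET or d.consensus is None:
            continue
        call = d.consensus.call
        if call == assay.wildtype_allele:
            n_wt += 1
            is_mut = False
        elif call in assay.mutant_alleles:
            n_mut += 1
            is_mut = True
        else:
            if call != NOCALL:
                n_other += 1
            continue
        if d.start_time is None:
            n_untimed += 1
            continue
        supporting.append((d.start_time, is_mut))
    if n_untimed:
        logger.warning("%d supporting reads lacked start_time; "
                       "excluded from timeline", n_untimed)

    supporting.sort(key=lambda t: t[0])
    timeline = SupportTimeline()
    mut_so_far = 0
    for i, (t, is_mut) in enumerate(supporting, start=1):
        mut_so_far += int(is_mut)
        timeline.points.append((t, i, mut_so_far / i))

    support = n_mut + n_wt
    ci = proportion_ci(n_mut, support, cl, ci_method) if support else None
    return (
        VafReport(n_mut=n_mut, n_wt=n_wt, n_other=n_other, ci=ci, confidence=cl),
        timeline,
    )


def time_to_support(
    timeline: SupportTimeline, threshold: int = DEFAULT_SUPPORT_TARGET
) -> float:
    """start_time of the threshold-th supporting read, or NOT_REACHED."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    for t, cum, _ in timeline.points:
        if cum >= threshold:
            return t
    return NOT_REACHED


def detection_power(
    depth: int,
    true_vaf: float,
    per_read_error: float,
    decision_threshold: float = 0.05,
) -> tuple[float, float]:
    """Exact binomial sensitivity/specificity at a VAF decision threshold.

    A sample is called positive when >= ceil(threshold * depth) of
    ``depth`` consensus calls are mutant.  Sensitivity is the tail
    probability under the true VAF; specificity is the complement tail
    under the per-read miscall rate.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    for name, x in (("true_vaf", true_vaf), ("per_read_error", per_read_error)):
        if not 0 < x < 1:
            raise ValueError(f"{name} must be in (0, 1)")
    if not 0 < decision_threshold < 1:
        raise ValueError("decision_threshold must be in (0, 1) exclusive")
    cutoff = math.ceil(decision_threshold * depth)
    sensitivity = float(stats.binom.sf(cutoff - 1, depth, true_vaf))
    specificity = float(stats.binom.cdf(cutoff - 1, depth, per_read_error))
    return (sensitivity, specificity)
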
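"""Threshold filtering on tag number and fold enrichment.

Criteria use the comparator set {>=, =, <=} (all inclusive) and combine
by logical AND.  A criterion's threshold may be *relative*: expressed
as a percentage of the tag count of the target-locus peak within the
same peak list, the "tag number >= 5% of the target locus" rule.  Such
criteria must be resolved to absolute thresholds (per peak list) before
filtering.

Criterion strings follow the grammar ``field op value[%target]`` with
``field`` one of ``tags``/``fe``/``fold_enrichment`` and ``op`` one of
``>=``, ``=``, ``<=``; e.g. ``tags>=50``, ``fe>=10``, ``tags>=5%target``.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum

from .errors import TargetLocusError, UsageError
from .model import PeakRecord, PeakSet

#: absolute tolerance for equality tests on real-valued fields
EQ_TOLERANCE = 1e-6


class Comparator(str, Enum):
    GE = ">="
    EQ = "="
    LE = "<="


@dataclass(frozen=True)
class FilterCriterion:
    """(field, comparator, threshold), optionally relative to the
    target-locus peak's tag count."""

    field: str  # "tags" | "fold_enrichment"
    comparator: Comparator
    threshold: float
    relative_to_target: bool = False

    def __post_init__(self) -> None:
        if self.field not in ("tags", "fold_enrichment"):
            raise ValueError(f"unknown filter field {self.field!r}")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.relative_to_target:
            if self.field != "tags":
                raise ValueError(
                    "relative thresholds apply to tag counts only")
            if not 0 <= self.threshold <= 100:
                raise ValueError("relative threshold is a percentage "
                                 "and must lie in [0, 100]")

    def matches(self, record: PeakRecord) -> bool:
        if self.relative_to_target:
            raise UsageError(
                "relative criterion must be resolved to an absolute "
                "threshold before filtering (see resolve_criteria)")
        value = record.tags if self.field == "tags" \
            else record.fold_enrichment
        if self.comparator is Comparator.GE:
            return value >= self.threshold
        if self.comparator is Comparator.LE:
            return value <= self.threshold
        if self.field == "tags":
            return value == self.threshold
        return abs(value - self.threshold) <= EQ_TOLERANCE


@dataclass(frozen=True)
class TargetLocusSpec:
    """Coordinates locating the enChIP target-locus peak in a list.

    1-based closed interval; the referent peak is the one overlapping
    this interval with the highest tag count (leftmost start on ties).
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("target locus end must be >= start")


_CRITERION_RE = re.compile(
    r"^\s*(?P<field>tags?|fe|fold_enrichment)\s*"
    r"(?P<op>>=|<=|=)\s*"
    r"(?P<value>\d+\.?\d*|\.\d+)\s*"
    r"(?P<rel>%\s*target)?\s*$", re.IGNORECASE)


def parse_criterion(text: str) -> FilterCriterion:
    """Parse a criterion string such as ``tags>=50`` or ``tags>=5%target``.

    Raises
    ------
    UsageError
        If the string does not match ``field op value[%target]``.
    """
    m = _CRITERION_RE.match(text)
    if m is None:
        raise UsageError(
            f"malformed criterion {text!r}; expected 'field op value"
            f"[%target]' with field in {{tags, fe, fold_enrichment}} "
            f"and op in {{>=, =, <=}}, e.g. tags>=50, fe>=10, "
            f"tags>=5%target")
    field = m.group("field").lower()
    field = "tags" if field in ("tag", "tags") else "fold_enrichment"
    return FilterCriterion(
        field=field,
        comparator=Comparator(m.group("op")),
        threshold=float(m.group("value")),
        relative_to_target=m.group("rel") is not None,
    )


def find_target_peak(peaks: PeakSet, target: TargetLocusSpec) -> PeakRecord:
    """The peak overlapping the target locus with the highest tag count.

    Ties break to the leftmost start.  Raises
    :class:`~enchip_peaks.errors.TargetLocusError` when no peak overlaps
    the locus — the target must appear in its own enChIP peak list.
    """
    hits = [r for r in peaks.records
            if r.chrom == target.chrom
            and min(r.end, target.end) >= max(r.start, target.start)]
    if not hits:
        raise TargetLocusError(
            f"no peak in {peaks.source!r} overlaps the target locus "
            f"{target.chrom}:{target.start}-{target.end}; check the "
            f"coordinates against the peak list")
    return max(hits, key=lambda r: (r.tags, -r.start))


def resolve_relative_threshold(peaks: PeakSet, target: TargetLocusSpec,
                               percent: float) -> float:
    """Absolute tag threshold equal to ``percent`` % of the target-locus
    peak's tag count.

    The resolved value is *not* rounded to an integer; comparisons use
    the real value.
    """
    if not 0 <= percent <= 100:
        raise ValueError("percent must lie in [0, 100]")
    target_peak = find_target_peak(peaks, target)
    return percent / 100.0 * target_peak.tags


def resolve_criteria(criteria: list[FilterCriterion], peaks: PeakSet,
                     target: TargetLocusSpec | None) -> list[FilterCriterion]:
    """Replace relative criteria with absolute ones resolved against
    ``peaks``' own target-locus peak."""
    out = []
    for crit in criteria:
        if crit.relative_to_target:
            if target is None:
                raise UsageError(
                    "a relative criterion requires a target locus")
            absolute = resolve_relative_threshold(peaks, target,
                                                  crit.threshold)
            out.append(replace(crit, threshold=absolute,
                               relative_to_target=False))
        else:
            out.append(crit)
    return out


def apply_filters(peaks: PeakSet,
                  criteria: list[FilterCriterion]) -> PeakSet:
    """Records satisfying the conjunction of all criteria, in order.

    An empty criteria list is the identity.  Relative criteria must be
    resolved first.
    """
    if not criteria:
        return peaks.with_records(list(peaks.records))
    survivors = [rec for rec in peaks.records
                 if all(c.matches(rec) for c in criteria)]
    return peaks.with_records(survivors)
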
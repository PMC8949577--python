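"""Peak-set algebra: overlap predicate, common-peak extraction and
negative-peak elimination.

Both set operations are *base-centric*: the result always consists of
records drawn verbatim from the designated base file, never merged or
intersected coordinates.  ``extract_common`` keeps base records that
overlap at least one record in every other set (the Positive/AND mode);
``eliminate_negative`` removes base records that overlap the union of
all negative records (the Negative/OR mode).

Overlap is evaluated on 1-based closed intervals; two peaks overlap
when they share at least ``min_overlap_bp`` bases (default 1, i.e. any
overlap including a single shared boundary base).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from intervaltree import IntervalTree

from .errors import UsageError
from .model import PeakRecord, PeakSet


@dataclass(frozen=True)
class OverlapRule:
    """Minimum number of shared bases for two peaks to count as
    overlapping."""

    min_overlap_bp: int = 1

    def __post_init__(self) -> None:
        if self.min_overlap_bp < 1:
            raise ValueError("min_overlap_bp must be >= 1")


@dataclass
class AlgebraResult:
    """Outcome of a set operation: surviving base records and their count."""

    surviving: PeakSet
    count: int
    mode: Literal["common", "negative-eliminated"]

    def __post_init__(self) -> None:
        assert self.count == len(self.surviving.records)


def overlaps(a: PeakRecord, b: PeakRecord,
             rule: OverlapRule = OverlapRule()) -> bool:
    """True iff ``a`` and ``b`` are on the same chromosome and their
    closed intervals share at least ``rule.min_overlap_bp`` bases.

    Shared bases of closed intervals:
    ``min(a.end, b.end) - max(a.start, b.start) + 1``.
    Symmetric and total.
    """
    if a.chrom != b.chrom:
        return False
    shared = min(a.end, b.end) - max(a.start, b.start) + 1
    return shared >= rule.min_overlap_bp


def _build_trees(records: Iterable[PeakRecord]) -> dict[str, IntervalTree]:
    """Per-chromosome interval index; closed [s, e] stored as [s, e+1)."""
    trees: dict[str, IntervalTree] = {}
    for rec in records:
        trees.setdefault(rec.chrom, IntervalTree()).addi(
            rec.start, rec.end + 1, rec)
    return trees


def _overlaps_any(rec: PeakRecord, trees: dict[str, IntervalTree],
                  rule: OverlapRule) -> bool:
    tree = trees.get(rec.chrom)
    if tree is None:
        return False
    for hit in tree.overlap(rec.start, rec.end + 1):
        shared = min(rec.end + 1, hit.end) - max(rec.start, hit.begin)
        if shared >= rule.min_overlap_bp:
            return True
    return False


def _merged_coverage(records: Iterable[PeakRecord]
                     ) -> dict[str, list[tuple[int, int]]]:
    """Union ranges per chromosome: sorted, merged closed intervals."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for rec in records:
        by_chrom.setdefault(rec.chrom, []).append((rec.start, rec.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out: list[tuple[int, int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1] + 1:  # adjacent closed intervals fuse
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[chrom] = out
    return merged


def extract_common(base: PeakSet, others: list[PeakSet],
                   rule: OverlapRule = OverlapRule(),
                   mutual: bool = False) -> AlgebraResult:
    """Extract base records common to every other peak set.

    A base record survives when it overlaps (per ``rule``) at least one
    record in *each* set of ``others`` individually.  With
    ``mutual=True`` the stricter variant is used instead: some single
    stretch of at least ``min_overlap_bp`` bases of the base record must
    be covered simultaneously by every other set.

    Records are returned verbatim from the base set in canonical order;
    duplicates within the base are deduplicated in the result.

    Raises
    ------
    UsageError
        If ``others`` is empty — common extraction needs two or more
        files.
    """
    if not others:
        raise UsageError("common extraction needs >=2 files "
                         "(a base file plus at least one other)")
    if mutual:
        survivors = _extract_common_mutual(base, others, rule)
    else:
        tree_sets = [_build_trees(o.records) for o in others]
        survivors = [rec for rec in base.records
                     if all(_overlaps_any(rec, trees, rule)
                            for trees in tree_sets)]
    survivors = _dedupe(survivors)
    out = base.with_records(survivors)
    return AlgebraResult(surviving=out, count=len(survivors), mode="common")


def _extract_common_mutual(base: PeakSet, others: list[PeakSet],
                           rule: OverlapRule) -> list[PeakRecord]:
    coverages = [_merged_coverage(o.records) for o in others]
    survivors = []
    for rec in base.records:
        pieces = [(rec.start, rec.end)]
        for cov in coverages:
            chrom_cov = cov.get(rec.chrom, [])
            pieces = _intersect_pieces(pieces, chrom_cov)
            if not pieces:
                break
        if any(e - s + 1 >= rule.min_overlap_bp for s, e in pieces):
            survivors.append(rec)
    return survivors


def _intersect_pieces(pieces: list[tuple[int, int]],
                      cov: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    for ps, pe in pieces:
        for cs, ce in cov:
            s, e = max(ps, cs), min(pe, ce)
            if s <= e:
                out.append((s, e))
    return out


def eliminate_negative(base: PeakSet, negatives: list[PeakSet],
                       rule: OverlapRule = OverlapRule()) -> AlgebraResult:
    """Remove base records that overlap any negative peak.

    The negative records from all sets are first merged into union
    ranges; a base record survives only if it overlaps none of them by
    at least ``rule.min_overlap_bp`` bases.  Records are returned
    verbatim from the base set.

    Raises
    ------
    UsageError
        If ``negatives`` is empty (an empty *set* is fine; a missing
        list of sets is an invocation error).
    """
    if not negatives:
        raise UsageError("negative elimination needs at least one "
                         "negative peak file")
    union: list[PeakRecord] = [r for neg in negatives for r in neg.records]
    merged = _merged_coverage(union)
    trees: dict[str, IntervalTree] = {}
    for chrom, ivs in merged.items():
        tree = IntervalTree()
        for s, e in ivs:
            tree.addi(s, e + 1, None)
        trees[chrom] = tree

    def hit(rec: PeakRecord) -> bool:
        tree = trees.get(rec.chrom)
        if tree is None:
            return False
        for iv in tree.overlap(rec.start, rec.end + 1):
            shared = min(rec.end + 1, iv.end) - max(rec.start, iv.begin)
            if shared >= rule.min_overlap_bp:
                return True
        return False

    survivors = _dedupe([rec for rec in base.records if not hit(rec)])
    out = base.with_records(survivors)
    return AlgebraResult(surviving=out, count=len(survivors),
                         mode="negative-eliminated")


def _dedupe(records: list[PeakRecord]) -> list[PeakRecord]:
    """Drop exact duplicate records, keeping first occurrence order."""
    seen: set[PeakRecord] = set()
    out = []
    for rec in records:
        if rec not in seen:
            seen.add(rec)
            out.append(rec)
    return out
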
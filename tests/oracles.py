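"""Independent brute-force oracles for the peak-set algebra.

All-pairs comparisons with no interval index — deliberately naive so
they stay independent of the implementation under test.  Vectorised
with numpy broadcasting for throughput only; the algorithm is still a
full base x other cross-product.
"""
from __future__ import annotations

import numpy as np

from enchip_peaks.model import PeakRecord, PeakSet


def shared_bases(a: PeakRecord, b: PeakRecord) -> int:
    """Per-base set-intersection size of two closed intervals."""
    if a.chrom != b.chrom:
        return 0
    bases_a = set(range(a.start, a.end + 1))
    bases_b = set(range(b.start, b.end + 1))
    return len(bases_a & bases_b)


def _arrays(ps: PeakSet, chrom_ids: dict[str, int]):
    for rec in ps.records:
        chrom_ids.setdefault(rec.chrom, len(chrom_ids))
    if not ps.records:
        return (np.empty(0, dtype=int),) * 3
    chrom = np.array([chrom_ids[r.chrom] for r in ps.records])
    start = np.array([r.start for r in ps.records])
    end = np.array([r.end for r in ps.records])
    return chrom, start, end


def _any_overlap(base: PeakSet, other: PeakSet,
                 min_bp: int) -> np.ndarray:
    """Boolean mask over base records: overlaps >= min_bp with any
    record of ``other`` (all-pairs)."""
    ids: dict[str, int] = {}
    bc, bs, be = _arrays(base, ids)
    oc, os_, oe = _arrays(other, ids)
    if len(bc) == 0 or len(oc) == 0:
        return np.zeros(len(bc), dtype=bool)
    same = bc[:, None] == oc[None, :]
    shared = (np.minimum(be[:, None], oe[None, :])
              - np.maximum(bs[:, None], os_[None, :]) + 1)
    return np.any(same & (shared >= min_bp), axis=1)


def brute_common(base: PeakSet, others: list[PeakSet],
                 min_bp: int = 1) -> list[PeakRecord]:
    """Base records overlapping every other set (deduplicated)."""
    mask = np.ones(len(base.records), dtype=bool)
    for other in others:
        mask &= _any_overlap(base, other, min_bp)
    return _dedupe([r for r, keep in zip(base.records, mask) if keep])


def brute_subtract(base: PeakSet, negatives: list[PeakSet],
                   min_bp: int = 1) -> list[PeakRecord]:
    """Base records overlapping the union of all negatives by < min_bp.

    The union of the negative records is formed per-base (a python set
    of positions) so union-range semantics are honoured even when
    min_bp > 1 and negative records are mutually adjacent.
    """
    if min_bp == 1:
        # union ranges are irrelevant at 1 bp: overlap-with-any suffices
        mask = np.zeros(len(base.records), dtype=bool)
        for neg in negatives:
            mask |= _any_overlap(base, neg, 1)
        return _dedupe([r for r, hit in zip(base.records, mask)
                        if not hit])
    union: dict[str, set[int]] = {}
    for neg in negatives:
        for rec in neg.records:
            union.setdefault(rec.chrom, set()).update(
                range(rec.start, rec.end + 1))
    survivors = []
    for rec in base.records:
        bases = union.get(rec.chrom, set())
        overlap = _max_run(sorted(
            p for p in range(rec.start, rec.end + 1) if p in bases))
        if overlap < min_bp:
            survivors.append(rec)
    return _dedupe(survivors)


def _max_run(positions: list[int]) -> int:
    best = run = 0
    prev = None
    for p in positions:
        run = run + 1 if prev is not None and p == prev + 1 else 1
        best = max(best, run)
        prev = p
    return best


def _dedupe(records: list[PeakRecord]) -> list[PeakRecord]:
    seen = set()
    out = []
    for rec in records:
        if rec not in seen:
            seen.add(rec)
            out.append(rec)
    return out
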
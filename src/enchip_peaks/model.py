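"""Core domain types: a MACS peak record and an ordered peak set.

Coordinates are 1-based closed intervals throughout the package (the
MACS ``peaks.xls`` convention); conversion to 0-based half-open happens
only at the BED boundary in :mod:`enchip_peaks.io_macs`.
"""
from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class PeakRecord:
    """One MACS peak: a genomic interval plus its enrichment statistics.

    Parameters
    ----------
    chrom
        Chromosome name, matched as an exact string elsewhere.
    start, end
        1-based inclusive interval bounds in bp; ``end >= start >= 1``.
    tags
        Number of sequencing reads (tags) supporting the peak.
    fold_enrichment
        Peak signal relative to input genomic DNA; positive.
    length
        Interval length in bp, ``end - start + 1``. Recomputed on
        construction if omitted.
    summit
        Summit offset within the peak (bp from ``start``), optional.
    neg10log10_pvalue
        MACS score, -10*log10(p-value), optional.
    fdr_percent
        False discovery rate in percent, optional.
    """

    chrom: str
    start: int
    end: int
    tags: int
    fold_enrichment: float
    length: int | None = None
    summit: int | None = None
    neg10log10_pvalue: float | None = None
    fdr_percent: float | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) must be >= start ({self.start})")
        if self.tags < 0:
            raise ValueError(f"tags must be >= 0, got {self.tags}")
        if self.fold_enrichment <= 0:
            raise ValueError(
                f"fold_enrichment must be > 0, got {self.fold_enrichment}")
        if self.length is None:
            object.__setattr__(self, "length", self.end - self.start + 1)

    @property
    def span(self) -> int:
        """Number of bases covered by the closed interval."""
        return self.end - self.start + 1

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class PeakSet:
    """An ordered, provenance-tagged collection of peaks from one file.

    Records are kept in canonical (chrom, start, end) order; the original
    ``#`` comment lines and the header line are preserved as metadata so
    that provenance survives the algebra.
    """

    source: str
    records: list[PeakRecord] = field(default_factory=list)
    comments: list[str] = field(default_factory=list)
    header: str | None = None

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=PeakRecord.sort_key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def with_records(self, records: list[PeakRecord],
                     source: str | None = None) -> "PeakSet":
        """A new set with the same provenance but different records."""
        return PeakSet(source=source or self.source,
                       records=list(records),
                       comments=list(self.comments),
                       header=self.header)
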
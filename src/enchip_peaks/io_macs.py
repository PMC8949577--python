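"""Reading MACS tab files and writing CSV/BED results.

The input dialect is the MACS 1.x ``peaks.xls`` export: tab-delimited
text, ``#``-prefixed comment lines, one header row naming the columns
(``chr start end length summit tags -10*log10(pvalue) fold_enrichment
FDR(%)``), then one peak per line.  Columns are mapped by header name
when a header is present, with positional fallback to the MACS 1.x
order otherwise.

Coordinates are 1-based closed on input and in memory; :func:`write_bed`
converts to BED's 0-based half-open convention (``bed_start = start - 1``,
``bed_end = end``).
"""
from __future__ import annotations

import csv
import logging
import re
from pathlib import Path

from .errors import PeakFormatError
from .model import PeakRecord, PeakSet

logger = logging.getLogger(__name__)

# Canonical column order for positional fallback and for output.
MACS_COLUMNS = ("chr", "start", "end", "length", "summit", "tags",
                "-10*log10(pvalue)", "fold_enrichment", "FDR(%)")

_REQUIRED = ("chrom", "start", "end", "tags", "fold_enrichment")

# header token (lower-cased, spaces stripped) -> internal field name
_HEADER_ALIASES = {
    "chr": "chrom", "chrom": "chrom", "chromosome": "chrom",
    "start": "start", "end": "end", "length": "length",
    "summit": "summit", "abs_summit": "summit",
    "tags": "tags", "tag": "tags", "tagnumber": "tags", "pileup": "tags",
    "fdr(%)": "fdr_percent", "fdr": "fdr_percent", "fdr%": "fdr_percent",
}


def _classify_header_token(token: str) -> str | None:
    key = token.strip().lower().replace(" ", "")
    if key in _HEADER_ALIASES:
        return _HEADER_ALIASES[key]
    if "log10" in key and ("pvalue" in key or "p-value" in key):
        return "neg10log10_pvalue"
    if "fold" in key:
        return "fold_enrichment"
    if "fdr" in key:
        return "fdr_percent"
    return None


def _is_number(token: str) -> bool:
    return re.fullmatch(r"[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?",
                        token.strip()) is not None


def _parse_int(token: str) -> int:
    # MACS prints integers plainly, but tolerate "12.0"
    value = float(token)
    if value != int(value):
        raise ValueError(f"expected integer, got {token!r}")
    return int(value)


def parse_macs_tab(path: str | Path, strict: bool = True) -> PeakSet:
    """Parse a MACS peak tab file into a :class:`PeakSet`.

    Comment lines (leading ``#``) and blank lines are skipped but the
    comments are retained as metadata.  The header is the first
    non-comment line whose second and third fields are non-numeric;
    without one, columns are mapped positionally in the MACS 1.x order.

    Parameters
    ----------
    path
        Tab-delimited peak file.
    strict
        If true (default), a malformed data line raises
        :class:`~enchip_peaks.errors.PeakFormatError` with its line
        number; if false, malformed lines are skipped and counted in a
        logged warning.

    Returns
    -------
    PeakSet
        Records in canonical (chrom, start, end) order, ``source`` set
        to the file path.
    """
    path = Path(path)
    comments: list[str] = []
    header_line: str | None = None
    column_map: dict[str, int] | None = None
    records: list[PeakRecord] = []
    n_skipped = 0

    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                comments.append(line)
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated files
                fields = line.split()
            if column_map is None:
                if len(fields) >= 3 and not _is_number(fields[1]) \
                        and not _is_number(fields[2]):
                    header_line = line
                    column_map = {}
                    for idx, token in enumerate(fields):
                        name = _classify_header_token(token)
                        if name is not None and name not in column_map:
                            column_map[name] = idx
                else:
                    # headerless file: positional MACS 1.x layout
                    column_map = {
                        "chrom": 0, "start": 1, "end": 2, "length": 3,
                        "summit": 4, "tags": 5, "neg10log10_pvalue": 6,
                        "fold_enrichment": 7, "fdr_percent": 8,
                    }
                missing = [c for c in _REQUIRED if c not in column_map]
                if missing:
                    raise PeakFormatError(
                        f"missing required column(s): {', '.join(missing)}",
                        path=str(path), line_number=lineno)
                if header_line is not None:
                    continue
            try:
                records.append(_record_from_fields(fields, column_map))
            except (ValueError, IndexError) as exc:
                if strict:
                    raise PeakFormatError(
                        f"malformed data line: {exc}",
                        path=str(path), line_number=lineno) from exc
                n_skipped += 1

    if column_map is None:
        # only comments (or nothing): legal empty set
        column_map = {}
    if n_skipped:
        logger.warning("%s: skipped %d malformed line(s)", path, n_skipped)

    return PeakSet(source=str(path), records=records,
                   comments=comments, header=header_line)


def _record_from_fields(fields: list[str],
                        column_map: dict[str, int]) -> PeakRecord:
    def get(name: str) -> str | None:
        idx = column_map.get(name)
        if idx is None or idx >= len(fields):
            return None
        token = fields[idx].strip()
        return token or None

    chrom = get("chrom")
    start_s, end_s = get("start"), get("end")
    tags_s, fold_s = get("tags"), get("fold_enrichment")
    if chrom is None or start_s is None or end_s is None \
            or tags_s is None or fold_s is None:
        raise ValueError("required field absent")

    start, end = _parse_int(start_s), _parse_int(end_s)
    length_s = get("length")
    length = _parse_int(length_s) if length_s is not None else None
    if length is not None and length not in (end - start + 1, end - start):
        logger.warning("length %d inconsistent with [%d, %d]; recomputing",
                       length, start, end)
    # length is derived, not primary: recompute so both MACS dialects
    # (end-start and end-start+1) normalise to the closed-interval span
    length = end - start + 1

    summit_s = get("summit")
    pval_s = get("neg10log10_pvalue")
    fdr_s = get("fdr_percent")
    return PeakRecord(
        chrom=chrom.strip(),
        start=start,
        end=end,
        length=length,
        summit=_parse_int(summit_s) if summit_s is not None else None,
        tags=_parse_int(tags_s),
        neg10log10_pvalue=float(pval_s) if pval_s is not None else None,
        fold_enrichment=float(fold_s),
        fdr_percent=float(fdr_s) if fdr_s is not None else None,
    )


def _format_number(value: int | float | None) -> str:
    if value is None:
        return ""
    if isinstance(value, int):
        return str(value)
    return repr(value)  # shortest round-trip representation


def _record_row(rec: PeakRecord) -> list[str]:
    return [rec.chrom,
            str(rec.start),
            str(rec.end),
            str(rec.length),
            _format_number(rec.summit),
            str(rec.tags),
            _format_number(rec.neg10log10_pvalue),
            _format_number(rec.fold_enrichment),
            _format_number(rec.fdr_percent)]


def write_csv(result: PeakSet, path: str | Path) -> None:
    """Write a peak set as RFC 4180 CSV: one header row, one row per
    record in canonical order.  Numbers use locale-independent,
    round-trip-stable formatting."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MACS_COLUMNS)
        for rec in result.records:
            writer.writerow(_record_row(rec))


def read_csv(path: str | Path) -> PeakSet:
    """Read back a CSV written by :func:`write_csv` into a PeakSet.

    Columns are mapped by header name exactly as for the tab dialect.
    """
    path = Path(path)
    records: list[PeakRecord] = []
    header_line: str | None = None
    column_map: dict[str, int] | None = None
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for lineno, fields in enumerate(csv.reader(fh), start=1):
            if not fields or not any(f.strip() for f in fields):
                continue
            if column_map is None:
                if len(fields) >= 3 and not _is_number(fields[1]) \
                        and not _is_number(fields[2]):
                    header_line = ",".join(fields)
                    column_map = {}
                    for idx, token in enumerate(fields):
                        name = _classify_header_token(token)
                        if name is not None and name not in column_map:
                            column_map[name] = idx
                    missing = [c for c in _REQUIRED if c not in column_map]
                    if missing:
                        raise PeakFormatError(
                            "missing required column(s): "
                            + ", ".join(missing),
                            path=str(path), line_number=lineno)
                    continue
                raise PeakFormatError("CSV file lacks a header row",
                                      path=str(path), line_number=lineno)
            try:
                records.append(_record_from_fields(fields, column_map))
            except (ValueError, IndexError) as exc:
                raise PeakFormatError(f"malformed data row: {exc}",
                                      path=str(path),
                                      line_number=lineno) from exc
    return PeakSet(source=str(path), records=records,
                   comments=[], header=header_line)


def write_macs_tab(result: PeakSet, path: str | Path) -> None:
    """Write a peak set back in the tab dialect (comments, header, data).

    Inverse of :func:`parse_macs_tab` up to number formatting; used by
    the synthetic generator and for staged intermediate files.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for comment in result.comments:
            fh.write(comment + "\n")
        fh.write((result.header or "\t".join(MACS_COLUMNS)) + "\n")
        for rec in result.records:
            fh.write("\t".join(_record_row(rec)) + "\n")


def write_bed(result: PeakSet, path: str | Path) -> None:
    """Write BED3+2: chrom, 0-based half-open start/end, name, score.

    A 1-based closed interval ``[start, end]`` becomes the half-open
    ``[start-1, end)``; ``name`` is ``<source basename>:<index>`` and
    ``score`` is the tag count.
    """
    stem = Path(result.source).name
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for i, rec in enumerate(result.records):
            fh.write(f"{rec.chrom}\t{rec.start - 1}\t{rec.end}\t"
                     f"{stem}:{i}\t{rec.tags}\n")
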
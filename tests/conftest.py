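"""Shared fixtures: tiny hand-written tab files and random peak-set
factories used across the suite."""
from __future__ import annotations

import random

import pytest

from enchip_peaks.model import PeakRecord, PeakSet

MACS_HEADER = ("chr\tstart\tend\tlength\tsummit\ttags\t"
               "-10*log10(pvalue)\tfold_enrichment\tFDR(%)")

SAMPLE_TAB = "\n".join([
    "# This file is generated by MACS",
    "# name = demo",
    "# format = BED",
    MACS_HEADER,
    "chr1\t1000\t1999\t1000\t420\t120\t512.33\t15.2\t0.4",
    "chr2\t5000\t5499\t500\t101\t30\t88.10\t8.5\t2.1",
    "",
])


@pytest.fixture
def sample_tab(tmp_path):
    """A 2-peak MACS tab file with three comment lines."""
    path = tmp_path / "demo_peaks.xls"
    path.write_text(SAMPLE_TAB, encoding="utf-8")
    return path


@pytest.fixture
def make_tab(tmp_path):
    """Factory writing a tab file from (chrom, start, end, tags, fold)
    tuples."""
    counter = {"n": 0}

    def _make(rows, name=None, comments=("# synthetic fixture",)):
        counter["n"] += 1
        path = tmp_path / (name or f"peaks_{counter['n']}.tab")
        lines = list(comments) + [MACS_HEADER]
        for chrom, start, end, tags, fold in rows:
            length = end - start + 1
            lines.append(f"{chrom}\t{start}\t{end}\t{length}\t"
                         f"{length // 2}\t{tags}\t100.0\t{fold}\t1.0")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return path

    return _make


def random_peak_set(rng: random.Random, n_peaks: int,
                    chroms=("chr1", "chr2", "chr3"),
                    pos_max: int = 10_000, len_max: int = 500,
                    source: str = "random") -> PeakSet:
    """Dense random peaks so overlaps between sets are frequent."""
    records = []
    for _ in range(n_peaks):
        start = rng.randint(1, pos_max)
        length = rng.randint(1, len_max)
        records.append(PeakRecord(
            chrom=rng.choice(chroms),
            start=start,
            end=start + length - 1,
            tags=rng.randint(0, 500),
            fold_enrichment=round(rng.uniform(0.5, 40.0), 3),
        ))
    return PeakSet(source=source, records=records)
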
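"""Peak-set algebra: common-peak extraction and negative elimination.

Two tiny hand-built peak lists share one region; a negative control
overlaps another. The surviving records always come verbatim from the
designated base file.
"""
from enchip_peaks import (PeakRecord, PeakSet, eliminate_negative,
                          extract_common)


def peak(chrom, start, end, tags, fold):
    return PeakRecord(chrom, start, end, tags=tags,
                      fold_enrichment=fold)


grna_a = PeakSet("gRNA_A", [
    peak("chr1", 1_000, 1_800, tags=120, fold=15.0),   # shared with B
    peak("chr1", 50_000, 50_900, tags=40, fold=8.0),   # only in A
    peak("chr2", 9_000, 9_700, tags=60, fold=12.0),    # off-target
])
grna_b = PeakSet("gRNA_B", [
    peak("chr1", 1_500, 2_300, tags=95, fold=13.0),    # shared with A
    peak("chr3", 7_000, 7_400, tags=25, fold=6.0),     # only in B
])
no_grna_control = PeakSet("no_gRNA", [
    peak("chr2", 8_800, 9_300, tags=55, fold=11.0),    # off-target site
])

common = extract_common(grna_a, [grna_b])
print(f"common peaks (base = {grna_a.source}): count = {common.count}")
for rec in common.surviving.records:
    print(f"  {rec.chrom}:{rec.start}-{rec.end} tags={rec.tags}")

specific = eliminate_negative(grna_a, [no_grna_control])
print(f"after eliminating control peaks: count = {specific.count}")
for rec in specific.surviving.records:
    print(f"  {rec.chrom}:{rec.start}-{rec.end}")

# count=1 for the common set: only the chr1 ~1-2 kb region appears in
# both gRNA lists, reported with the base file's exact coordinates.
# The chr2 peak vanishes after subtraction because it overlaps the
# no-gRNA control — the signature of a dCas9 off-target site.
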
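"""Tag-number and fold-enrichment filtering, including the relative
"tags >= 5 % of the target locus" rule.

The relative criterion is resolved against the peak overlapping the
target locus that has the highest tag count, then applied as an
ordinary absolute threshold.
"""
from enchip_peaks import (PeakRecord, PeakSet, TargetLocusSpec,
                          apply_filters, parse_criterion,
                          resolve_criteria)


def peak(start, end, tags, fold):
    return PeakRecord("chr1", start, end, tags=tags,
                      fold_enrichment=fold)


peaks = PeakSet("gRNA_A", [
    peak(5_000, 6_000, tags=1000, fold=60.0),   # the target-locus peak
    peak(20_000, 20_700, tags=80, fold=14.0),   # passes both criteria
    peak(40_000, 40_500, tags=30, fold=22.0),   # fails the 5 % rule
    peak(60_000, 60_900, tags=200, fold=9.9),   # fails fold >= 10
])
locus = TargetLocusSpec("chr1", 5_200, 5_800)

criteria = [parse_criterion("tags>=5%target"),
            parse_criterion("fe>=10")]
resolved = resolve_criteria(criteria, peaks, locus)
print(f"relative rule resolved: tags >= {resolved[0].threshold} "
      f"(5 % of the 1000-tag target peak)")

survivors = apply_filters(peaks, resolved)
print(f"{len(survivors)} of {len(peaks)} peaks pass both criteria:")
for rec in survivors.records:
    print(f"  chr1:{rec.start}-{rec.end} tags={rec.tags} "
          f"fold={rec.fold_enrichment}")

# Two peaks survive: the target peak itself and the 80-tag/fold-14
# peak. Thresholds are inclusive (a fold enrichment of exactly 10.0
# would pass fe>=10); 80 tags means the region was captured in ~8 % of
# pull-downs relative to the target locus.
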
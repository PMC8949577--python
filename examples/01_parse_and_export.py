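"""Parse a MACS peak tab file and export it as CSV and BED.

Builds a small synthetic peak list first so the script is
self-contained, then shows the parsed records and the coordinate
conversion applied on BED export.
"""
import tempfile
from pathlib import Path

from enchip_peaks import parse_macs_tab, write_bed, write_csv
from enchip_peaks.synthetic import (SyntheticParams,
                                    generate_synthetic_experiment)

with tempfile.TemporaryDirectory() as tmp:
    params = SyntheticParams(n_common=3, n_decoys_per_file=2,
                             n_offtargets=1)
    positives, _, _ = generate_synthetic_experiment(params, seed=5,
                                                    out_dir=tmp)
    tab_file = positives["g1"]

    peaks = parse_macs_tab(tab_file)
    print(f"parsed {len(peaks)} peaks from {Path(tab_file).name} "
          f"({len(peaks.comments)} comment lines preserved)")
    for rec in peaks.records[:3]:
        print(f"  {rec.chrom}:{rec.start}-{rec.end}  tags={rec.tags}  "
              f"fold={rec.fold_enrichment}")

    write_csv(peaks, Path(tmp) / "peaks.csv")
    write_bed(peaks, Path(tmp) / "peaks.bed")
    first = peaks.records[0]
    bed_line = (Path(tmp) / "peaks.bed").read_text().splitlines()[0]
    print(f"first record 1-based closed [{first.start}, {first.end}] "
          f"-> BED 0-based half-open: {bed_line.split(chr(9))[1]}-"
          f"{bed_line.split(chr(9))[2]}")

# The tag count is the number of sequencing reads supporting each peak;
# fold enrichment is signal over input DNA. BED start is start-1 because
# BED uses 0-based half-open coordinates.
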
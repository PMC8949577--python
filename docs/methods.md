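# Methods

## Data model and coordinate conventions

A peak is a row of a MACS 1.x `peaks.xls`-style tab export: chromosome,
1-based closed start/end, length, summit offset, tag count, a
−10·log10(p-value) score, fold enrichment over input, and FDR in
percent. Columns are mapped by header name when a header row is present
(the first non-comment line whose second and third fields are
non-numeric), with positional fallback to the MACS 1.x order. `#`
comment lines and blank lines never contribute records but are retained
as metadata. Chromosome names are compared as exact trimmed strings; no
`chr`-prefix normalisation is applied, since silent renaming can create
false overlaps.

All in-memory intervals are 1-based closed. `length` is treated as
derived: files in which `length = end − start` (a dialect some exports
use) are accepted with a warning and the span is recomputed as
`end − start + 1`. BED output is the only place coordinates change
convention (0-based half-open, `bed_start = start − 1`).

Duplicate identical records are retained on parse to preserve input
fidelity; the set algebra reports each surviving base record at most
once, however many partners it overlaps.

## Set algebra

Two peaks overlap when they lie on the same chromosome and their closed
intervals share at least `min_overlap_bp` bases
(`min(end_a, end_b) − max(start_a, start_b) + 1 ≥ min_overlap_bp`).
The default is 1 bp — any overlap, including a single shared boundary
base — because the extent of required overlap is a free parameter of
the method; it is exposed rather than fixed.

Both operations are base-centric and return base records verbatim:

* **Common extraction**: a base record survives if it overlaps at
  least one record in *each* other set individually. Across more than
  two files this is the AND of pairwise overlap with the base, not a
  requirement that one genomic position be shared by all sets
  simultaneously; the stricter mutual-position variant is available via
  `mutual=True`, implemented by intersecting the base interval with the
  merged coverage of every other set.
* **Negative elimination**: the pooled negative records are first
  merged into union ranges (overlapping *or adjacent* closed intervals
  fuse, since their base sets are contiguous); a base record survives
  only if it overlaps no union range by `min_overlap_bp` or more. At
  the default 1 bp this coincides with "overlaps any negative record",
  but for larger thresholds the union semantics matter when negatives
  abut.

Overlap queries use a per-chromosome interval tree; the test suite
checks the indexed implementation exactly against a naive all-pairs
oracle (and, for union elimination, a per-base position-set oracle) on
~1,000 randomized instances.

## Filtering

Criteria are `(field, comparator, threshold)` with field in
{tags, fold_enrichment} and the inclusive comparator set {≥, =, ≤};
multiple criteria combine by logical AND. Equality on tag counts is
exact; on fold enrichment it holds within an absolute tolerance of
1e-6, because fold enrichment is a printed decimal and exact float
equality is meaningless.

A relative criterion (`tags>=5%target`) is resolved per peak list: the
referent is the peak overlapping the configured target locus with the
highest tag count (leftmost start on ties — the target-locus peak is
the dominant signal by construction, and the tie-break makes resolution
deterministic), and the absolute threshold is `percent/100 × referent
tags`, deliberately not rounded to an integer so results do not depend
on a floor/ceil choice. If no peak overlaps the locus, resolution fails
with an instructive error: the target must appear in its own enChIP
peak list. Locating the referent by coordinate overlap (rather than by
peak ID or manual entry) is a design choice of this package.

## The two-step workflow

Per gRNA list: eliminate peaks overlapping the negative-control union,
then apply the two confidence criteria (tags ≥ `tag_percent` % of that
list's own target peak, fold enrichment ≥ `fold_enrichment_min`;
defaults 5 and 10). The 5 % referent is resolved within each gRNA's
own list because each enChIP experiment has its own enrichment level.
Elimination precedes filtering, matching the narrative order of the
procedure; the `order_independence_check` harness verifies that
subtraction and intersection commute on given inputs (filtering is
excluded from the commuted variant since its relative threshold is
file-specific). Commutativity is a property of the data, not a theorem:
it can fail when a base record's only partner in another list is itself
eliminated by a negative while the base record is not. On generated
scenarios it always holds, because records of one planted locus overlap
negatives consistently across files.

When at least two gRNA lists are given, Step 2 extracts the records of
the base list (the first-listed gRNA unless overridden; the method
requires an explicit base but prescribes no selection rule) common to
all per-gRNA specific lists. Zero survivors at any stage is a valid,
logged outcome. Per-stage CSVs (`<gRNA>_specific.csv`, `common.csv`)
and a tab-separated count log are written when an output directory is
configured; identical inputs and configuration yield byte-identical
outputs.

## Synthetic experiments

The generator emulates the comparison design of a multi-gRNA study on
a 3 × 10 Mb synthetic genome with 200–2000 bp peaks — desk-scale sizes
at which collision-free placement is easy to guarantee. Four planted
categories occupy pairwise non-overlapping loci (separated by more than
twice the jitter): a target-locus peak in every positive file (1000
tags, fold 60, so the 5 % rule resolves to 50 tags), common peaks in
every positive file and no negative, decoys in exactly one positive
file each, and off-target peaks in every positive *and* negative file.
Per-file realisations jitter by up to ±50 bp (bounded below half the
minimum peak length, so records of one locus always overlap across
files) and draw tags and fold enrichment independently: common peaks
uniform-integer tags on [10, 200] and fold on [5, 30], both straddling
the 50-tag and fold-10 thresholds so every filter branch is exercised;
decoys and off-targets use [20, 300] and [5, 40]. All draws come from
one seeded generator, making files byte-reproducible.

Ground truth records, per planted locus, the exact per-file records,
and `expected_common` derives which loci must survive: those passing
both criteria in every positive file. The planted target-locus peak is
itself genuinely common, absent from negatives and passes its own
criteria, so it is part of the expected final set — the workflow does
not special-case it, and reports it alongside the interacting regions.

What passing tests show — and do not show — about real data: the
generator plants clean, non-overlapping, well-separated peaks with
consistent cross-file overlap, so perfect precision and recall here
demonstrate the correctness of the algebra and workflow wiring, not
robustness to partially overlapping peak calls, copy-number artefacts,
blacklist regions, or MACS model variation between samples. Those
properties belong to the upstream peak caller and experimental design.

## Numerical and degenerate-input choices

* CSV floats are written with Python's shortest round-trip
  representation; tab files written by the generator round fold
  enrichment, p-value score and FDR to two decimals at draw time, so
  write → parse → write is byte-stable.
* An empty peak list is legal everywhere (an empty *negative file* is
  the identity for elimination); an empty list of negative *files* is
  an invocation error, mirroring the required inputs of the procedure.
* Problem sizes in the test suite and acceptance script (hundreds of
  randomized instances of ≤ 200 peaks, ~100 generated experiments)
  were chosen as the smallest scales at which every code path and both
  filter branches are exercised; all checks are exact, so larger sizes
  add runtime, not information.

## Known limitations

* MACS2 `narrowPeak`/`broadPeak` are not parsed natively (convert
  externally); Excel binary exports are out of scope.
* Peaks are never merged into consensus intervals, and no statistical
  significance (permutation or otherwise) is attached to overlaps —
  the method is deterministic set algebra.
* Filtering on the p-value/FDR columns is not implemented, as the
  workflow's criteria use tags and fold enrichment only.
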
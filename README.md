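# enchip-peaks

Consolidation of MACS peak lists from enChIP-Seq experiments.

enChIP-Seq (engineered DNA-binding molecule-mediated ChIP followed by
sequencing) identifies genomic regions physically associated with a
chosen target locus: a nuclease-dead Cas9 tagged at the locus by a
guide RNA is immunoprecipitated together with its cross-linked
interaction partners, and the pulled-down DNA is sequenced and
peak-called with MACS. Two systematic artefacts must then be removed
from each per-gRNA peak list before the remaining peaks can be read as
genuine chromatin interactions:

1. **dCas9 off-target binding** — peaks that also appear in negative
   controls (enChIP without a gRNA, or with an irrelevant gRNA);
2. **weak, irreproducible enrichment** — peaks that fail the two
   confidence criteria
   * tag number ≥ 5 % of the tag number of the target-locus peak in the
     same list (an interacting ratio of ≥ 5 %), and
   * fold enrichment over input genomic DNA ≥ 10.

With several gRNAs tiling the target locus as quasi-replicates, peaks
surviving both steps in **every** gRNA's list — the cross-gRNA common
peaks — are the bona fide physically interacting regions.

This package implements that consolidation as a library plus a thin
CLI: MACS tab-file parsing, base-file-centric interval set algebra on
1-based closed coordinates (any overlap of ≥ 1 bp counts by default,
configurable), threshold filtering with the inclusive comparator set
{≥, =, ≤}, the two-step workflow, CSV/BED export, and a deterministic
synthetic-experiment generator with planted ground truth for testing.

## The operations

For a designated *base* peak list `B` and other lists `S₁…Sₖ`, with
overlap predicate `ov(a,b)` (shared bases of the closed intervals
≥ `min_overlap_bp`):

* **common extraction** keeps `b ∈ B` with `∀i ∃s ∈ Sᵢ : ov(b,s)` —
  records are reported verbatim from the base file, never merged;
* **negative elimination** keeps `b ∈ B` overlapping no union range of
  the pooled negative records;
* **filtering** keeps records satisfying the conjunction of criteria
  such as `tags>=5%target` (resolved per list against the highest-tag
  peak overlapping the target locus) and `fe>=10`.

## Worked example

`examples/04_full_workflow.py` generates a two-gRNA experiment with
six planted interacting regions, 20 decoys per file and 15 shared
off-target sites, then runs both steps:

```
g1:parsed: 42
g1:after_subtraction: 27
g1:after_filters: 25
g2:parsed: 42
g2:after_subtraction: 27
g2:after_filters: 24
common: 7

final common peaks (base = g1):
  chr1:2569480-2571169 tags=129 fold=13.32
  ...
  chr2:7550803-7551923 tags=1000 fold=60.0
```

Each gRNA list starts with 42 peaks; subtraction removes the 15
off-target sites, filtering removes low-confidence peaks, and the
cross-gRNA intersection leaves 7 common peaks: the 1000-tag
target-locus peak itself plus the six planted interacting regions.
Decoys never survive Step 2 because they are file-specific.

The same run from the shell:

```sh
enchip-peaks synth --out data --seed 1
enchip-peaks run --config workflow.yaml --out results
```

where `workflow.yaml` names the positive files per gRNA label, the
negative files, the target locus and the thresholds:

```yaml
positive_files: {g1: data/g1.tab, g2: data/g2.tab}
negative_files: [data/neg1.tab]
target_locus: {chrom: chr2, start: 7550853, end: 7551873}
tag_percent: 5
fold_enrichment_min: 10
```

Single operations are available as `enchip-peaks common`, `subtract`,
`filter` and `show`; every command logs the surviving-record `count`.

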
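"""Synthetic enChIP-Seq experiments with planted ground truth.

The generator emulates the comparison design of a multi-gRNA enChIP-Seq
study: several "positive" MACS peak lists (one per on-target gRNA), one
or more "negative" lists (no-gRNA / irrelevant-gRNA controls), and four
planted peak categories —

* the **target-locus peak**: one high-tag, high-fold-enrichment peak at
  the tagged locus, present in every positive file;
* **common peaks**: genuine interacting regions, present in every
  positive file and absent from negatives;
* **decoy peaks**: file-specific noise, present in exactly one positive
  file;
* **off-target peaks**: dCas9 off-target binding, present in every
  positive *and* every negative file.

Category placements are pairwise non-overlapping genomic intervals
(separated by more than twice the jitter), so overlap relations between
files are exactly the planted ones.  Per-file coordinates jitter by up
to ``jitter_bp`` around the canonical placement, and per-file tag counts
and fold enrichments are drawn independently, so a planted common peak
may pass the tag/fold filters in one file and fail them in another —
both filter branches are exercised.  Everything is deterministic given
the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import GenerationError
from .filters import TargetLocusSpec
from .io_macs import write_macs_tab
from .model import PeakRecord, PeakSet

DEFAULT_CHROM_SIZES = {"chr1": 10_000_000, "chr2": 10_000_000,
                       "chr3": 10_000_000}


@dataclass(frozen=True)
class SyntheticParams:
    """Knobs of the synthetic experiment.

    Defaults describe a desk-scale study: two gRNAs, one negative
    control, a 1000-tag target peak so that the 5 % relative rule
    resolves to 50 tags, common-peak tags uniform on [10, 200] and fold
    enrichments uniform on [5, 30] so both straddle the canonical
    thresholds (50 tags, fold 10).
    """

    n_grnas: int = 2
    n_negatives: int = 1
    n_common: int = 6
    n_decoys_per_file: int = 20
    n_offtargets: int = 15
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_SIZES))
    peak_length_range: tuple[int, int] = (200, 2000)
    jitter_bp: int = 50
    target_tags: int = 1000
    target_fold: float = 60.0
    common_tags_range: tuple[int, int] = (10, 200)
    common_fold_range: tuple[float, float] = (5.0, 30.0)
    noise_tags_range: tuple[int, int] = (20, 300)
    noise_fold_range: tuple[float, float] = (5.0, 40.0)


@dataclass
class PlantedPeak:
    """One planted locus: canonical interval plus its per-file records."""

    chrom: str
    start: int
    end: int
    category: str  # target | common | decoy | offtarget
    per_file: dict[str, PeakRecord] = field(default_factory=dict)


@dataclass
class SyntheticTruth:
    """Ground truth of a generated experiment."""

    target_locus: TargetLocusSpec
    target_peak: PlantedPeak
    common_peaks: list[PlantedPeak]
    decoy_peaks: dict[str, list[PlantedPeak]]  # positive label -> decoys
    offtarget_peaks: list[PlantedPeak]
    positive_labels: list[str]
    negative_labels: list[str]
    seed: int
    params: SyntheticParams

    def expected_common(self, base_label: str, tag_percent: float = 5.0,
                        fold_enrichment_min: float = 10.0
                        ) -> list[PeakRecord]:
        """Base-file records that the two-step workflow must recover.

        A planted common peak is recoverable iff its per-file record
        passes both criteria (tags >= tag_percent % of that file's
        target tags, fold enrichment >= the minimum) in *every*
        positive file.  The target-locus peak itself is genuinely
        common, absent from negatives and passes its own criteria, so
        it is part of the expectation.
        """
        expected = []
        if self._passes_everywhere(self.target_peak, tag_percent,
                                   fold_enrichment_min):
            expected.append(self.target_peak.per_file[base_label])
        for peak in self.common_peaks:
            if self._passes_everywhere(peak, tag_percent,
                                       fold_enrichment_min):
                expected.append(peak.per_file[base_label])
        return sorted(expected, key=PeakRecord.sort_key)

    def _passes_everywhere(self, peak: PlantedPeak, tag_percent: float,
                           fold_min: float) -> bool:
        for label in self.positive_labels:
            rec = peak.per_file[label]
            threshold = tag_percent / 100.0 \
                * self.target_peak.per_file[label].tags
            if rec.tags < threshold or rec.fold_enrichment < fold_min:
                return False
        return True


def generate_synthetic_experiment(
        params: SyntheticParams = SyntheticParams(),
        seed: int = 0,
        out_dir: str | Path | None = None,
) -> tuple[dict[str, Path], list[Path], SyntheticTruth]:
    """Generate one synthetic experiment and write its MACS tab files.

    Returns ``(positive_files, negative_files, truth)`` where
    ``positive_files`` maps gRNA labels (``g1``, ``g2``, ...) to file
    paths and ``negative_files`` lists the control file paths.  With
    ``out_dir=None`` no files are written and the paths are the labels
    themselves (the per-file records are always available via
    ``truth``).

    Deterministic: the same ``params`` and ``seed`` produce
    byte-identical files.
    """
    if 2 * params.jitter_bp >= params.peak_length_range[0]:
        raise GenerationError(
            "jitter_bp must be < half the minimum peak length so that "
            "records of one planted locus always overlap across files")
    rng = np.random.default_rng(seed)
    pos_labels = [f"g{i + 1}" for i in range(params.n_grnas)]
    neg_labels = [f"neg{i + 1}" for i in range(params.n_negatives)]

    n_loci = (1 + params.n_common + params.n_offtargets
              + params.n_decoys_per_file * params.n_grnas)
    placements = _place_loci(rng, params, n_loci)

    cursor = iter(placements)
    target = _plant(next(cursor), "target")
    commons = [_plant(next(cursor), "common")
               for _ in range(params.n_common)]
    offtargets = [_plant(next(cursor), "offtarget")
                  for _ in range(params.n_offtargets)]
    decoys = {label: [_plant(next(cursor), "decoy")
                      for _ in range(params.n_decoys_per_file)]
              for label in pos_labels}

    for label in pos_labels:
        _realise(rng, target, label, params, is_target=True)
        for peak in commons:
            _realise(rng, peak, label, params,
                     tags_range=params.common_tags_range,
                     fold_range=params.common_fold_range)
        for peak in offtargets:
            _realise(rng, peak, label, params)
        for peak in decoys[label]:
            _realise(rng, peak, label, params)
    for label in neg_labels:
        for peak in offtargets:
            _realise(rng, peak, label, params)

    truth = SyntheticTruth(
        target_locus=TargetLocusSpec(target.chrom, target.start,
                                     target.end),
        target_peak=target,
        common_peaks=commons,
        decoy_peaks=decoys,
        offtarget_peaks=offtargets,
        positive_labels=pos_labels,
        negative_labels=neg_labels,
        seed=seed,
        params=params,
    )

    positives: dict[str, Path] = {}
    negatives: list[Path] = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for label in pos_labels:
            path = out_dir / f"{label}.tab"
            write_macs_tab(peak_set_for(truth, label), path)
            positives[label] = path
        for label in neg_labels:
            path = out_dir / f"{label}.tab"
            write_macs_tab(peak_set_for(truth, label), path)
            negatives.append(path)
    else:
        positives = {label: Path(label) for label in pos_labels}
        negatives = [Path(label) for label in neg_labels]
    return positives, negatives, truth


def peak_set_for(truth: SyntheticTruth, label: str) -> PeakSet:
    """Assemble the in-memory PeakSet of one synthetic file."""
    records = []
    planted: list[PlantedPeak] = [truth.target_peak, *truth.common_peaks,
                                  *truth.offtarget_peaks]
    for decoy_list in truth.decoy_peaks.values():
        planted.extend(decoy_list)
    for peak in planted:
        rec = peak.per_file.get(label)
        if rec is not None:
            records.append(rec)
    comments = [f"# synthetic enChIP-Seq peak list, sample = {label}",
                f"# seed = {truth.seed}"]
    return PeakSet(source=label, records=records, comments=comments)


def _place_loci(rng: np.random.Generator, params: SyntheticParams,
                n_loci: int) -> list[tuple[str, int, int]]:
    """Non-overlapping canonical placements, separated by > 2*jitter."""
    chroms = list(params.chrom_sizes)
    min_gap = 2 * params.jitter_bp + 10
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    placements: list[tuple[str, int, int]] = []
    max_len = params.peak_length_range[1]
    genome = sum(params.chrom_sizes.values())
    if n_loci * (max_len + min_gap) > genome:
        raise GenerationError(
            f"cannot place {n_loci} peaks of up to {max_len} bp in a "
            f"{genome} bp genome without overlap")
    attempts = 0
    while len(placements) < n_loci:
        attempts += 1
        if attempts > 200 * n_loci:
            raise GenerationError(
                "placement failed; genome too crowded for the "
                "requested peak counts")
        chrom = chroms[int(rng.integers(len(chroms)))]
        size = params.chrom_sizes[chrom]
        length = int(rng.integers(params.peak_length_range[0],
                                  params.peak_length_range[1] + 1))
        start = int(rng.integers(1 + params.jitter_bp,
                                 size - length - params.jitter_bp))
        end = start + length - 1
        clash = any(start - min_gap <= e and end + min_gap >= s
                    for s, e in occupied[chrom])
        if clash:
            continue
        occupied[chrom].append((start, end))
        placements.append((chrom, start, end))
    return placements


def _plant(placement: tuple[str, int, int], category: str) -> PlantedPeak:
    chrom, start, end = placement
    return PlantedPeak(chrom=chrom, start=start, end=end,
                       category=category)


def _realise(rng: np.random.Generator, peak: PlantedPeak, label: str,
             params: SyntheticParams, is_target: bool = False,
             tags_range: tuple[int, int] | None = None,
             fold_range: tuple[float, float] | None = None) -> None:
    """Draw one file's record of a planted peak (jitter, tags, fold)."""
    jitter = int(rng.integers(-params.jitter_bp, params.jitter_bp + 1)) \
        if params.jitter_bp else 0
    start, end = peak.start + jitter, peak.end + jitter
    if is_target:
        tags, fold = params.target_tags, params.target_fold
    else:
        lo, hi = tags_range or params.noise_tags_range
        tags = int(rng.integers(lo, hi + 1))
        flo, fhi = fold_range or params.noise_fold_range
        fold = round(float(rng.uniform(flo, fhi)), 2)
    summit = int(rng.integers(1, end - start + 1))
    pvalue = round(float(rng.uniform(50.0, 3000.0)), 2)
    fdr = round(float(rng.uniform(0.0, 5.0)), 2)
    peak.per_file[label] = PeakRecord(
        chrom=peak.chrom, start=start, end=end, tags=tags,
        fold_enrichment=fold, summit=summit,
        neg10log10_pvalue=pvalue, fdr_percent=fdr)
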
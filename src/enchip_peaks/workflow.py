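"""The two-step consolidation pipeline.

Step 1, per gRNA: eliminate off-target peaks (those overlapping the
union of the negative-control peak lists), then filter the survivors on
(i) tag number >= ``tag_percent`` % of that file's own target-locus
peak tag count and (ii) fold enrichment >= ``fold_enrichment_min``.

Step 2 (when two or more gRNAs are given): extract the peaks common to
all per-gRNA specific lists, reported as records of the base gRNA's
file.

The 5 % referent is resolved per gRNA file against that file's own
target-locus peak, since each enChIP experiment has its own enrichment
level.  Zero survivors at any stage is a valid outcome, not an error.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from .errors import UsageError
from .filters import (Comparator, FilterCriterion, TargetLocusSpec,
                      apply_filters, resolve_criteria)
from .intervals import (AlgebraResult, OverlapRule, eliminate_negative,
                        extract_common)
from .io_macs import parse_macs_tab, write_csv
from .model import PeakSet

logger = logging.getLogger(__name__)


@dataclass
class WorkflowConfig:
    """Inputs and parameters of the two-step pipeline.

    ``positive_files`` maps gRNA labels to MACS tab files (insertion
    order matters: the first entry is the default base for Step 2);
    ``negative_files`` lists the control peak files.
    """

    positive_files: dict[str, Path]
    negative_files: list[Path]
    target_locus: TargetLocusSpec
    tag_percent: float = 5.0
    fold_enrichment_min: float = 10.0
    overlap_rule: OverlapRule = field(default_factory=OverlapRule)
    output_dir: Path | None = None
    base_label: str | None = None

    def __post_init__(self) -> None:
        if not self.positive_files:
            raise UsageError("at least one positive (gRNA) file required")
        if not self.negative_files:
            raise UsageError("at least one negative-control file required")
        if not 0 <= self.tag_percent <= 100:
            raise UsageError("tag_percent must lie in [0, 100]")
        if self.fold_enrichment_min < 0:
            raise UsageError("fold_enrichment_min must be >= 0")
        if self.base_label is None:
            self.base_label = next(iter(self.positive_files))
        elif self.base_label not in self.positive_files:
            raise UsageError(
                f"base label {self.base_label!r} is not among the "
                f"positive files {list(self.positive_files)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorkflowConfig":
        """Load a config from a YAML file (schema in the README)."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        locus = raw["target_locus"]
        return cls(
            positive_files={str(k): Path(v)
                            for k, v in raw["positive_files"].items()},
            negative_files=[Path(p) for p in raw["negative_files"]],
            target_locus=TargetLocusSpec(str(locus["chrom"]),
                                         int(locus["start"]),
                                         int(locus["end"])),
            tag_percent=float(raw.get("tag_percent", 5.0)),
            fold_enrichment_min=float(raw.get("fold_enrichment_min", 10.0)),
            overlap_rule=OverlapRule(int(raw.get("min_overlap_bp", 1))),
            output_dir=Path(raw["output_dir"])
            if raw.get("output_dir") else None,
            base_label=raw.get("base"),
        )


@dataclass
class WorkflowReport:
    """Per-stage results and counts of one pipeline run."""

    per_grna_specific: dict[str, AlgebraResult]
    common: AlgebraResult | None
    counts: dict[str, int]
    provenance: dict

    @property
    def common_count(self) -> int:
        return self.common.count if self.common is not None else 0


def run_workflow(config: WorkflowConfig,
                 peak_sets: dict[str, PeakSet] | None = None,
                 negative_sets: list[PeakSet] | None = None
                 ) -> WorkflowReport:
    """Run Step 1 (subtract off-targets, filter) per gRNA, then Step 2
    (cross-gRNA common-peak extraction).

    ``peak_sets``/``negative_sets`` allow pre-parsed inputs (used by
    the synthetic-experiment tests); by default the files named in the
    config are parsed.  When ``config.output_dir`` is set, per-stage
    CSVs (``<gRNA>_specific.csv``, ``common.csv``) and a run log are
    written.
    """
    if peak_sets is None:
        peak_sets = {label: parse_macs_tab(path)
                     for label, path in config.positive_files.items()}
    if negative_sets is None:
        negative_sets = [parse_macs_tab(p) for p in config.negative_files]

    counts: dict[str, int] = {}
    per_grna: dict[str, AlgebraResult] = {}
    criteria = [
        FilterCriterion("tags", Comparator.GE, config.tag_percent,
                        relative_to_target=True),
        FilterCriterion("fold_enrichment", Comparator.GE,
                        config.fold_enrichment_min),
    ]
    for label, peaks in peak_sets.items():
        counts[f"{label}:parsed"] = len(peaks)
        subtracted = eliminate_negative(peaks, negative_sets,
                                        config.overlap_rule)
        counts[f"{label}:after_subtraction"] = subtracted.count
        resolved = resolve_criteria(criteria, peaks, config.target_locus)
        filtered = apply_filters(subtracted.surviving, resolved)
        result = AlgebraResult(surviving=filtered, count=len(filtered),
                               mode="negative-eliminated")
        counts[f"{label}:after_filters"] = result.count
        per_grna[label] = result
        logger.info("Step 1 [%s]: %d parsed -> %d after subtraction "
                    "-> %d after filters", label, len(peaks),
                    subtracted.count, result.count)

    common: AlgebraResult | None = None
    if len(per_grna) >= 2:
        base = per_grna[config.base_label].surviving
        others = [res.surviving for label, res in per_grna.items()
                  if label != config.base_label]
        common = extract_common(base, others, config.overlap_rule)
        counts["common"] = common.count
        logger.info("Step 2: %d common peak(s), base = %s",
                    common.count, config.base_label)

    report = WorkflowReport(
        per_grna_specific=per_grna,
        common=common,
        counts=counts,
        provenance={
            "base": config.base_label,
            "tag_percent": config.tag_percent,
            "fold_enrichment_min": config.fold_enrichment_min,
            "min_overlap_bp": config.overlap_rule.min_overlap_bp,
            "positive_files": {k: str(v)
                               for k, v in config.positive_files.items()},
            "negative_files": [str(p) for p in config.negative_files],
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
    )
    if config.output_dir is not None:
        _write_outputs(report, config)
    return report


def _write_outputs(report: WorkflowReport, config: WorkflowConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for label, result in report.per_grna_specific.items():
        write_csv(result.surviving, out / f"{label}_specific.csv")
    if report.common is not None:
        write_csv(report.common.surviving, out / "common.csv")
    log_lines = [f"{stage}\t{count}"
                 for stage, count in report.counts.items()]
    (out / "run_log.tsv").write_text("\n".join(log_lines) + "\n",
                                     encoding="utf-8")


def order_independence_check(config: WorkflowConfig,
                             peak_sets: dict[str, PeakSet] | None = None,
                             negative_sets: list[PeakSet] | None = None
                             ) -> bool:
    """Whether subtract-then-intersect equals intersect-then-subtract.

    Filtering is excluded from the commuted variant because the
    relative tag threshold is file-specific and does not commute with
    intersection.  A property harness for users and tests; union-based
    elimination makes the two orders agree, and any counterexample
    would indicate a defect.
    """
    if len(config.positive_files) < 2:
        raise UsageError("order-independence check needs >=2 positives")
    if peak_sets is None:
        peak_sets = {label: parse_macs_tab(path)
                     for label, path in config.positive_files.items()}
    if negative_sets is None:
        negative_sets = [parse_macs_tab(p) for p in config.negative_files]

    base_label = config.base_label
    rule = config.overlap_rule
    others = [peak_sets[label] for label in peak_sets
              if label != base_label]

    # subtract first, then intersect the subtracted sets
    sub = {label: eliminate_negative(ps, negative_sets, rule).surviving
           for label, ps in peak_sets.items()}
    sub_then_int = extract_common(
        sub[base_label],
        [sub[label] for label in peak_sets if label != base_label],
        rule)

    # intersect first, then subtract
    common_first = extract_common(peak_sets[base_label], others, rule)
    int_then_sub = eliminate_negative(common_first.surviving,
                                      negative_sets, rule)

    return (sub_then_int.surviving.records
            == int_then_sub.surviving.records)
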
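"""The two-step pipeline: composition, ground-truth recovery,
order independence, config handling."""
import pytest

from enchip_peaks import (OverlapRule, TargetLocusSpec, UsageError,
                          WorkflowConfig, apply_filters,
                          eliminate_negative, extract_common,
                          order_independence_check, parse_criterion,
                          parse_macs_tab, resolve_criteria, run_workflow)
from enchip_peaks.synthetic import (SyntheticParams,
                                    generate_synthetic_experiment,
                                    peak_set_for)


@pytest.fixture(scope="module")
def experiment(tmp_path_factory):
    out = tmp_path_factory.mktemp("exp")
    params = SyntheticParams(n_grnas=2, n_negatives=1)
    positives, negatives, truth = generate_synthetic_experiment(
        params, seed=101, out_dir=out)
    config = WorkflowConfig(positive_files=positives,
                            negative_files=negatives,
                            target_locus=truth.target_locus)
    return config, truth


class TestRunWorkflow:
    def test_recovers_planted_common_peaks(self, experiment):
        config, truth = experiment
        report = run_workflow(config)
        expected = truth.expected_common(config.base_label)
        assert report.common.surviving.records == expected
        assert report.common.count == len(expected)

    def test_no_decoys_or_offtargets_survive(self, experiment):
        config, truth = experiment
        report = run_workflow(config)
        survived = {(r.chrom, r.start, r.end)
                    for r in report.common.surviving.records}
        for label, decoys in truth.decoy_peaks.items():
            for peak in decoys:
                for rec in peak.per_file.values():
                    assert (rec.chrom, rec.start, rec.end) not in survived
        for peak in truth.offtarget_peaks:
            for rec in peak.per_file.values():
                assert (rec.chrom, rec.start, rec.end) not in survived

    def test_staged_equals_monolithic(self, experiment):
        """run_workflow is exactly the manual composition of the module
        operations."""
        config, truth = experiment
        report = run_workflow(config)
        criteria = [parse_criterion(f"tags>={config.tag_percent}%target"),
                    parse_criterion(f"fe>={config.fold_enrichment_min}")]
        negs = [parse_macs_tab(p) for p in config.negative_files]
        staged = {}
        for label, path in config.positive_files.items():
            peaks = parse_macs_tab(path)
            subtracted = eliminate_negative(peaks, negs,
                                            config.overlap_rule)
            resolved = resolve_criteria(criteria, peaks,
                                        config.target_locus)
            staged[label] = apply_filters(subtracted.surviving, resolved)
        for label in config.positive_files:
            assert report.per_grna_specific[label].surviving.records \
                == staged[label].records
        manual_common = extract_common(
            staged[config.base_label],
            [staged[lb] for lb in staged if lb != config.base_label],
            config.overlap_rule)
        assert report.common.surviving.records \
            == manual_common.surviving.records

    def test_report_counts_consistent(self, experiment):
        config, _ = experiment
        report = run_workflow(config)
        for label, result in report.per_grna_specific.items():
            assert report.counts[f"{label}:after_filters"] == result.count
        assert report.counts["common"] == report.common.count

    def test_single_positive_skips_step2(self, experiment):
        config, truth = experiment
        label = config.base_label
        solo = WorkflowConfig(
            positive_files={label: config.positive_files[label]},
            negative_files=config.negative_files,
            target_locus=config.target_locus)
        report = run_workflow(solo)
        assert report.common is None
        assert report.common_count == 0

    def test_zero_survivors_is_not_an_error(self, experiment):
        config, _ = experiment
        strict = WorkflowConfig(positive_files=config.positive_files,
                                negative_files=config.negative_files,
                                target_locus=config.target_locus,
                                tag_percent=100.0,
                                fold_enrichment_min=1000.0)
        report = run_workflow(strict)
        # only a peak as enriched as the target itself could pass
        assert report.common.count <= 1

    def test_tag_percent_sweep_is_non_increasing(self, experiment):
        config, _ = experiment
        previous = None
        for pct in (0.0, 5.0, 20.0, 60.0, 100.0):
            cfg = WorkflowConfig(positive_files=config.positive_files,
                                 negative_files=config.negative_files,
                                 target_locus=config.target_locus,
                                 tag_percent=pct)
            count = run_workflow(cfg).common.count
            if previous is not None:
                assert count <= previous
            previous = count

    def test_byte_identical_outputs_across_runs(self, experiment,
                                                tmp_path):
        config, _ = experiment
        outputs = []
        for run_dir in ("r1", "r2"):
            cfg = WorkflowConfig(positive_files=config.positive_files,
                                 negative_files=config.negative_files,
                                 target_locus=config.target_locus,
                                 output_dir=tmp_path / run_dir)
            run_workflow(cfg)
            outputs.append({p.name: p.read_bytes()
                            for p in sorted((tmp_path / run_dir).iterdir())
                            if p.suffix == ".csv"})
        assert outputs[0] == outputs[1]
        assert "common.csv" in outputs[0]

    def test_identity_composition_without_negatives_overlap(self,
                                                            experiment,
                                                            tmp_path):
        """One positive, an empty negative file, permissive filters:
        the specific set equals the parsed input."""
        config, truth = experiment
        empty_neg = tmp_path / "empty.tab"
        empty_neg.write_text("# empty control\nchr\tstart\tend\tlength\t"
                             "summit\ttags\t-10*log10(pvalue)\t"
                             "fold_enrichment\tFDR(%)\n")
        label = config.base_label
        cfg = WorkflowConfig(
            positive_files={label: config.positive_files[label]},
            negative_files=[empty_neg],
            target_locus=config.target_locus,
            tag_percent=0.0, fold_enrichment_min=0.0)
        report = run_workflow(cfg)
        parsed = parse_macs_tab(cfg.positive_files[label])
        assert report.per_grna_specific[label].surviving.records \
            == parsed.records


class TestOrderIndependence:
    def test_disjoint_negatives_trivially_true(self, experiment):
        config, _ = experiment
        assert order_independence_check(config) is True

    def test_needs_two_positives(self, experiment):
        config, _ = experiment
        label = config.base_label
        solo = WorkflowConfig(
            positive_files={label: config.positive_files[label]},
            negative_files=config.negative_files,
            target_locus=config.target_locus)
        with pytest.raises(UsageError):
            order_independence_check(solo)

    @pytest.mark.parametrize("seed", range(12))
    def test_generator_scenarios_commute(self, seed):
        """Subtract-then-intersect equals intersect-then-subtract on
        planted scenarios, including ones where negatives overlap
        common-category loci in every file (union-based elimination)."""
        params = SyntheticParams(n_grnas=2 + seed % 2)
        _, _, truth = generate_synthetic_experiment(params, seed=seed)
        sets = {lb: peak_set_for(truth, lb)
                for lb in truth.positive_labels}
        negs = [peak_set_for(truth, lb) for lb in truth.negative_labels]
        config = WorkflowConfig(
            positive_files={lb: f"{lb}.tab" for lb in sets},
            negative_files=["neg.tab"],
            target_locus=truth.target_locus)
        assert order_independence_check(config, peak_sets=sets,
                                        negative_sets=negs) is True


class TestConfig:
    def test_yaml_round_trip(self, experiment, tmp_path):
        config, truth = experiment
        yaml_path = tmp_path / "wf.yaml"
        yaml_path.write_text(
            "positive_files:\n"
            + "".join(f"  {lb}: {p}\n"
                      for lb, p in config.positive_files.items())
            + "negative_files:\n"
            + "".join(f"  - {p}\n" for p in config.negative_files)
            + "target_locus:\n"
            + f"  chrom: {truth.target_locus.chrom}\n"
            + f"  start: {truth.target_locus.start}\n"
            + f"  end: {truth.target_locus.end}\n"
            + "tag_percent: 5\nfold_enrichment_min: 10\n",
            encoding="utf-8")
        loaded = WorkflowConfig.from_yaml(yaml_path)
        assert loaded.base_label == config.base_label
        assert loaded.target_locus == config.target_locus
        assert run_workflow(loaded).common.count \
            == run_workflow(config).common.count

    def test_invalid_base_label_rejected(self, experiment):
        config, _ = experiment
        with pytest.raises(UsageError):
            WorkflowConfig(positive_files=config.positive_files,
                           negative_files=config.negative_files,
                           target_locus=config.target_locus,
                           base_label="nonexistent")

    def test_overlap_rule_validation(self):
        with pytest.raises(ValueError):
            OverlapRule(0)
        with pytest.raises(UsageError):
            WorkflowConfig(positive_files={},
                           negative_files=["n.tab"],
                           target_locus=TargetLocusSpec("chr1", 1, 10))
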
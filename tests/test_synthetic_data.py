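import filecmp

import numpy as np
import pytest

from hprep import normalization as norm
from hprep.io_formats import read_bin_pairs, read_peaks_to_anchors
from hprep.pipeline import normalize_study, study_matrices
from hprep.reproducibility import genome_score
from hprep.synthetic_data import (
    SimConfig,
    simulate_condition_anchors,
    simulate_study,
    simulate_unclassified_pairs,
    simulate_ztp_pairs,
    write_study,
)


class TestConditionAnchors:
    def test_jaccard_one_gives_identical_sets(self):
        cfg = SimConfig(anchor_jaccard=1.0, seed=1)
        sets = simulate_condition_anchors(cfg)
        a, b = sets["A"], sets["B"]
        for chrom in cfg.chromosomes:
            assert np.array_equal(a.chrom_anchors(chrom), b.chrom_anchors(chrom))

    @pytest.mark.parametrize("target", [0.54, 0.32])
    def test_realized_jaccard_near_target(self, target):
        cfg = SimConfig(anchor_jaccard=target, seed=2)
        sets = simulate_condition_anchors(cfg)
        realized = sets["A"].jaccard(sets["B"])
        assert abs(realized - target) <= 0.05

    def test_infeasible_target_rejected(self):
        cfg = SimConfig(
            n_bins=100, anchor_density=0.4, anchor_jaccard=0.05, n_conditions=3, seed=0
        )
        with pytest.raises(ValueError, match="bins|Jaccard"):
            simulate_condition_anchors(cfg)


class TestStudyGeneration:
    def test_outputs_pass_io_validation(self, tiny_study, tmp_path):
        write_study(tiny_study, tmp_path)
        cfg = tiny_study.config
        for sid in tiny_study.samples:
            for chrom in cfg.chromosomes:
                for cls in ("and", "xor"):
                    df = read_bin_pairs(
                        tmp_path / sid / f"{chrom}.{cls}.tsv", cls.upper(), cfg.resolution
                    )
                    assert (df["count"] >= 1).all()
        # peaks recover the condition anchor sets exactly
        for cond, aset in tiny_study.condition_anchors.items():
            back = read_peaks_to_anchors(tmp_path / "peaks" / f"{cond}.bed", cfg.resolution)
            for chrom in cfg.chromosomes:
                assert np.array_equal(back.chrom_anchors(chrom), aset.chrom_anchors(chrom))

    def test_every_pair_class_is_exercised(self, tiny_study):
        cfg = tiny_study.config
        sample = next(iter(tiny_study.samples.values()))
        assert any(len(bc["AND"]) > 0 for bc in sample.tables.values())
        assert any(len(bc["XOR"]) > 0 for bc in sample.tables.values())
        raw = simulate_unclassified_pairs(cfg, cfg.chromosomes[0], 300, seed=5)
        parts = norm.classify_pairs(raw, tiny_study.union_anchors)
        assert all(len(parts[cls]) > 0 for cls in ("AND", "XOR", "NOT"))

    def test_some_peaks_span_bin_boundaries(self, tiny_study, tmp_path):
        write_study(tiny_study, tmp_path)
        cfg = tiny_study.config
        spans = []
        for cond in tiny_study.condition_anchors:
            for line in (tmp_path / "peaks" / f"{cond}.bed").read_text().splitlines():
                _, s, e = line.split("\t")
                spans.append(int(e) - int(s) > cfg.resolution)
        assert any(spans)

    def test_private_anchors_exist_between_conditions(self, tiny_study):
        a = tiny_study.condition_anchors["A"]
        b = tiny_study.condition_anchors["B"]
        chrom = tiny_study.config.chromosomes[0]
        only_a = np.setdiff1d(a.chrom_anchors(chrom), b.chrom_anchors(chrom))
        assert only_a.size > 0

    def test_byte_identical_under_fixed_seed(self, tmp_path):
        cfg = SimConfig(seed=9, n_chroms=1, n_bins=600, depth=3e4)
        d1, d2 = tmp_path / "run1", tmp_path / "run2"
        write_study(simulate_study(cfg), d1)
        write_study(simulate_study(cfg), d2)
        for rel in sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file()):
            assert filecmp.cmp(d1 / rel, d2 / rel, shallow=False), rel


class TestPipelineBehaviour:
    def test_near_noiseless_replicates_score_near_one(self):
        """With vanishing replicate noise and deep sequencing, the score
        between replicates approaches its upper limit."""
        cfg = SimConfig(seed=4, n_chroms=1, n_bins=1000, noise_sd=0.0, depth=5e5)
        study = simulate_study(cfg)
        tables = {sid: study.samples[sid].tables for sid in ("A1", "A2")}
        _, normalized = normalize_study(tables)
        mats = study_matrices(normalized, study.union_anchors, study.study_config())
        score = genome_score(mats["A1"], mats["A2"], d=5).mean
        assert score > 0.98

    def test_cross_condition_scores_below_replicates(self, tiny_pipeline):
        mats = tiny_pipeline["matrices"]
        rep = genome_score(mats["A1"], mats["A2"], d=3).mean
        cross = genome_score(mats["A1"], mats["B1"], d=3).mean
        assert cross < rep

    def test_ztp_generator_recovers_coefficients(self):
        beta = (1.0, 0.3, -0.2, 0.1, 0.5)
        df = simulate_ztp_pairs(beta, 100_000, seed=12)
        fit = norm.fit_ztp(df)
        assert np.all(np.abs(fit.beta - np.array(beta)) < 3 * fit.standard_errors)
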
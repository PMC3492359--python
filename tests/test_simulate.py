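import dataclasses
import json

import numpy as np
import pytest

from isncrna.annotation import IS_NCRNA_CLASSES
from isncrna.coverage import build_coverage
from isncrna.qpcr import ddct
from isncrna.simulate import (
    SimulationConfig,
    condition_multiplier,
    simulate_ct,
    simulate_genome,
    simulate_microarray,
    simulate_reads,
    simulate_screen_matrix,
)


def _snapshot(genome, truth):
    recs = [
        (r.locus_id, r.category, r.ncrna_class, r.interval.chrom, r.interval.start, r.interval.end, r.interval.strand)
        for r in genome.records
    ]
    novel = {k: dataclasses.asdict(v) for k, v in truth.novel.items()}
    known = {k: dataclasses.asdict(v) for k, v in truth.known.items()}
    return json.dumps([recs, novel, known], default=str, sort_keys=True)


class TestGenome:
    def test_same_seed_is_byte_identical(self, small_sim_config):
        a = simulate_genome(small_sim_config, np.random.default_rng(7))
        b = simulate_genome(small_sim_config, np.random.default_rng(7))
        assert _snapshot(*a) == _snapshot(*b)

    def test_bounds_unique_ids_and_class_counts(self, small_sim_config):
        genome, truth = simulate_genome(small_sim_config, np.random.default_rng(1))
        ids = [r.locus_id for r in genome.records]
        assert len(ids) == len(set(ids))
        for rec in genome.records:
            assert rec.interval.end <= genome.chrom_lengths[rec.interval.chrom]
        by_class = {}
        for rec in genome.ncrna_records():
            by_class[rec.ncrna_class] = by_class.get(rec.ncrna_class, 0) + 1
        assert by_class == small_sim_config.ncrna_class_counts
        assert len(truth.novel) == small_sim_config.n_novel_loci

    def test_novel_loci_avoid_annotated_ncrna(self, small_sim_config):
        genome, truth = simulate_genome(small_sim_config, np.random.default_rng(2))
        for t in truth.novel.values():
            for rec in genome.ncrna_records():
                assert t.interval.overlap_length(rec.interval) == 0

    def test_placement_mix_present(self, small_sim_config):
        genome, truth = simulate_genome(small_sim_config, np.random.default_rng(3))
        kinds = {t.placement for t in truth.novel.values()}
        assert "intergenic" in kinds and "intronic" in kinds

    def test_zero_novel_loci(self, small_sim_config):
        cfg = dataclasses.replace(small_sim_config, n_novel_loci=0)
        _genome, truth = simulate_genome(cfg, np.random.default_rng(1))
        assert truth.novel == {}

    def test_genome_too_small_rejected(self, small_sim_config):
        cfg = dataclasses.replace(small_sim_config, chrom_lengths={"chrI": 20_000})
        with pytest.raises(ValueError, match="too small"):
            simulate_genome(cfg, np.random.default_rng(1))


class TestReads:
    def test_planted_coverage_matches_poisson_expectation(self, small_sim_config):
        rng = np.random.default_rng(11)
        genome, truth = simulate_genome(small_sim_config, rng)
        reads = simulate_reads(genome, truth, small_sim_config, "N2", rng)
        track = build_coverage(reads, genome, sample_id="N2")
        for lid, t in truth.novel.items():
            iv = t.interval
            mean_cov = track.array(iv.chrom, iv.strand)[iv.start : iv.end].mean()
            lam = t.base_coverage * iv.length / small_sim_config.read_length
            sd = np.sqrt(lam) * small_sim_config.read_length / iv.length
            # multi-mapped decoys remove some weight; allow one-sided slack
            assert mean_cov > t.base_coverage * 0.8 - 4 * sd
            assert mean_cov < t.base_coverage + 4 * sd + 2.0

    def test_uv_condition_doubles_responsive_loci(self, small_sim_config):
        rng = np.random.default_rng(12)
        genome, truth = simulate_genome(small_sim_config, rng)
        n2 = build_coverage(simulate_reads(genome, truth, small_sim_config, "N2", rng), genome)
        uv = build_coverage(simulate_reads(genome, truth, small_sim_config, "N2_UV", rng), genome)
        ratios = []
        for t in truth.novel.values():
            if not t.responsive:
                continue
            iv = t.interval
            a = n2.array(iv.chrom, iv.strand)[iv.start : iv.end].mean()
            b = uv.array(iv.chrom, iv.strand)[iv.start : iv.end].mean()
            ratios.append((b / a) / t.uv_fold)
        assert np.median(ratios) == pytest.approx(1.0, abs=0.25)

    def test_no_expression_leaves_only_background(self, small_sim_config):
        rng = np.random.default_rng(13)
        genome, truth = simulate_genome(small_sim_config, rng)
        for t in truth.known.values():
            t.expressed = False
        cfg = dataclasses.replace(
            small_sim_config, n_novel_loci=0, exon_coverage=0.0, n_background_reads=50
        )
        truth.novel = {}
        reads = simulate_reads(genome, truth, cfg, "N2", rng)
        assert len(reads) == 50

    def test_multi_mapped_reads_share_hit_count(self, small_sim_config):
        rng = np.random.default_rng(14)
        genome, truth = simulate_genome(small_sim_config, rng)
        reads = simulate_reads(genome, truth, small_sim_config, "N2", rng)
        multi = [r for r in reads if r.n_hits > 1]
        assert multi, "expected some multi-mapped placements"
        # placements appear in groups matching their declared hit count
        from collections import Counter

        counts = Counter(r.n_hits for r in multi)
        for h, n in counts.items():
            assert n % h == 0


class TestArraysAndCt:
    def test_microarray_noise_free_recovers_folds(self, small_sim_config):
        rng = np.random.default_rng(21)
        genome, truth = simulate_genome(small_sim_config, rng)
        cfg = dataclasses.replace(
            small_sim_config, array_noise_sigma_log2=0.0, distorted_array=None
        )
        probes = [(lid, t.interval) for lid, t in sorted(truth.novel.items())]
        matrix, _seq = simulate_microarray(probes, truth, cfg, rng)
        for lid, t in truth.novel.items():
            ratio = matrix.data.loc[lid, "N2_UV"] / matrix.data.loc[lid, "N2"]
            assert ratio == pytest.approx(t.uv_fold if t.responsive else 1.0, rel=1e-9)
        assert set(truth.probe_responders) == {
            lid for lid, t in truth.novel.items() if t.responsive
        }

    def test_screen_matrix_shapes_and_determinism(self):
        a = simulate_screen_matrix(np.random.default_rng(5), n_probes=40, n_responders=4)
        b = simulate_screen_matrix(np.random.default_rng(5), n_probes=40, n_responders=4)
        assert a[0].data.equals(b[0].data)
        assert a[2] == b[2]
        assert a[0].data.shape == (40, 4)

    def test_noise_free_ct_recovers_folds_exactly(self, small_sim_config):
        rng = np.random.default_rng(22)
        genome, truth = simulate_genome(small_sim_config, rng)
        cfg = dataclasses.replace(small_sim_config, ct_noise_sigma=0.0)
        ct = simulate_ct(truth, cfg, rng)
        results = ddct(ct, "N2")
        for r in results:
            assert r.rq == pytest.approx(truth.ct_folds[r.target_id][r.condition], rel=1e-9)

    def test_condition_multiplier(self):
        assert condition_multiplier("N2_UV", 3.0, True) == 3.0
        assert condition_multiplier("N2", 3.0, True) == 1.0
        assert condition_multiplier("N2_UV", 3.0, False) == 1.0
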
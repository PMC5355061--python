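"""Generator correctness: determinism, planted structure, config validation."""

import hashlib
import json

import numpy as np
import pytest

from oncofusion.synthetic import (
    ConfigError, SimulationConfig, plant_motifs, simulate_all,
    simulate_expression, simulate_genome, simulate_peaksets, simulate_tags,
    union_regions, write_fasta,
)
from oncofusion.motifs import consensus_pwm, scan_peak
from oncofusion.tag_density import count_tags
from oncofusion.intervals import GenomicInterval


def tiny_config(**kw):
    defaults = dict(
        seed=1, n_chromosomes=2, chrom_length=300_000, n_genes=50,
        n_peaks_per_factor=100, peak_width=200, tags_per_library=20_000,
        peak_enrichment=20.0, n_samples_per_group=3,
        n_signature_per_subtype=5, n_common_targets=10,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_triple_above_pairwise_rejected(self):
        with pytest.raises(ConfigError, match="triple"):
            tiny_config(overlap_abc=0.3, overlap_ac=0.05)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            tiny_config(motif_planted_fraction=1.5)

    def test_short_chromosome_rejected(self):
        with pytest.raises(ConfigError, match="10 x peak_width"):
            tiny_config(chrom_length=1_000, peak_width=200)

    def test_single_sample_group_rejected(self):
        with pytest.raises(ConfigError):
            tiny_config(n_samples_per_group=1)


class TestSimulateGenome:
    def test_deterministic_under_fixed_seed(self, tmp_path):
        cfg = tiny_config()
        sums = []
        for run in range(2):
            genome, catalog, _ = simulate_genome(cfg)
            p = tmp_path / f"g{run}.fa"
            write_fasta(genome, p)
            sums.append(hashlib.sha256(p.read_bytes()).hexdigest())
        assert sums[0] == sums[1]

    def test_gene_records_non_overlapping_both_strands(self):
        genome, catalog, gt = simulate_genome(tiny_config())
        assert len(catalog) == 50
        by_chrom = {}
        for g in catalog:
            by_chrom.setdefault(g.chrom, []).append(g)
        for genes in by_chrom.values():
            genes.sort(key=lambda g: g.tx_start)
            for a, b in zip(genes, genes[1:]):
                assert a.tx_end <= b.tx_start
        assert {g.strand for g in catalog} == {"+", "-"}
        assert set(gt.tss) == {g.gene_id for g in catalog}

    def test_zero_genes_gives_empty_catalog_valid_fasta(self, tmp_path):
        genome, catalog, _ = simulate_genome(tiny_config(n_genes=0))
        assert len(catalog) == 0
        write_fasta(genome, tmp_path / "g.fa")
        from pyfaidx import Fasta
        f = Fasta(str(tmp_path / "g.fa"))
        assert len(f["chr1"]) == 300_000

    def test_infeasible_placement_fails_naming_constraint(self):
        with pytest.raises(ConfigError, match="non-overlapping genes"):
            simulate_genome(tiny_config(n_genes=500))


class TestSimulatePeaksets:
    def test_planted_category_counts_partition_peaks(self):
        cfg = tiny_config()
        sets, gt = simulate_peaksets(cfg)
        n = cfg.n_peaks_per_factor
        c = gt.venn_counts
        assert c["A"] + c["AB"] + c["AC"] + c["ABC"] == n
        assert c["B"] + c["AB"] + c["BC"] + c["ABC"] == n
        assert c["C"] + c["AC"] + c["BC"] + c["ABC"] == n
        assert all(len(ps) == n for ps in sets.values())

    def test_all_overlaps_zero_gives_disjoint_sets(self):
        cfg = tiny_config(overlap_ab=0, overlap_ac=0, overlap_bc=0,
                          overlap_abc=0)
        sets, gt = simulate_peaksets(cfg)
        from oncofusion.intervals import pairwise_sharing
        a, b, c = sets.values()
        assert pairwise_sharing(a, b).n_a_shared == 0
        assert pairwise_sharing(a, c).n_a_shared == 0
        assert pairwise_sharing(b, c).n_a_shared == 0

    def test_all_overlaps_one_gives_identical_coordinates(self):
        cfg = tiny_config(overlap_ab=1, overlap_ac=1, overlap_bc=1,
                          overlap_abc=1)
        sets, _ = simulate_peaksets(cfg)
        coords = [
            [(i.chrom, i.start, i.end) for i in ps] for ps in sets.values()
        ]
        assert coords[0] == coords[1] == coords[2]

    def test_unique_peaks_separated_by_more_than_width(self):
        cfg = tiny_config()
        _, gt = simulate_peaksets(cfg)
        regions = sorted(
            (r["chrom"], r["start"], r["end"]) for r in gt.venn_labels
        )
        for a, b in zip(regions, regions[1:]):
            if a[0] == b[0]:
                assert b[1] - a[2] > cfg.peak_width


class TestSimulateTags:
    def test_library_total_exact(self):
        cfg = tiny_config()
        _, gt = simulate_peaksets(cfg)
        lib, planted = simulate_tags(cfg, union_regions(gt))
        assert lib.total == cfg.tags_per_library
        assert len(planted) == len(gt.venn_labels)

    def test_zero_enrichment_flat_at_peaks(self):
        cfg = tiny_config()
        _, gt = simulate_peaksets(cfg)
        lib, planted = simulate_tags(cfg, union_regions(gt), enrichment=0.0)
        assert all(k == 0 for k in planted)
        # peak-region density comparable to genome-average density
        peak_tags = sum(count_tags(iv, lib) for iv in union_regions(gt))
        peak_bp = sum(iv.length for iv in union_regions(gt))
        genome_bp = cfg.n_chromosomes * cfg.chrom_length
        expected = cfg.tags_per_library * peak_bp / genome_bp
        assert peak_tags < 3 * expected + 30

    def test_enriched_profile_modes_at_midpoint(self):
        cfg = tiny_config(peak_enrichment=100.0, tags_per_library=50_000)
        _, gt = simulate_peaksets(cfg)
        union = union_regions(gt)
        lib, _ = simulate_tags(cfg, union)
        from oncofusion.tag_density import average_profile, density_matrix
        m = density_matrix(union, lib, w=500, n_bins=20)
        prof = average_profile(m)
        assert abs(int(np.argmax(prof["mean"])) - 10) <= 1

    def test_fixed_seed_identical_tag_files(self, tmp_path):
        cfg = tiny_config()
        _, gt = simulate_peaksets(cfg)
        sums = []
        for run in range(2):
            lib, _ = simulate_tags(cfg, union_regions(gt))
            p = tmp_path / f"t{run}.bed"
            lib.write_bed(p)
            sums.append(hashlib.sha256(p.read_bytes()).hexdigest())
        assert sums[0] == sums[1]

    def test_overcommitted_enrichment_fails(self):
        cfg = tiny_config(tags_per_library=100, peak_enrichment=50.0)
        _, gt = simulate_peaksets(cfg)
        with pytest.raises(ConfigError, match="tags_per_library"):
            simulate_tags(cfg, union_regions(gt))


class TestPlantMotifs:
    def test_planted_count_is_rounded_fraction(self):
        cfg = tiny_config(motif_planted_fraction=0.6)
        genome, _, _ = simulate_genome(cfg)
        _, gt = simulate_peaksets(cfg)
        union = union_regions(gt)
        flags, pwm = plant_motifs(cfg, genome, union)
        assert sum(flags) == round(0.6 * len(union))

    def test_fraction_zero_leaves_fasta_unchanged(self, tmp_path):
        cfg = tiny_config(motif_planted_fraction=0.0)
        genome, _, _ = simulate_genome(cfg)
        before = hashlib.sha256(bytes(genome["chr1"])).hexdigest()
        _, gt = simulate_peaksets(cfg)
        flags, _ = plant_motifs(cfg, genome, union_regions(gt))
        assert not any(flags)
        assert hashlib.sha256(bytes(genome["chr1"])).hexdigest() == before

    def test_motif_longer_than_peak_fails(self):
        cfg = tiny_config(peak_width=200, chrom_length=300_000)
        genome, _, _ = simulate_genome(cfg)
        _, gt = simulate_peaksets(cfg)
        long_pwm = consensus_pwm("LONG", "ACGT" * 60)
        with pytest.raises(ConfigError, match="peak_width"):
            plant_motifs(cfg, genome, union_regions(gt), pwm=long_pwm)

    def test_half_planted_on_each_strand(self):
        cfg = tiny_config(motif_planted_fraction=0.5)
        genome, _, _ = simulate_genome(cfg)
        _, gt = simulate_peaksets(cfg)
        union = union_regions(gt)
        flags, pwm = plant_motifs(cfg, genome, union)
        from oncofusion.motifs import reverse_complement
        n_plus = n_minus = 0
        for iv, f in zip(union, flags):
            if not f:
                continue
            seq = bytes(genome[iv.chrom][iv.start:iv.end]).decode()
            if pwm.consensus in seq:
                n_plus += 1
            if reverse_complement(pwm.consensus) in seq:
                n_minus += 1
        planted = sum(flags)
        assert n_minus == planted // 2
        assert n_plus == planted - planted // 2

    def test_scanner_concordance_at_strict_threshold(self):
        cfg = tiny_config(motif_planted_fraction=0.4)
        genome, _, _ = simulate_genome(cfg)
        _, gt = simulate_peaksets(cfg)
        union = union_regions(gt)
        flags, pwm = plant_motifs(cfg, genome, union)
        for iv, planted in zip(union, flags):
            seq = bytes(genome[iv.chrom][iv.start:iv.end]).decode()
            assert bool(scan_peak(seq, pwm, threshold_frac=1.0)) == planted


class TestSimulateExpression:
    def test_point_planting_realizes_fc_in_band(self):
        # planting exactly the configured fold change: realized discovery FC
        # lands in [6, 10] at 20 samples/group
        cfg = tiny_config(n_samples_per_group=20, n_genes=100,
                          signature_fc=8.0, signature_fc_max=8.0,
                          n_signature_per_subtype=5, n_common_targets=10)
        genes = [f"G{i:05d}" for i in range(100)]
        sim = simulate_expression(cfg, genes)
        from oncofusion.signature import _subtype_fc
        from oncofusion.synthetic import AML_SUBTYPES
        fc = _subtype_fc(sim.cohort1, sim.groups1, AML_SUBTYPES)
        for gene, subtype in sim.truth.gene_signature.items():
            assert 6.0 <= fc.loc[gene, subtype] <= 10.0

    def test_null_simulation_yields_no_candidates(self):
        from oncofusion.signature import discovery_filter
        from oncofusion.synthetic import AML_SUBTYPES
        for seed in range(5):
            cfg = tiny_config(seed=seed, n_signature_per_subtype=0,
                              n_common_targets=0, n_samples_per_group=10)
            genes = [f"G{i:05d}" for i in range(50)]
            sim = simulate_expression(cfg, genes)
            cands = discovery_filter(sim.cohort1, sim.groups1, AML_SUBTYPES,
                                     fc_threshold=8.0)
            assert cands == []

    def test_common_targets_shift_aml_groups_only(self):
        cfg = tiny_config()
        genes = [f"G{i:05d}" for i in range(50)]
        sim = simulate_expression(cfg, genes)
        from oncofusion.synthetic import AML_SUBTYPES, NORMAL_GROUPS
        for g in sim.truth.common_targets:
            means = sim.truth.true_group_means[g]
            for aml in AML_SUBTYPES:
                assert means[aml] == pytest.approx(
                    cfg.common_target_shift * means["CD34+"])
            for normal in NORMAL_GROUPS:
                assert means[normal] == pytest.approx(means["CD34+"])

    def test_two_cohorts_share_planted_genes(self):
        cfg = tiny_config()
        genes = [f"G{i:05d}" for i in range(50)]
        s1 = simulate_expression(cfg, genes)
        # cohort matrices differ (independent noise) but planted sets match
        assert not s1.cohort1.values.equals(s1.cohort2.values)
        assert set(s1.cohort1.genes) == set(s1.cohort2.genes)

    def test_too_many_planted_effects_fails(self):
        cfg = tiny_config()
        with pytest.raises(ConfigError, match="planted effects"):
            simulate_expression(cfg, [f"G{i}" for i in range(10)])


class TestSimulateAll:
    def test_byte_identical_outputs_across_runs(self, tmp_path):
        cfg = tiny_config()
        digests = []
        for run in range(2):
            d = tmp_path / f"run{run}"
            paths = simulate_all(cfg, d)
            digests.append({
                name: hashlib.sha256(p.read_bytes()).hexdigest()
                for name, p in sorted(paths.items())
            })
        assert digests[0] == digests[1]

    def test_ground_truth_consistent_with_files(self, simulated_dir):
        gt = json.loads((simulated_dir / "ground_truth.json").read_text())
        n_regions = len(gt["venn_labels"])
        assert sum(gt["venn_counts"].values()) == n_regions
        assert len(gt["motif_planted"]) == n_regions
        assert len(gt["planted_tag_counts"]) == n_regions
        union_bed = (simulated_dir / "peaks_union.bed").read_text()
        assert len(union_bed.strip().splitlines()) == n_regions
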
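"""Generator determinism, spectrum planting, read fidelity, pipeline recovery."""

import hashlib
import math
from collections import Counter

import numpy as np
import pytest

from asepipe.snp_discovery import canonical_class
from asepipe.synthetic_data import (
    SimulationConfig,
    TruthTable,
    assign_transcript_truth,
    generate_dataset,
    generate_genome_and_annotation,
    plant_snps,
    simulate_reads,
)

SMALL = dict(n_transcripts=8, seed=11)


def file_hash(path):
    return hashlib.sha256(open(path, "rb").read()).hexdigest()


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        p1 = generate_dataset(SimulationConfig(**SMALL), tmp_path / "a")
        p2 = generate_dataset(SimulationConfig(**SMALL), tmp_path / "b")
        for key in ("reference", "annotation", "truth_snps", "truth_transcripts"):
            assert file_hash(p1[key]) == file_hash(p2[key])
        for key, paths in p1["sam"].items():
            for f1, f2 in zip(paths, p2["sam"][key]):
                assert file_hash(f1) == file_hash(f2)

    def test_different_seed_differs(self, tmp_path):
        p1 = generate_dataset(SimulationConfig(**SMALL), tmp_path / "a")
        p2 = generate_dataset(SimulationConfig(n_transcripts=8, seed=12), tmp_path / "b")
        assert file_hash(p1["reference"]) != file_hash(p2["reference"])


class TestGenomeAndAnnotation:
    def test_transcript_count_and_exon_structure(self):
        rng = np.random.default_rng(0)
        config = SimulationConfig(
            n_transcripts=10,
            exon_count_range=(2, 2),
            exon_length_range=(200, 200),
        )
        genome, models = generate_genome_and_annotation(config, rng)
        assert len(models) == 10
        assert all(m.summed_exon_length == 400 for m in models)
        assert all(len(m.exons) == 2 for m in models)
        total = sum(len(seq) for seq in genome.values())
        assert total > 10 * 400


class TestPlantSnps:
    def test_degenerate_spectrum_all_transitions(self):
        rng = np.random.default_rng(0)
        weights = {c: 0.0 for c in ("A:C", "A:G", "A:T", "C:A", "C:G")}
        weights["C:T"] = 1.0
        config = SimulationConfig(n_transcripts=10, snp_rate=10.0, spectrum_weights=weights)
        genome, models = generate_genome_and_annotation(config, rng)
        snps = plant_snps(models, genome, config, rng)
        assert snps
        assert all((s.allele_p1, s.allele_p2) in {("C", "T"), ("G", "A")} for s in snps)
        # the planted reference base matches the parent-1 allele
        for s in snps:
            assert genome[s.chrom][s.pos] == s.allele_p1

    def test_zero_rate_plants_nothing(self):
        rng = np.random.default_rng(0)
        config = SimulationConfig(n_transcripts=5, snp_rate=0.0)
        genome, models = generate_genome_and_annotation(config, rng)
        assert plant_snps(models, genome, config, rng) == []

    def test_no_duplicate_positions(self):
        rng = np.random.default_rng(3)
        config = SimulationConfig(n_transcripts=10, snp_rate=30.0)
        genome, models = generate_genome_and_annotation(config, rng)
        snps = plant_snps(models, genome, config, rng)
        positions = [(s.chrom, s.pos) for s in snps]
        assert len(positions) == len(set(positions))

    def test_planted_classes_match_alleles(self):
        rng = np.random.default_rng(4)
        config = SimulationConfig(n_transcripts=10, snp_rate=20.0)
        genome, models = generate_genome_and_annotation(config, rng)
        snps = plant_snps(models, genome, config, rng)
        for s in snps:
            assert canonical_class(s.allele_p1, s.allele_p2) == s.substitution_class


class TestSimulatedReads:
    def _tiny(self, **kwargs):
        config = SimulationConfig(
            n_transcripts=3, snp_rate=8.0, seed=5,
            junk_read_fraction=0.0, low_quality_base_fraction=0.0,
            **kwargs,
        )
        rng = np.random.default_rng(config.seed)
        genome, models = generate_genome_and_annotation(config, rng)
        snps = plant_snps(models, genome, config, rng)
        truth = TruthTable(snps=snps, transcripts=assign_transcript_truth(models, config, rng))
        return config, rng, genome, models, truth

    def test_parent1_reads_match_reference_exactly(self):
        config, rng, genome, models, truth = self._tiny(base_error_rate=0.0)
        for line in simulate_reads(genome, models, truth, config, "parent1", "tillering", 1, rng):
            fields = line.split("\t")
            pos = int(fields[3]) - 1
            seq = fields[9]
            # walk the CIGAR to compare against the reference
            ref_pos, idx = pos, 0
            num = ""
            for ch in fields[5]:
                if ch.isdigit():
                    num += ch
                elif ch == "M":
                    n = int(num)
                    ref = "".join(genome[fields[2]][ref_pos:ref_pos + n])
                    assert seq[idx:idx + n] == ref
                    ref_pos += n
                    idx += n
                    num = ""
                else:  # N
                    ref_pos += int(num)
                    num = ""

    def test_parent2_reads_carry_alt_allele(self):
        config, rng, genome, models, truth = self._tiny(base_error_rate=0.0)
        covered = 0
        snps_by_chrom = {(s.chrom, s.pos): s for s in truth.snps}
        for line in simulate_reads(genome, models, truth, config, "parent2", "tillering", 1, rng):
            fields = line.split("\t")
            pos, seq, cigar = int(fields[3]) - 1, fields[9], fields[5]
            ref_pos, idx, num = pos, 0, ""
            for ch in cigar:
                if ch.isdigit():
                    num += ch
                elif ch == "M":
                    n = int(num)
                    for j in range(n):
                        snp = snps_by_chrom.get((fields[2], ref_pos + j))
                        if snp is not None:
                            covered += 1
                            assert seq[idx + j] == snp.allele_p2
                    ref_pos += n
                    idx += n
                    num = ""
                else:
                    ref_pos += int(num)
                    num = ""
        assert covered > 0

    def test_monoallelic_hybrid_fraction_one(self):
        config, rng, genome, models, truth = self._tiny()
        for t in truth.transcripts.values():
            t.fraction_tillering = 1.0
        snps_at = {(s.chrom, s.pos): s for s in truth.snps}
        for line in simulate_reads(genome, models, truth, config, "hybrid", "tillering", 1, rng):
            fields = line.split("\t")
            pos, seq, cigar = int(fields[3]) - 1, fields[9], fields[5]
            ref_pos, idx, num = pos, 0, ""
            for ch in cigar:
                if ch.isdigit():
                    num += ch
                elif ch == "M":
                    n = int(num)
                    for j in range(n):
                        snp = snps_at.get((fields[2], ref_pos + j))
                        if snp is not None:
                            assert seq[idx + j] == snp.allele_p1
                    ref_pos += n
                    idx += n
                    num = ""
                else:
                    ref_pos += int(num)
                    num = ""


class TestPipelineRecovery:
    def test_snp_recall_and_fraction_estimates(self, pipeline_run, parental_pileups):
        """The pipeline recovers planted SNPs meeting the depth criteria and
        estimates hybrid allelic fractions within binomial sampling error."""
        result = pipeline_run["result"]
        truth = pipeline_run["dataset"]["truth"]
        called = {(s.transcript_id, s.pos) for s in result.snps}

        eligible = []
        for snp in truth.snps:
            key = (snp.transcript_id, snp.pos)
            depths_ok = all(
                key in parental_pileups[sample][stage]
                and parental_pileups[sample][stage][key].depth >= 10
                for sample in ("parent1", "parent2")
                for stage in ("tillering", "heading")
            )
            if depths_ok:
                eligible.append(key)
        assert eligible
        recall = sum(key in called for key in eligible) / len(eligible)
        assert recall >= 0.95
        # no spurious SNPs: every call corresponds to a planted site
        planted = {(s.transcript_id, s.pos) for s in truth.snps}
        assert called <= planted

        # fraction recovery for well-supported transcripts
        checked = 0
        for call in result.bias_calls:
            if call.supporting_reads < 100 or call.p1_fraction is None:
                continue
            true_f = truth.true_fraction(call.transcript_id, call.stage)
            tol = 4 * math.sqrt(true_f * (1 - true_f) / call.supporting_reads) + 0.01
            assert abs(call.p1_fraction - true_f) <= tol, call
            checked += 1
        assert checked >= 5

    def test_truth_categories_cover_config_fractions(self, sim_dataset):
        truth = sim_dataset["truth"]
        cats = Counter(t.category for t in truth.transcripts.values())
        assert cats["biased"] > 0
        assert cats["conserved"] > 0
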
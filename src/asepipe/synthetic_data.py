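"""Synthetic RNA-seq datasets with planted ground truth.

Generates a small reference genome, transcript annotation, and
already-aligned reads (SAM) for two inbred parental lines and their F1
hybrid at two developmental stages, together with truth tables for the
planted SNPs, allelic fractions and regulatory modes.  The generator
emulates the statistical structure the analysis assumes:

- inter-parental SNPs with a complement-collapsed substitution spectrum
  enriched for transitions (C<->T / G<->A, default 68% of planted SNPs);
- per-transcript hybrid allelic fractions — balanced for most
  transcripts, biased for a planted minority, strongly mono-allelic
  (parent-1 fraction < 0.3 or > 0.7) for part of that minority;
- stage-specific bias (one-stage-only and stage-switching transcripts);
- optional sequencing error, low-quality bases and junk reads to
  exercise the quality filters;
- optional planted cis / trans regulatory divergence (parental
  expression ratio mirrored, or not, by the hybrid allelic fraction).

Reads are emitted as aligned SAM records (correct POS and M/N CIGAR over
exons); alignment itself is outside the scope of the pipeline.  All
output is deterministic given the seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

from asepipe.annotation_io import TranscriptModel, merge_intervals
from asepipe.snp_discovery import SPECTRUM_CLASSES

STAGES = ("tillering", "heading")
SAMPLES = ("parent1", "parent2", "hybrid")

#: Directed substitutions contained in each canonical class.
CLASS_MEMBERS = {
    "A:C": (("A", "C"), ("T", "G")),
    "A:G": (("A", "G"), ("T", "C")),
    "A:T": (("A", "T"), ("T", "A")),
    "C:A": (("C", "A"), ("G", "T")),
    "C:G": (("C", "G"), ("G", "C")),
    "C:T": (("C", "T"), ("G", "A")),
}

#: Default substitution-class weights: 68% of SNPs are transitions
#: (split evenly between the C:T and A:G classes), the remaining mass is
#: uniform over the four transversion classes.
DEFAULT_SPECTRUM_WEIGHTS = {
    "A:C": 0.08,
    "A:G": 0.34,
    "A:T": 0.08,
    "C:A": 0.08,
    "C:G": 0.08,
    "C:T": 0.34,
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic dataset.

    Depths are mean per-base fold coverages per library (stage, pooled
    over replicates); ``snp_rate`` is planted SNPs per exonic kilobase.
    ``planted_fractions`` is a discrete distribution of hybrid parent-1
    allelic fractions for biased transcripts, (fraction, weight) pairs,
    including mass outside (0.3, 0.7) for strong mono-allelic cases.
    """

    n_transcripts: int = 40
    exon_count_range: tuple[int, int] = (2, 4)
    exon_length_range: tuple[int, int] = (150, 300)
    intron_length_range: tuple[int, int] = (60, 150)
    intergenic_gap: int = 100
    snp_rate: float = 3.0
    spectrum_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECTRUM_WEIGHTS)
    )
    depth_mean: float = 40.0
    hybrid_depth_mean: float = 60.0
    read_length: int = 100
    base_error_rate: float = 0.0
    low_quality_base_fraction: float = 0.02
    junk_read_fraction: float = 0.01
    n_replicates: int = 2
    frac_biased: float = 0.17
    planted_fractions: tuple[tuple[float, float], ...] = (
        (0.20, 0.10),
        (0.35, 0.20),
        (0.65, 0.30),
        (0.80, 0.40),
    )
    frac_one_stage: float = 0.70  # among biased: biased at only one stage
    frac_stage_switching: float = 0.03  # among biased: fraction flips between stages
    frac_cis: float = 0.0
    frac_trans: float = 0.0
    de_fold: float = 4.0
    #: sigma of the log-normal per-transcript expression level (shared
    #: across samples and replicates: the biological signal that makes
    #: replicate log-RPKM profiles correlate).
    expression_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.spectrum_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("spectrum_weights must sum to 1")
        if set(self.spectrum_weights) != set(SPECTRUM_CLASSES):
            raise ValueError(f"spectrum_weights keys must be {SPECTRUM_CLASSES}")


@dataclass(frozen=True)
class PlantedSnp:
    chrom: str
    pos: int
    transcript_id: str
    allele_p1: str
    allele_p2: str
    substitution_class: str


@dataclass
class TranscriptTruth:
    transcript_id: str
    category: str  # conserved | biased | cis | trans
    fraction_tillering: float
    fraction_heading: float
    p2_expression_scale: float  # parent2 depth multiplier (1.0 = no DE)
    base_expression: float = 1.0  # per-transcript depth multiplier


@dataclass
class TruthTable:
    """Planted ground truth; deterministic given the simulation seed."""

    snps: list[PlantedSnp] = field(default_factory=list)
    transcripts: dict[str, TranscriptTruth] = field(default_factory=dict)

    def snps_of(self, transcript_id: str) -> list[PlantedSnp]:
        return [s for s in self.snps if s.transcript_id == transcript_id]

    def true_fraction(self, transcript_id: str, stage: str) -> float:
        t = self.transcripts[transcript_id]
        return t.fraction_tillering if stage == "tillering" else t.fraction_heading


def generate_genome_and_annotation(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], list[TranscriptModel]]:
    """Random genome (one chromosome) with non-overlapping transcripts."""
    bases = np.array(list("ACGT"))
    models = []
    cursor = config.intergenic_gap
    exon_records: list[tuple[str, tuple[tuple[int, int], ...], str]] = []
    for i in range(config.n_transcripts):
        tid = f"TX{i + 1:04d}"
        n_exons = int(rng.integers(config.exon_count_range[0], config.exon_count_range[1] + 1))
        exons = []
        for j in range(n_exons):
            length = int(
                rng.integers(config.exon_length_range[0], config.exon_length_range[1] + 1)
            )
            exons.append((cursor, cursor + length))
            cursor += length
            if j < n_exons - 1:
                cursor += int(
                    rng.integers(config.intron_length_range[0], config.intron_length_range[1] + 1)
                )
        cursor += config.intergenic_gap
        strand = "+" if rng.random() < 0.5 else "-"
        exon_records.append((tid, merge_intervals(exons), strand))
    genome_len = cursor + config.intergenic_gap
    seq = rng.choice(bases, size=genome_len)
    genome = {"chr1": seq}
    for tid, exons, strand in exon_records:
        models.append(TranscriptModel(tid, "chr1", strand, exons))
    return genome, models


def plant_snps(
    transcripts: Sequence[TranscriptModel],
    genome: dict[str, np.ndarray],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[PlantedSnp]:
    """Plant inter-parental SNPs along exons per the substitution spectrum.

    Parent 1 carries the reference base (the reference is rewritten so
    that it matches the drawn substitution's origin base); parent 2
    carries the substituted base.  SNP counts per transcript are
    Poisson(snp_rate x exonic kb); no two SNPs share a position.
    """
    classes = list(SPECTRUM_CLASSES)
    weights = np.array([config.spectrum_weights[c] for c in classes])
    snps: list[PlantedSnp] = []
    for tx in transcripts:
        n = int(rng.poisson(config.snp_rate * tx.summed_exon_length / 1000.0))
        if n == 0:
            continue
        positions = np.array(list(tx.positions()))
        n = min(n, len(positions))
        chosen = rng.choice(positions, size=n, replace=False)
        for pos in sorted(int(p) for p in chosen):
            cls = classes[int(rng.choice(len(classes), p=weights))]
            a1, a2 = CLASS_MEMBERS[cls][int(rng.integers(2))]
            genome[tx.chrom][pos] = a1
            snps.append(PlantedSnp(tx.chrom, pos, tx.transcript_id, a1, a2, cls))
    return snps


def assign_transcript_truth(
    transcripts: Sequence[TranscriptModel],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, TranscriptTruth]:
    """Assign each transcript a category, allelic fractions and DE scale."""
    fracs = np.array([f for f, _ in config.planted_fractions])
    fweights = np.array([w for _, w in config.planted_fractions])
    fweights = fweights / fweights.sum()
    truth = {}
    for tx in transcripts:
        u = rng.random()
        if u < config.frac_cis:
            category = "cis"
        elif u < config.frac_cis + config.frac_trans:
            category = "trans"
        elif u < config.frac_cis + config.frac_trans + config.frac_biased:
            category = "biased"
        else:
            category = "conserved"
        p2_scale = 1.0
        f_till = f_head = 0.5
        if category == "cis":
            p2_scale = 1.0 / config.de_fold
            f_till = f_head = config.de_fold / (1.0 + config.de_fold)
        elif category == "trans":
            p2_scale = 1.0 / config.de_fold
            f_till = f_head = 0.5
        elif category == "biased":
            f = float(fracs[int(rng.choice(len(fracs), p=fweights))])
            v = rng.random()
            if v < config.frac_stage_switching:
                f_till, f_head = f, 1.0 - f
            elif v < config.frac_stage_switching + config.frac_one_stage:
                if rng.random() < 0.5:
                    f_till, f_head = f, 0.5
                else:
                    f_till, f_head = 0.5, f
            else:
                f_till = f_head = f
        truth[tx.transcript_id] = TranscriptTruth(
            transcript_id=tx.transcript_id,
            category=category,
            fraction_tillering=f_till,
            fraction_heading=f_head,
            p2_expression_scale=p2_scale,
            base_expression=float(rng.lognormal(0.0, config.expression_sigma)),
        )
    return truth


def _transcript_layout(tx: TranscriptModel) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Map transcript coordinates to genomic positions and exon segments."""
    positions = np.fromiter(tx.positions(), dtype=np.int64)
    segments = [(start, end - start) for start, end in tx.exons]
    return positions, segments


def _cigar_for(tx: TranscriptModel, t_start: int, length: int) -> tuple[int, str]:
    """Genomic start and M/N CIGAR for a read spanning transcript coords."""
    parts = []
    g_start = None
    offset = 0
    remaining = length
    prev_end = None
    for start, end in tx.exons:
        seg_len = end - start
        if t_start >= offset + seg_len:
            offset += seg_len
            continue
        local = max(t_start - offset, 0)
        take = min(seg_len - local, remaining)
        g = start + local
        if g_start is None:
            g_start = g
        elif prev_end is not None and g > prev_end:
            parts.append(f"{g - prev_end}N")
        parts.append(f"{take}M")
        prev_end = g + take
        remaining -= take
        offset += seg_len
        if remaining == 0:
            break
    return g_start, "".join(parts)


def simulate_reads(
    genome: dict[str, np.ndarray],
    transcripts: Sequence[TranscriptModel],
    truth: TruthTable,
    config: SimulationConfig,
    sample: str,
    stage: str,
    replicate: int,
    rng: np.random.Generator,
) -> Iterable[str]:
    """Yield aligned SAM record lines for one sample x stage x replicate.

    Parental reads carry their parent's allele at every planted SNP;
    each hybrid read draws its parent of origin from the transcript's
    true stage-specific parent-1 fraction, so all SNPs on one read share
    an origin (reads are single molecules).
    """
    base_arr = np.array(list("ACGT"))
    base_index = {b: i for i, b in enumerate("ACGT")}
    snps_by_tid: dict[str, list[PlantedSnp]] = {}
    for snp in truth.snps:
        snps_by_tid.setdefault(snp.transcript_id, []).append(snp)

    for tx in transcripts:
        tx_truth = truth.transcripts[tx.transcript_id]
        positions, _ = _transcript_layout(tx)
        length = len(positions)
        read_len = min(config.read_length, length)
        ref_seq = genome[tx.chrom][positions]
        # haplotypes in transcript coordinates
        hap1 = ref_seq.copy()
        hap2 = ref_seq.copy()
        pos_to_t = {int(g): t for t, g in enumerate(positions)}
        for snp in snps_by_tid.get(tx.transcript_id, ()):
            t = pos_to_t[snp.pos]
            hap1[t] = snp.allele_p1
            hap2[t] = snp.allele_p2

        if sample == "parent1":
            depth = config.depth_mean * tx_truth.base_expression
        elif sample == "parent2":
            depth = config.depth_mean * tx_truth.p2_expression_scale * tx_truth.base_expression
        else:
            depth = config.hybrid_depth_mean * tx_truth.base_expression
        mean_reads = depth * length / read_len / config.n_replicates
        n_reads = int(rng.poisson(mean_reads))
        n_junk = int(rng.binomial(n_reads, config.junk_read_fraction)) if n_reads else 0
        frac_p1 = truth.true_fraction(tx.transcript_id, stage)

        for r in range(n_reads + n_junk):
            junk = r >= n_reads
            t0 = int(rng.integers(0, length - read_len + 1))
            if sample == "parent1":
                hap = hap1
            elif sample == "parent2":
                hap = hap2
            else:
                hap = hap1 if rng.random() < frac_p1 else hap2
            seq = hap[t0 : t0 + read_len].copy()
            if config.base_error_rate > 0:
                n_err = rng.binomial(read_len, config.base_error_rate)
                for epos in rng.integers(0, read_len, size=n_err):
                    orig = base_index[seq[epos]]
                    seq[epos] = base_arr[(orig + 1 + int(rng.integers(3))) % 4]
            quals = np.full(read_len, 38, dtype=np.int64)
            if junk:
                n_low = int(0.4 * read_len) + 1
            else:
                n_low = rng.binomial(read_len, config.low_quality_base_fraction)
            if n_low:
                low_pos = rng.choice(read_len, size=min(n_low, read_len), replace=False)
                quals[low_pos] = 11
            g_start, cigar = _cigar_for(tx, t0, read_len)
            qual_str = "".join(chr(q + 33) for q in quals)
            name = f"{sample}.{stage}.r{replicate}.{tx.transcript_id}.{r}"
            yield (
                f"{name}\t0\t{tx.chrom}\t{g_start + 1}\t60\t{cigar}\t*\t0\t0\t"
                f"{''.join(seq)}\t{qual_str}"
            )


def sam_header(genome: dict[str, np.ndarray]) -> str:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for chrom, seq in genome.items():
        lines.append(f"@SQ\tSN:{chrom}\tLN:{len(seq)}")
    return "\n".join(lines) + "\n"


def write_fasta(genome: dict[str, np.ndarray], path: str | os.PathLike) -> None:
    with open(path, "w") as out:
        for chrom, seq in genome.items():
            out.write(f">{chrom}\n")
            s = "".join(seq)
            for i in range(0, len(s), 70):
                out.write(s[i : i + 70] + "\n")


def write_gff3(transcripts: Sequence[TranscriptModel], path: str | os.PathLike) -> None:
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for tx in transcripts:
            start = tx.exons[0][0] + 1
            end = tx.exons[-1][1]
            out.write(
                f"{tx.chrom}\tasepipe\tmRNA\t{start}\t{end}\t.\t{tx.strand}\t.\t"
                f"ID={tx.transcript_id}\n"
            )
            for i, (s, e) in enumerate(tx.exons, 1):
                out.write(
                    f"{tx.chrom}\tasepipe\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t"
                    f"ID={tx.transcript_id}.exon{i};Parent={tx.transcript_id}\n"
                )


def generate_dataset(config: SimulationConfig, outdir: str | os.PathLike) -> dict:
    """Generate the full dataset: FASTA, GFF3, SAMs and truth tables.

    Returns a dict with paths ('annotation', 'reference', 'sam' mapping
    (sample, stage) -> list of replicate SAM paths, 'truth_snps',
    'truth_transcripts') plus the in-memory truth table and models.
    """
    import pandas as pd

    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    genome, transcripts = generate_genome_and_annotation(config, rng)
    snps = plant_snps(transcripts, genome, config, rng)
    tx_truth = assign_transcript_truth(transcripts, config, rng)
    truth = TruthTable(snps=snps, transcripts=tx_truth)

    ref_path = os.path.join(outdir, "reference.fa")
    write_fasta(genome, ref_path)
    gff_path = os.path.join(outdir, "annotation.gff3")
    write_gff3(transcripts, gff_path)

    header = sam_header(genome)
    sam_paths: dict[tuple[str, str], list[str]] = {}
    for sample in SAMPLES:
        for stage in STAGES:
            paths = []
            for rep in range(1, config.n_replicates + 1):
                path = os.path.join(outdir, f"{sample}.{stage}.rep{rep}.sam")
                with open(path, "w") as out:
                    out.write(header)
                    for line in simulate_reads(
                        genome, transcripts, truth, config, sample, stage, rep, rng
                    ):
                        out.write(line + "\n")
                paths.append(path)
            sam_paths[(sample, stage)] = paths

    snp_df = pd.DataFrame([asdict(s) for s in snps])
    snp_path = os.path.join(outdir, "truth_snps.tsv")
    snp_df.to_csv(snp_path, sep="\t", index=False)
    tx_df = pd.DataFrame([asdict(t) for t in tx_truth.values()])
    tx_path = os.path.join(outdir, "truth_transcripts.tsv")
    tx_df.to_csv(tx_path, sep="\t", index=False)

    return {
        "reference": ref_path,
        "annotation": gff_path,
        "sam": sam_paths,
        "truth_snps": snp_path,
        "truth_transcripts": tx_path,
        "truth": truth,
        "transcripts": transcripts,
        "genome": genome,
    }


# ---------------------------------------------------------------------------
# Counts-level draws for statistical calibration studies


def simulate_allele_counts(
    n_snps: int, fraction: float, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """Parent-1 allele counts at ``n_snps`` SNPs of fixed informative depth."""
    return rng.binomial(depth, fraction, size=n_snps)


def simulate_regulation_counts(
    n_cis: int,
    n_trans: int,
    rng: np.random.Generator,
    *,
    parent_base_mean: float = 800.0,
    expression_ratio: float = 4.0,
    hybrid_depth: int = 600,
    library_size: int = 1_000_000,
) -> list[dict]:
    """Counts-level cis/trans cohort.

    cis transcripts: parent-1 expression ``expression_ratio`` times
    parent 2, hybrid parent-1 allele fraction equal to the parental
    expression share r/(1+r).  trans transcripts: same parental
    difference, hybrid balanced at 0.5.
    """
    cohort = []
    for i in range(n_cis + n_trans):
        mode = "cis" if i < n_cis else "trans"
        c1 = int(rng.poisson(parent_base_mean * expression_ratio))
        c2 = int(rng.poisson(parent_base_mean))
        frac = (
            expression_ratio / (1.0 + expression_ratio) if mode == "cis" else 0.5
        )
        k = int(rng.binomial(hybrid_depth, frac))
        cohort.append(
            {
                "transcript_id": f"SIM{i + 1:04d}",
                "true_mode": mode,
                "count_p1": c1,
                "count_p2": c2,
                "n_p1": k,
                "n_p2": hybrid_depth - k,
                "total_p1": library_size,
                "total_p2": library_size,
            }
        )
    return cohort
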
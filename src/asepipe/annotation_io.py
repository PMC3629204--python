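"""Annotation and alignment I/O: transcript models, pileups, VCF output.

Internal coordinates are 0-based half-open everywhere; serialized output
(VCF) is 1-based per convention.  Pileups are restricted to annotated
exons, built from primary mapped alignments only, and count only bases
with phred quality >= 20 (lower-quality and N bases are tallied
separately and never used for calling).
"""

from __future__ import annotations

import logging
import os
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pysam

logger = logging.getLogger(__name__)

STAGES = ("tillering", "heading")
BASES = ("A", "C", "G", "T")

#: Minimum base quality for a base to enter a pileup column.
MIN_BASE_QUALITY = 20
#: Reads with more than this fraction of bases below MIN_BASE_QUALITY
#: are discarded outright.
MAX_LOW_QUALITY_FRACTION = 0.30


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure of one annotated transcript.

    ``exons`` are sorted, non-overlapping, 0-based half-open genomic
    intervals; they define the coordinate frame within which SNPs are
    called and reads are counted.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise AnnotationError(
                    f"{self.transcript_id}: empty exon interval ({start}, {end})"
                )
            if prev_end is not None and start < prev_end:
                raise AnnotationError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: no exons")

    @property
    def summed_exon_length(self) -> int:
        return sum(end - start for start, end in self.exons)

    def positions(self) -> Iterable[int]:
        for start, end in self.exons:
            yield from range(start, end)


@dataclass
class PileupColumn:
    """Per-position base counts for one pooled sample after quality filtering."""

    chrom: str
    pos: int
    counts: Counter = field(default_factory=Counter)
    other_count: int = 0

    @property
    def depth(self) -> int:
        """Number of quality bases (A/C/G/T with Q>=20)."""
        return sum(self.counts.values())


@dataclass
class SampleLibrary:
    """One pooled sequencing library (sample x stage)."""

    sample_id: str
    parent_of_origin: str  # parent1 | parent2 | hybrid
    stage: str
    total_mapped_reads: int = 0


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Union of possibly overlapping intervals, sorted."""
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return tuple((s, e) for s, e in merged)


def load_annotation(path: str | os.PathLike) -> list[TranscriptModel]:
    """Read transcript models from a GFF3 or BED12 file.

    Format is chosen by extension (.bed -> BED12, otherwise GFF3).
    Overlapping exon records within one transcript are merged; a
    transcript with zero total exon length is rejected with a warning.
    """
    path = os.fspath(path)
    if path.endswith(".bed") or path.endswith(".bed12"):
        models = _load_bed12(path)
    else:
        models = _load_gff3(path)
    if not models:
        logger.warning("no transcripts parsed from %s", path)
    return models


def _load_bed12(path: str) -> list[TranscriptModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 12 BED fields, got {len(fields)}"
                )
            try:
                chrom, chrom_start = fields[0], int(fields[1])
                name, strand = fields[3], fields[5]
                block_sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                block_starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            exons = merge_intervals(
                [
                    (chrom_start + off, chrom_start + off + size)
                    for off, size in zip(block_starts, block_sizes)
                    if size > 0
                ]
            )
            if not exons:
                logger.warning("%s:%d: transcript %s has zero exon length, skipped",
                               path, lineno, name)
                continue
            models.append(TranscriptModel(name, chrom, strand, exons))
    return models


def _load_gff3(path: str) -> list[TranscriptModel]:
    import gffutils

    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise AnnotationError(f"failed to parse GFF3 {path}: {exc}") from exc

    exons_by_parent: dict[str, list[tuple[int, int]]] = defaultdict(list)
    meta: dict[str, tuple[str, str]] = {}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", [exon.id])
        for parent in parents:
            # gffutils start is 1-based inclusive
            exons_by_parent[parent].append((exon.start - 1, exon.end))
            meta.setdefault(parent, (exon.seqid, exon.strand))
    models = []
    for tid in sorted(exons_by_parent):
        chrom, strand = meta[tid]
        exons = merge_intervals(exons_by_parent[tid])
        if sum(e - s for s, e in exons) == 0:
            logger.warning("transcript %s has zero exon length, skipped", tid)
            continue
        models.append(TranscriptModel(tid, chrom, strand, exons))
    return models


def read_filter(
    qualities: Sequence[int] | None,
    *,
    min_quality: int = MIN_BASE_QUALITY,
    max_low_fraction: float = MAX_LOW_QUALITY_FRACTION,
    missing_quality_policy: str = "discard",
) -> tuple[bool, int, int]:
    """Quality-filter one read.

    Returns ``(keep, trim_start, trim_end)`` where ``[trim_start,
    trim_end)`` is the query interval surviving 5'/3' trimming of
    low-quality (Q < ``min_quality``) bases.  The read is discarded
    (keep=False) when strictly more than ``max_low_fraction`` of its
    bases fall below the quality cutoff.
    """
    if qualities is None or len(qualities) == 0:
        if missing_quality_policy == "keep":
            return True, 0, 0
        logger.warning("read without base qualities discarded")
        return False, 0, 0
    n = len(qualities)
    n_low = sum(1 for q in qualities if q < min_quality)
    if n_low > max_low_fraction * n:
        return False, 0, 0
    start = 0
    while start < n and qualities[start] < min_quality:
        start += 1
    end = n
    while end > start and qualities[end - 1] < min_quality:
        end -= 1
    return True, start, end


@dataclass
class PileupSet:
    """Pileups and library bookkeeping for one pooled sample x stage."""

    library: SampleLibrary
    # (transcript_id, pos) -> PileupColumn
    columns: dict[tuple[str, int], PileupColumn] = field(default_factory=dict)
    # transcript_id -> number of retained reads overlapping its exons
    transcript_read_counts: Counter = field(default_factory=Counter)
    # per input file: retained mapped read totals (replicate-level)
    per_file_totals: dict[str, int] = field(default_factory=dict)
    per_file_transcript_counts: dict[str, Counter] = field(default_factory=dict)


def _exon_index(transcripts: Iterable[TranscriptModel]) -> dict[str, dict[int, list[str]]]:
    index: dict[str, dict[int, list[str]]] = defaultdict(dict)
    for tx in transcripts:
        chrom_map = index[tx.chrom]
        for pos in tx.positions():
            chrom_map.setdefault(pos, []).append(tx.transcript_id)
    return index


def build_pileups(
    sam_paths: Sequence[str | os.PathLike],
    transcripts: Sequence[TranscriptModel],
    library: SampleLibrary,
    *,
    min_quality: int = MIN_BASE_QUALITY,
    max_low_fraction: float = MAX_LOW_QUALITY_FRACTION,
) -> PileupSet:
    """Build exon-restricted pileups from one or more SAM/BAM files.

    Multiple files (biological replicates) are pooled into a single
    pileup; per-file totals are retained for replicate-agreement
    reporting.  Secondary, supplementary and unmapped alignments are
    skipped; duplicates are kept.
    """
    index = _exon_index(transcripts)
    annot_chroms = set(index)
    result = PileupSet(library=library)
    for sam_path in sam_paths:
        sam_path = os.fspath(sam_path)
        retained = 0
        tx_counts: Counter = Counter()
        with pysam.AlignmentFile(sam_path, check_sq=False) as sam:
            sam_chroms = set(sam.references or ())
            if sam_chroms and annot_chroms and not (sam_chroms & annot_chroms):
                raise AnnotationError(
                    "chromosome names in SAM do not match annotation: "
                    f"SAM has {sorted(sam_chroms)[:5]}, "
                    f"annotation has {sorted(annot_chroms)[:5]}"
                )
            for read in sam:
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                quals = read.query_qualities
                keep, trim_start, trim_end = read_filter(
                    quals,
                    min_quality=min_quality,
                    max_low_fraction=max_low_fraction,
                )
                if not keep:
                    continue
                retained += 1
                chrom_map = index.get(read.reference_name)
                if chrom_map is None:
                    continue
                seq = read.query_sequence
                touched: set[str] = set()
                for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                    if qpos < trim_start or qpos >= trim_end:
                        continue
                    tids = chrom_map.get(rpos)
                    if tids is None:
                        continue
                    base = seq[qpos].upper()
                    high_q = quals[qpos] >= min_quality and base in BASES
                    for tid in tids:
                        touched.add(tid)
                        key = (tid, rpos)
                        col = result.columns.get(key)
                        if col is None:
                            col = PileupColumn(chrom=read.reference_name, pos=rpos)
                            result.columns[key] = col
                        if high_q:
                            col.counts[base] += 1
                        else:
                            col.other_count += 1
                for tid in touched:
                    tx_counts[tid] += 1
        result.per_file_totals[sam_path] = retained
        result.per_file_transcript_counts[sam_path] = tx_counts
        result.transcript_read_counts.update(tx_counts)
        result.library.total_mapped_reads += retained
    return result


# ---------------------------------------------------------------------------
# VCF output

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=TID,Number=1,Type=String,Description="Transcript id">
##INFO=<ID=DP1,Number=1,Type=Integer,Description="Supporting depth in parent 1">
##INFO=<ID=DP2,Number=1,Type=Integer,Description="Supporting depth in parent 2">
##INFO=<ID=STAGES,Number=.,Type=String,Description="Stages at which the SNP was detected">
"""


def write_snp_vcf(snps: Iterable, path: str | os.PathLike, contigs: Mapping[str, int] | None = None) -> None:
    """Write inter-parental SNP calls as VCF 4.2 (REF = parent1 allele)."""
    snps = sorted(snps, key=lambda s: (s.chrom, s.pos, s.transcript_id))
    with open(path, "w") as out:
        out.write(VCF_HEADER)
        if contigs:
            for name, length in contigs.items():
                out.write(f"##contig=<ID={name},length={length}>\n")
        else:
            for name in sorted({s.chrom for s in snps}):
                out.write(f"##contig=<ID={name}>\n")
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for snp in snps:
            stages = ",".join(sorted(snp.stages_detected))
            info = (
                f"TID={snp.transcript_id};DP1={snp.depth_p1};DP2={snp.depth_p2};"
                f"STAGES={stages}"
            )
            out.write(
                f"{snp.chrom}\t{snp.pos + 1}\t.\t{snp.allele_p1}\t{snp.allele_p2}\t"
                f"{snp.qual:.2f}\tPASS\t{info}\n"
            )


def read_snp_vcf(path: str | os.PathLike) -> list:
    """Read a VCF written by :func:`write_snp_vcf` back into SnpCall objects."""
    from asepipe.snp_discovery import SnpCall

    calls = []
    with pysam.VariantFile(os.fspath(path)) as vcf:
        for rec in vcf:
            info = rec.info
            stages = info["STAGES"]
            if isinstance(stages, str):
                stages = (stages,)
            stage_set = frozenset(
                s for item in stages for s in str(item).split(",")
            )
            calls.append(
                SnpCall(
                    transcript_id=str(info["TID"]),
                    chrom=rec.chrom,
                    pos=rec.pos - 1,
                    allele_p1=rec.ref,
                    allele_p2=rec.alts[0],
                    depth_p1=int(info["DP1"]),
                    depth_p2=int(info["DP2"]),
                    qual=float(rec.qual),
                    stages_detected=stage_set,
                )
            )
    return calls
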
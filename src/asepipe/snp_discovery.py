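"""Inter-parental transcriptome SNP calling and substitution-spectrum analysis.

A site is called as a SNP between the two inbred parental lines when
each parent's quality-filtered pileup yields a consensus base, the two
consensus bases differ, each parent supports its base with at least
``min_depth`` reads at every stage, the site quality is at least
``min_qual``, and the identical allele pair is observed independently at
both developmental stages.  Because the parents are inbred (homozygous)
lines, within-parent heterozygosity is excluded by design and the
consensus requirement defaults to strict unanimity among Q>=20 bases.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy.stats import binom

from asepipe.annotation_io import PileupColumn

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Canonical labels for the six complement-collapsed directed substitution
#: classes.  A directed substitution X->Y (parent1 allele -> parent2 allele)
#: is equivalent to its reverse complement comp(X)->comp(Y), which is the
#: same event read off the opposite strand; each class is labelled by the
#: member whose first base is A or C (so G->A collapses into C:T, T->C into
#: A:G, G->T into C:A, and so on).
SPECTRUM_CLASSES = ("A:C", "A:G", "A:T", "C:A", "C:G", "C:T")

#: The two classes jointly holding every transition (C<->T on either
#: strand orientation, equivalently G<->A): C:T = {C->T, G->A} and
#: A:G = {A->G, T->C}.
TRANSITION_CLASSES = ("A:G", "C:T")


@dataclass(frozen=True)
class SnpCall:
    """One inter-parental SNP in transcript space."""

    transcript_id: str
    chrom: str
    pos: int  # 0-based
    allele_p1: str
    allele_p2: str
    depth_p1: int
    depth_p2: int
    qual: float
    stages_detected: frozenset[str]

    def __post_init__(self) -> None:
        if self.allele_p1 == self.allele_p2:
            raise ValueError("SNP alleles must differ")

    @property
    def substitution_class(self) -> str:
        return canonical_class(self.allele_p1, self.allele_p2)


@dataclass
class SpectrumSummary:
    """Counts over the six complement-collapsed substitution classes.

    ``ct_ga_fraction`` is the strand-agnostic transition fraction: the
    share of SNPs that are C<->T on one strand (equivalently G<->A on the
    other), i.e. the combined mass of the C:T and A:G classes.  Under a
    uniform spectrum (all 12 directed substitutions equally likely) it
    converges to 1/3.
    """

    class_counts: dict[str, int]
    ct_ga_fraction: float

    @property
    def total(self) -> int:
        return sum(self.class_counts.values())


def canonical_class(allele_1: str, allele_2: str) -> str:
    """Collapse a directed substitution onto its canonical class label."""
    a, b = allele_1.upper(), allele_2.upper()
    if a not in COMPLEMENT or b not in COMPLEMENT or a == b:
        raise ValueError(f"invalid substitution {allele_1}->{allele_2}")
    if a not in ("A", "C"):
        a, b = COMPLEMENT[a], COMPLEMENT[b]
    return f"{a}:{b}"


def consensus_base(column: PileupColumn, max_minor_fraction: float = 0.0) -> str | None:
    """Consensus base of one parental pileup column, or None.

    Returns the single base carrying at least ``1 - max_minor_fraction``
    of the quality (Q>=20) bases.  With the default 0 this demands
    strict unanimity.  Ties never yield a consensus.
    """
    total = column.depth
    if total == 0:
        return None
    (top_base, top_count), *rest = column.counts.most_common()
    if rest and rest[0][1] == top_count:
        return None
    if total - top_count <= max_minor_fraction * total:
        return top_base
    return None


def site_quality(column_p1: PileupColumn, column_p2: PileupColumn) -> float:
    """Phred-scaled confidence that both parental columns are homogeneous.

    For each parent the score is -10*log10 of the probability that a
    truly heterogeneous site (minor-allele fraction 0.5) would show at
    most the observed number of minor bases; the site quality is the
    minimum over the two parents.  The score increases with depth and
    decreases with discordant reads, and any unanimous column of depth
    >= 10 scores above 30.
    """
    quals = []
    for col in (column_p1, column_p2):
        depth = col.depth
        if depth == 0:
            return 0.0
        minor = depth - max(col.counts.values())
        p = float(binom.cdf(minor, depth, 0.5))
        quals.append(-10.0 * math.log10(max(p, 1e-300)))
    return min(quals)


def call_snps(
    pileups_p1: Mapping[str, Mapping[tuple[str, int], PileupColumn]],
    pileups_p2: Mapping[str, Mapping[tuple[str, int], PileupColumn]],
    *,
    min_depth: int = 10,
    min_qual: float = 20.0,
    max_minor_fraction: float = 0.0,
    chrom_of: Mapping[str, str] | None = None,
) -> list[SnpCall]:
    """Call inter-parental SNPs from per-stage parental pileups.

    ``pileups_p1`` / ``pileups_p2`` map stage -> {(transcript_id, pos):
    PileupColumn}.  A SNP must be independently supported, with the
    identical allele pair and depth >= ``min_depth`` in each parent, at
    every stage; sites with conflicting alleles between stages are
    dropped (and logged), as are multi-allelic sites.
    """
    stages = tuple(pileups_p1)
    if tuple(pileups_p2) != stages:
        raise ValueError("parental pileups cover different stages")
    # candidate alleles per stage
    per_stage: dict[str, dict[tuple[str, int], tuple[str, str, int, int, float]]] = {}
    for stage in stages:
        cols1, cols2 = pileups_p1[stage], pileups_p2[stage]
        found: dict[tuple[str, int], tuple[str, str, int, int, float]] = {}
        for key, col1 in cols1.items():
            col2 = cols2.get(key)
            if col2 is None:
                continue
            b1 = consensus_base(col1, max_minor_fraction)
            b2 = consensus_base(col2, max_minor_fraction)
            if b1 is None or b2 is None or b1 == b2:
                continue
            d1, d2 = col1.counts[b1], col2.counts[b2]
            if d1 < min_depth or d2 < min_depth:
                continue
            found[key] = (b1, b2, d1, d2, site_quality(col1, col2))
        per_stage[stage] = found

    first, *others = stages
    calls: list[SnpCall] = []
    for key, cand in per_stage[first].items():
        alleles = (cand[0], cand[1])
        ok = True
        depth1, depth2 = cand[2], cand[3]
        qual = cand[4]
        for stage in others:
            other = per_stage[stage].get(key)
            if other is None:
                ok = False
                break
            if (other[0], other[1]) != alleles:
                logger.info("site %s dropped: conflicting alleles between stages", key)
                ok = False
                break
            depth1 += other[2]
            depth2 += other[3]
            qual = min(qual, other[4])
        if not ok or qual < min_qual:
            continue
        tid, pos = key
        chrom = (
            chrom_of[tid]
            if chrom_of is not None
            else pileups_p1[first][key].chrom
        )
        calls.append(
            SnpCall(
                transcript_id=tid,
                chrom=chrom,
                pos=pos,
                allele_p1=alleles[0],
                allele_p2=alleles[1],
                depth_p1=depth1,
                depth_p2=depth2,
                qual=qual,
                stages_detected=frozenset(stages),
            )
        )
    calls.sort(key=lambda s: (s.chrom, s.pos, s.transcript_id))
    return calls


def substitution_spectrum(snps: Iterable[SnpCall]) -> SpectrumSummary:
    """Tally SNPs into the six complement-collapsed substitution classes."""
    counts = Counter({cls: 0 for cls in SPECTRUM_CLASSES})
    for snp in snps:
        counts[snp.substitution_class] += 1
    total = sum(counts.values())
    transitions = sum(counts[c] for c in TRANSITION_CLASSES)
    fraction = transitions / total if total else 0.0
    return SpectrumSummary(class_counts=dict(counts), ct_ga_fraction=fraction)
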
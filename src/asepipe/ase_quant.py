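"""Allele-specific expression quantification in the F1 hybrid.

At every inter-parental SNP the hybrid's reads are partitioned by the
parental allele they carry; a two-sided exact binomial test against the
null of equal allelic expression (p = 0.5) flags allelic imbalance.
SNP-level results are aggregated to transcript-level bias calls, and
transcripts are classified by the stage pattern of their bias (both
stages, one stage, stage-switching) and by strong mono-allelic
expression (parent-1 read fraction below 0.3 or above 0.7).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from asepipe.annotation_io import PileupColumn
from asepipe.snp_discovery import SnpCall

#: SNP-level significance threshold for allelic bias.
DEFAULT_ALPHA = 0.01
#: Transcripts with fewer SNP-supporting hybrid reads are discarded.
DEFAULT_MIN_SUPPORT = 20
#: Strong mono-allelic expression cutoffs on the parent-1 read fraction.
STRONG_LO = 0.3
STRONG_HI = 0.7


@dataclass
class AseRecord:
    """Hybrid allele counts and bias test at one SNP, one stage."""

    snp: SnpCall
    stage: str
    n_p1: int
    n_p2: int
    n_other: int
    p_value: float | None = None

    @property
    def n_informative(self) -> int:
        return self.n_p1 + self.n_p2

    @property
    def p1_fraction(self) -> float | None:
        n = self.n_informative
        return self.n_p1 / n if n else None


@dataclass
class BiasCall:
    """Transcript-level allelic-bias call at one stage."""

    transcript_id: str
    stage: str
    n_snps: int
    n_significant: int
    direction: str  # p1_biased | p2_biased | balanced | contradictory
    supporting_reads: int
    p1_fraction: float | None = None  # read-weighted pooled fraction


@dataclass
class StagePattern:
    """Cross-stage bias pattern of one transcript."""

    transcript_id: str
    pattern: str  # both_stages | tillering_only | heading_only | none
    strong_bias: str  # p1_predominant | p2_predominant | switching | none


def binomial_bias_test(n_p1: int, n_p2: int) -> float:
    """Two-sided exact binomial p-value under H0: p = 0.5.

    Minimum-likelihood method: the p-value sums P(k) over every outcome
    k whose null probability does not exceed that of the observation.
    Because the null pmf is symmetric and strictly unimodal, this equals
    the doubled smaller tail, computed here in exact integer arithmetic
    (correctly rounded on conversion to float).  Symmetric in its
    arguments by construction.
    """
    if n_p1 < 0 or n_p2 < 0:
        raise ValueError("counts must be non-negative")
    n = n_p1 + n_p2
    if n == 0:
        raise ValueError("binomial test undefined for zero informative reads")
    k = min(n_p1, n_p2)
    if 2 * k >= n:
        return 1.0
    tail = 0
    coeff = 1  # C(n, 0)
    for i in range(k + 1):
        tail += coeff
        coeff = coeff * (n - i) // (i + 1)
    return min(1.0, (2 * tail) / (1 << n))


def count_hybrid_alleles(
    hybrid_pileups: Mapping[tuple[str, int], PileupColumn],
    snps: Iterable[SnpCall],
    stage: str,
    *,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[AseRecord]:
    """Count parental alleles in hybrid reads at each SNP for one stage.

    SNP positions uncovered in the hybrid yield zero-count records (kept
    but never tested); transcripts whose summed informative reads across
    SNPs fall below ``min_support`` are dropped entirely for the stage.
    """
    records: list[AseRecord] = []
    support: dict[str, int] = {}
    for snp in snps:
        col = hybrid_pileups.get((snp.transcript_id, snp.pos))
        if col is None:
            rec = AseRecord(snp=snp, stage=stage, n_p1=0, n_p2=0, n_other=0)
        else:
            n_p1 = col.counts[snp.allele_p1]
            n_p2 = col.counts[snp.allele_p2]
            n_other = col.depth - n_p1 - n_p2
            rec = AseRecord(snp=snp, stage=stage, n_p1=n_p1, n_p2=n_p2, n_other=n_other)
        records.append(rec)
        support[snp.transcript_id] = support.get(snp.transcript_id, 0) + rec.n_informative
    kept = [r for r in records if support[r.snp.transcript_id] >= min_support]
    return kept


def attach_p_values(records: Iterable[AseRecord]) -> list[AseRecord]:
    """Attach exact binomial p-values; zero-count records stay untested."""
    out = []
    for rec in records:
        if rec.n_informative > 0:
            rec.p_value = binomial_bias_test(rec.n_p1, rec.n_p2)
        out.append(rec)
    return out


def aggregate_transcript(
    records: Sequence[AseRecord],
    alpha: float = DEFAULT_ALPHA,
) -> BiasCall:
    """Aggregate the SNP-level records of one transcript and stage.

    Direction is decided on the significant SNPs only: p1_biased if all
    of them favor parent 1, p2_biased if all favor parent 2,
    contradictory if they disagree (such transcripts are excluded
    downstream), balanced if none is significant.
    """
    if not records:
        raise ValueError("no records to aggregate")
    tid = records[0].snp.transcript_id
    stage = records[0].stage
    tested = [r for r in records if r.p_value is not None]
    significant = [r for r in tested if r.p_value < alpha]
    n_p1 = sum(r.n_p1 for r in records)
    n_inf = sum(r.n_informative for r in records)
    pooled = n_p1 / n_inf if n_inf else None
    if not significant:
        direction = "balanced"
    else:
        signs = {r.p1_fraction > 0.5 for r in significant}
        if len(signs) > 1:
            direction = "contradictory"
        elif signs == {True}:
            direction = "p1_biased"
        else:
            direction = "p2_biased"
    return BiasCall(
        transcript_id=tid,
        stage=stage,
        n_snps=len(records),
        n_significant=len(significant),
        direction=direction,
        supporting_reads=n_inf,
        p1_fraction=pooled,
    )


def classify_stage_pattern(
    call_tillering: BiasCall,
    call_heading: BiasCall,
    *,
    strong_lo: float = STRONG_LO,
    strong_hi: float = STRONG_HI,
) -> StagePattern:
    """Cross-stage pattern and strong-bias class of one transcript.

    ``pattern`` records at which stages the transcript shows a
    significant (non-contradictory) allelic bias.  ``strong_bias`` uses
    the read-weighted pooled parent-1 fraction per stage with strict
    cutoffs (< strong_lo or > strong_hi): a transcript is
    p1_predominant / p2_predominant if at least one stage is strongly
    skewed toward that parent and no stage is strongly skewed toward the
    other, and switching if the two stages are strongly skewed toward
    opposite parents.
    """
    if call_tillering.transcript_id != call_heading.transcript_id:
        raise ValueError("stage calls belong to different transcripts")
    biased = {
        call.stage
        for call in (call_tillering, call_heading)
        if call.direction in ("p1_biased", "p2_biased")
    }
    if biased == {"tillering", "heading"}:
        pattern = "both_stages"
    elif biased == {"tillering"}:
        pattern = "tillering_only"
    elif biased == {"heading"}:
        pattern = "heading_only"
    else:
        pattern = "none"

    skews = []
    for call in (call_tillering, call_heading):
        f = call.p1_fraction
        if f is None:
            skews.append(0)
        elif f > strong_hi:
            skews.append(1)
        elif f < strong_lo:
            skews.append(-1)
        else:
            skews.append(0)
    if 1 in skews and -1 in skews:
        strong = "switching"
    elif 1 in skews:
        strong = "p1_predominant"
    elif -1 in skews:
        strong = "p2_predominant"
    else:
        strong = "none"
    return StagePattern(
        transcript_id=call_tillering.transcript_id,
        pattern=pattern,
        strong_bias=strong,
    )


@dataclass
class Census:
    """Summary of the allelic-bias landscape across stages."""

    per_stage: dict[str, dict[str, int]] = field(default_factory=dict)
    n_at_least_one_stage: int = 0
    n_both_stages: int = 0
    n_one_stage: int = 0
    n_both_p1: int = 0
    strong_counts: dict[str, int] = field(default_factory=dict)


def bias_census(
    patterns: Sequence[StagePattern],
    calls: Sequence[BiasCall],
) -> Census:
    """Tally the transcript-level calls into a census table."""
    census = Census()
    for stage in sorted({c.stage for c in calls}):
        stage_calls = [c for c in calls if c.stage == stage]
        tested = len(stage_calls)
        p1 = sum(1 for c in stage_calls if c.direction == "p1_biased")
        p2 = sum(1 for c in stage_calls if c.direction == "p2_biased")
        contradictory = sum(1 for c in stage_calls if c.direction == "contradictory")
        census.per_stage[stage] = {
            "tested": tested,
            "biased": p1 + p2,
            "p1_biased": p1,
            "p2_biased": p2,
            "contradictory": contradictory,
        }
    census.n_both_stages = sum(1 for p in patterns if p.pattern == "both_stages")
    census.n_one_stage = sum(
        1 for p in patterns if p.pattern in ("tillering_only", "heading_only")
    )
    census.n_at_least_one_stage = census.n_both_stages + census.n_one_stage

    both_ids = {p.transcript_id for p in patterns if p.pattern == "both_stages"}
    census.n_both_p1 = sum(
        1
        for tid in both_ids
        if all(
            c.direction == "p1_biased" for c in calls if c.transcript_id == tid
        )
    )
    census.strong_counts = {
        key: sum(1 for p in patterns if p.strong_bias == key)
        for key in ("p1_predominant", "p2_predominant", "switching")
    }
    census.strong_counts["total"] = sum(census.strong_counts.values())
    return census


def derived_census(
    *,
    n_tested_transcripts: int,
    n_biased_at_least_one: int,
    n_biased_both: int,
    tillering_p1: int,
    tillering_biased: int,
    heading_p1: int,
    heading_biased: int,
    both_p1: int,
    strong_p1: int,
    strong_p2: int,
    strong_switching: int,
) -> dict[str, float | int]:
    """Derived percentages and partitions from census counts.

    Pure arithmetic on transcript counts — usable both on a pipeline
    census and on externally reported counts.  Percentages are rounded
    to the nearest integer except the balanced share, reported to two
    decimals.
    """
    return {
        "pct_biased_at_least_one": round(100 * n_biased_at_least_one / n_tested_transcripts),
        "pct_p1_tillering": round(100 * tillering_p1 / tillering_biased),
        "pct_p1_heading": round(100 * heading_p1 / heading_biased),
        "pct_p1_both_stages": round(100 * both_p1 / n_biased_both),
        "pct_balanced_tillering": round(
            100 * (n_tested_transcripts - tillering_biased) / n_tested_transcripts, 2
        ),
        "n_one_stage": n_biased_at_least_one - n_biased_both,
        "n_strong_total": strong_p1 + strong_p2 + strong_switching,
    }
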
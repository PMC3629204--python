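"""Total-expression metrics and cis/trans regulatory classification.

Expression is summarized as RPKM (reads per kilobase of exon per million
mapped reads) and fold-coverage.  Parental differential expression is
tested with a two-sided Fisher exact test on pooled counts followed by
Benjamini-Hochberg FDR; a transcript is significantly differentially
expressed when FDR <= 0.05 and |log2 fold change| >= 1.

Regulatory mode is inferred by confronting the parental expression
ratio with the hybrid allelic ratio: a pure cis effect reproduces the
parental ratio between the two alleles of the hybrid (both alleles keep
their parental behaviour), whereas a pure trans effect exposes both
alleles to the same cellular environment and equalizes them, so the
parental difference vanishes from the hybrid's allelic ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy.stats import binomtest, fisher_exact
from statsmodels.stats.multitest import multipletests

#: Pseudocount added to both RPKM values before the log2 ratio.
LOG2FC_PSEUDOCOUNT = 0.5
#: Dual significance gate for parental differential expression.
DEFAULT_FDR = 0.05
DEFAULT_MIN_LOG2FC = 1.0
#: Default p-value floor for allelic/parental ratio compatibility (cis call).
DEFAULT_COMPAT_ALPHA = 0.05


@dataclass
class ExpressionRecord:
    """Per-transcript expression in one library."""

    transcript_id: str
    sample_id: str
    read_count: int
    rpkm: float
    coverage: float


@dataclass
class DiffExpressionCall:
    """Parental differential-expression test for one transcript."""

    transcript_id: str
    log2_fc: float  # parent1 over parent2
    p_value: float
    fdr: float
    significant: bool
    ratio: float | None = None  # pseudocounted RPKM ratio parent1/parent2


@dataclass
class RegulatoryCall:
    """cis/trans classification of one transcript at one stage."""

    transcript_id: str
    stage: str
    parental_ratio: float
    allelic_ratio: float | None
    mode: str  # cis | trans | cis_plus_trans | conserved | ambiguous
    compat_p: float | None = None


def compute_rpkm(read_count: int, summed_exon_length: int, total_mapped: int) -> float:
    """Reads per kilobase of exon per million mapped reads."""
    if summed_exon_length <= 0:
        raise ValueError("summed exon length must be positive")
    if total_mapped <= 0:
        raise ValueError("total mapped reads must be positive")
    return read_count / (summed_exon_length / 1000.0) / (total_mapped / 1e6)


def compute_coverage(read_count: int, summed_exon_length: int) -> float:
    """Fold coverage: mapped reads x 100 bp over the summed exon length."""
    if summed_exon_length <= 0:
        raise ValueError("summed exon length must be positive")
    return read_count * 100.0 / summed_exon_length


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values."""
    if len(p_values) == 0:
        return []
    return list(multipletests(p_values, method="fdr_bh")[1])


def diff_expression(
    counts_p1: Mapping[str, int],
    counts_p2: Mapping[str, int],
    total_p1: int,
    total_p2: int,
    exon_lengths: Mapping[str, int],
    *,
    fdr_threshold: float = DEFAULT_FDR,
    min_log2fc: float = DEFAULT_MIN_LOG2FC,
) -> list[DiffExpressionCall]:
    """Test each transcript for parental differential expression.

    Each transcript's pooled counts are confronted in a 2x2 Fisher exact
    test against the rest of its library; BH FDR is applied across
    transcripts, and the fold change is computed on pseudocounted RPKM.
    """
    tids = sorted(set(counts_p1) | set(counts_p2))
    p_values = []
    log2fcs = []
    ratios = []
    for tid in tids:
        c1 = counts_p1.get(tid, 0)
        c2 = counts_p2.get(tid, 0)
        table = [[c1, total_p1 - c1], [c2, total_p2 - c2]]
        p_values.append(fisher_exact(table, alternative="two-sided")[1])
        rpkm1 = compute_rpkm(c1, exon_lengths[tid], total_p1)
        rpkm2 = compute_rpkm(c2, exon_lengths[tid], total_p2)
        ratio = (rpkm1 + LOG2FC_PSEUDOCOUNT) / (rpkm2 + LOG2FC_PSEUDOCOUNT)
        ratios.append(ratio)
        log2fcs.append(math.log2(ratio))
    fdrs = bh_adjust(p_values)
    calls = []
    for tid, p, fdr, lfc, ratio in zip(tids, p_values, fdrs, log2fcs, ratios):
        calls.append(
            DiffExpressionCall(
                transcript_id=tid,
                log2_fc=lfc,
                p_value=p,
                fdr=fdr,
                significant=bool(fdr <= fdr_threshold and abs(lfc) >= min_log2fc),
                ratio=ratio,
            )
        )
    return calls


def classify_regulation(
    transcript_id: str,
    stage: str,
    parental_ratio: float,
    parental_significant: bool,
    n_p1: int,
    n_p2: int,
    *,
    allelic_significant: bool | None = None,
    bias_alpha: float = 0.01,
    compat_alpha: float = DEFAULT_COMPAT_ALPHA,
) -> RegulatoryCall:
    """Classify one transcript's regulatory mode at one stage.

    - conserved: no parental difference, no allelic bias;
    - cis: parental difference mirrored by the hybrid allelic ratio
      (binomial test of the parent-1 allele count against the fraction
      expected from the parental ratio is non-significant, p >=
      ``compat_alpha``);
    - trans: parental difference with balanced hybrid alleles;
    - cis_plus_trans: parental difference and allelic bias, but the
      allelic ratio is incompatible with the parental ratio;
    - ambiguous: allelic bias without a parental difference (or
      uncomputable ratios).

    ``allelic_significant`` may be supplied from an upstream
    transcript-level bias call; by default it is recomputed from the
    pooled counts with the exact binomial test at ``bias_alpha``.
    """
    from asepipe.ase_quant import binomial_bias_test

    n = n_p1 + n_p2
    if n == 0 or parental_ratio <= 0 or not math.isfinite(parental_ratio):
        return RegulatoryCall(transcript_id, stage, parental_ratio, None, "ambiguous")
    allelic_ratio = n_p1 / n_p2 if n_p2 else math.inf
    if allelic_significant is None:
        allelic_significant = binomial_bias_test(n_p1, n_p2) < bias_alpha

    if not parental_significant and not allelic_significant:
        mode, compat_p = "conserved", None
    elif not parental_significant:
        mode, compat_p = "ambiguous", None
    elif not allelic_significant:
        mode, compat_p = "trans", None
    else:
        expected = parental_ratio / (1.0 + parental_ratio)
        compat_p = binomtest(n_p1, n, expected, alternative="two-sided").pvalue
        mode = "cis" if compat_p >= compat_alpha else "cis_plus_trans"
    return RegulatoryCall(
        transcript_id=transcript_id,
        stage=stage,
        parental_ratio=parental_ratio,
        allelic_ratio=allelic_ratio,
        mode=mode,
        compat_p=compat_p,
    )
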
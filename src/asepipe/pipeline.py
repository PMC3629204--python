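"""End-to-end orchestration: pileups -> SNPs -> ASE -> expression -> regulation.

`run_pipeline` consumes a :class:`PipelineConfig` naming the annotation
and the per-sample, per-stage SAM files (replicates pooled), applies
every stage of the analysis with the configured thresholds, and writes a
report bundle: SNP VCF, substitution-spectrum TSV, per-SNP and
per-transcript ASE tables, bias census, expression / differential
expression / regulation tables, replicate-agreement R^2 table, and a
machine-readable run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from asepipe import ase_quant, expression_metrics, snp_discovery
from asepipe.annotation_io import (
    SampleLibrary,
    build_pileups,
    load_annotation,
    write_snp_vcf,
)

logger = logging.getLogger(__name__)

STAGES = ("tillering", "heading")
SAMPLES = ("parent1", "parent2", "hybrid")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run.

    ``sam`` maps sample name (parent1/parent2/hybrid) to stage
    (tillering/heading) to a list of replicate SAM paths (pooled before
    pileup).  Threshold defaults follow the analysis design: SNP support
    depth 10 per parent per stage, site quality 20, 20 SNP-supporting
    hybrid reads per transcript, SNP-level bias alpha 0.01, DE gate
    FDR <= 0.05 with |log2FC| >= 1, strong-bias cutoffs 0.3/0.7.
    """

    annotation: str
    sam: dict[str, dict[str, list[str]]]
    outdir: str
    min_depth: int = 10
    min_qual: float = 20.0
    max_minor_fraction: float = 0.0
    min_support: int = 20
    alpha: float = 0.01
    fdr: float = 0.05
    min_log2fc: float = 1.0
    strong_lo: float = 0.3
    strong_hi: float = 0.7
    compat_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.strong_lo < 0.5 < self.strong_hi < 1):
            raise ValueError("strong-bias cutoffs must satisfy lo < 0.5 < hi")
        for name in ("min_depth", "min_qual", "min_support", "alpha", "fdr", "min_log2fc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike, **overrides) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)


@dataclass
class PipelineResult:
    snps: list = field(default_factory=list)
    spectrum: object = None
    ase_records: dict[str, list] = field(default_factory=dict)
    bias_calls: list = field(default_factory=list)
    patterns: list = field(default_factory=list)
    census: object = None
    expression: list = field(default_factory=list)
    de_calls: dict[str, list] = field(default_factory=dict)
    regulation: list = field(default_factory=list)
    replicate_r2: pd.DataFrame | None = None
    outputs: dict[str, str] = field(default_factory=dict)


def replicate_agreement(
    rep1: Sequence[float], rep2: Sequence[float]
) -> float:
    """Squared Pearson correlation of log10(RPKM + 1) between replicates."""
    x = np.log10(np.asarray(rep1, dtype=float) + 1.0)
    y = np.log10(np.asarray(rep2, dtype=float) + 1.0)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("replicate vectors must share >= 3 transcripts")
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the report bundle to ``config.outdir``."""
    os.makedirs(config.outdir, exist_ok=True)
    result = PipelineResult()

    # --- annotation -------------------------------------------------------
    try:
        transcripts = load_annotation(config.annotation)
    except Exception as exc:
        raise PipelineError(f"annotation stage failed: {exc}") from exc
    exon_lengths = {t.transcript_id: t.summed_exon_length for t in transcripts}
    chrom_of = {t.transcript_id: t.chrom for t in transcripts}

    # --- pileups ----------------------------------------------------------
    pileups: dict[tuple[str, str], object] = {}
    try:
        for sample in SAMPLES:
            for stage in STAGES:
                paths = config.sam[sample][stage]
                lib = SampleLibrary(f"{sample}.{stage}", sample, stage)
                pileups[(sample, stage)] = build_pileups(paths, transcripts, lib)
    except KeyError as exc:
        raise PipelineError(f"pileup stage failed: missing SAM entry for {exc}") from exc
    except Exception as exc:
        raise PipelineError(f"pileup stage failed: {exc}") from exc

    # --- SNP discovery ----------------------------------------------------
    try:
        snps = snp_discovery.call_snps(
            {stage: pileups[("parent1", stage)].columns for stage in STAGES},
            {stage: pileups[("parent2", stage)].columns for stage in STAGES},
            min_depth=config.min_depth,
            min_qual=config.min_qual,
            max_minor_fraction=config.max_minor_fraction,
            chrom_of=chrom_of,
        )
        spectrum = snp_discovery.substitution_spectrum(snps)
    except Exception as exc:
        raise PipelineError(f"snp stage failed: {exc}") from exc
    result.snps, result.spectrum = snps, spectrum

    vcf_path = os.path.join(config.outdir, "snps.vcf")
    write_snp_vcf(snps, vcf_path)
    result.outputs["snp_vcf"] = vcf_path

    spec_rows = [
        {"class": cls, "count": n}
        for cls, n in sorted(spectrum.class_counts.items())
    ]
    spec_df = pd.DataFrame(spec_rows)
    spec_df["fraction"] = (
        spec_df["count"] / spectrum.total if spectrum.total else 0.0
    )
    spec_path = os.path.join(config.outdir, "spectrum.tsv")
    spec_df.to_csv(spec_path, sep="\t", index=False)
    result.outputs["spectrum"] = spec_path

    # --- hybrid ASE -------------------------------------------------------
    try:
        calls: list = []
        per_stage_records: dict[str, list] = {}
        for stage in STAGES:
            records = ase_quant.count_hybrid_alleles(
                pileups[("hybrid", stage)].columns,
                snps,
                stage,
                min_support=config.min_support,
            )
            records = ase_quant.attach_p_values(records)
            per_stage_records[stage] = records
            by_tid: dict[str, list] = {}
            for rec in records:
                by_tid.setdefault(rec.snp.transcript_id, []).append(rec)
            for tid in sorted(by_tid):
                calls.append(ase_quant.aggregate_transcript(by_tid[tid], config.alpha))
        result.ase_records = per_stage_records
        result.bias_calls = calls

        calls_by_tid: dict[str, dict[str, object]] = {}
        for call in calls:
            calls_by_tid.setdefault(call.transcript_id, {})[call.stage] = call
        patterns = [
            ase_quant.classify_stage_pattern(
                stage_calls["tillering"],
                stage_calls["heading"],
                strong_lo=config.strong_lo,
                strong_hi=config.strong_hi,
            )
            for stage_calls in (
                calls_by_tid[tid] for tid in sorted(calls_by_tid)
            )
            if len(stage_calls) == 2
        ]
        result.patterns = patterns
        result.census = ase_quant.bias_census(patterns, calls)
    except Exception as exc:
        raise PipelineError(f"ase stage failed: {exc}") from exc

    snp_rows = []
    for stage, records in per_stage_records.items():
        for rec in records:
            snp_rows.append(
                {
                    "transcript_id": rec.snp.transcript_id,
                    "chrom": rec.snp.chrom,
                    "pos": rec.snp.pos + 1,
                    "allele_p1": rec.snp.allele_p1,
                    "allele_p2": rec.snp.allele_p2,
                    "stage": stage,
                    "n_p1": rec.n_p1,
                    "n_p2": rec.n_p2,
                    "n_other": rec.n_other,
                    "p1_fraction": rec.p1_fraction,
                    "p_value": rec.p_value,
                }
            )
    ase_snp_path = os.path.join(config.outdir, "ase_snps.tsv")
    pd.DataFrame(snp_rows).to_csv(ase_snp_path, sep="\t", index=False)
    result.outputs["ase_snps"] = ase_snp_path

    tx_rows = [dataclasses.asdict(c) for c in calls]
    ase_tx_path = os.path.join(config.outdir, "ase_transcripts.tsv")
    pd.DataFrame(tx_rows).to_csv(ase_tx_path, sep="\t", index=False)
    result.outputs["ase_transcripts"] = ase_tx_path

    census_path = os.path.join(config.outdir, "census.json")
    with open(census_path, "w") as fh:
        json.dump(dataclasses.asdict(result.census), fh, indent=2)
    result.outputs["census"] = census_path

    pattern_path = os.path.join(config.outdir, "stage_patterns.tsv")
    pd.DataFrame([dataclasses.asdict(p) for p in patterns]).to_csv(
        pattern_path, sep="\t", index=False
    )
    result.outputs["stage_patterns"] = pattern_path

    # --- expression and differential expression --------------------------
    try:
        expr_records = []
        for (sample, stage), pset in pileups.items():
            total = pset.library.total_mapped_reads
            for tx in transcripts:
                tid = tx.transcript_id
                count = pset.transcript_read_counts.get(tid, 0)
                expr_records.append(
                    expression_metrics.ExpressionRecord(
                        transcript_id=tid,
                        sample_id=f"{sample}.{stage}",
                        read_count=count,
                        rpkm=expression_metrics.compute_rpkm(
                            count, exon_lengths[tid], total
                        )
                        if total
                        else 0.0,
                        coverage=expression_metrics.compute_coverage(
                            count, exon_lengths[tid]
                        ),
                    )
                )
        result.expression = expr_records

        de_calls: dict[str, list] = {}
        for stage in STAGES:
            p1 = pileups[("parent1", stage)]
            p2 = pileups[("parent2", stage)]
            de_calls[stage] = expression_metrics.diff_expression(
                dict(p1.transcript_read_counts),
                dict(p2.transcript_read_counts),
                p1.library.total_mapped_reads,
                p2.library.total_mapped_reads,
                exon_lengths,
                fdr_threshold=config.fdr,
                min_log2fc=config.min_log2fc,
            )
        result.de_calls = de_calls
    except Exception as exc:
        raise PipelineError(f"expression stage failed: {exc}") from exc

    expr_path = os.path.join(config.outdir, "expression.tsv")
    pd.DataFrame([dataclasses.asdict(r) for r in expr_records]).to_csv(
        expr_path, sep="\t", index=False
    )
    result.outputs["expression"] = expr_path

    de_rows = []
    for stage, stage_calls in de_calls.items():
        for call in stage_calls:
            row = dataclasses.asdict(call)
            row["stage"] = stage
            de_rows.append(row)
    de_path = os.path.join(config.outdir, "diff_expression.tsv")
    pd.DataFrame(de_rows).to_csv(de_path, sep="\t", index=False)
    result.outputs["diff_expression"] = de_path

    # --- cis/trans regulation --------------------------------------------
    try:
        regulation = []
        for stage in STAGES:
            de_by_tid = {c.transcript_id: c for c in de_calls[stage]}
            bias_by_tid = {
                c.transcript_id: c for c in calls if c.stage == stage
            }
            for tid in sorted(set(de_by_tid) & set(bias_by_tid)):
                bias = bias_by_tid[tid]
                if bias.direction == "contradictory":
                    continue
                de = de_by_tid[tid]
                n_p1 = sum(
                    r.n_p1
                    for r in per_stage_records[stage]
                    if r.snp.transcript_id == tid
                )
                n_p2 = sum(
                    r.n_p2
                    for r in per_stage_records[stage]
                    if r.snp.transcript_id == tid
                )
                regulation.append(
                    expression_metrics.classify_regulation(
                        tid,
                        stage,
                        de.ratio,
                        de.significant,
                        n_p1,
                        n_p2,
                        allelic_significant=bias.direction
                        in ("p1_biased", "p2_biased"),
                        compat_alpha=config.compat_alpha,
                    )
                )
        result.regulation = regulation
    except Exception as exc:
        raise PipelineError(f"regulation stage failed: {exc}") from exc

    reg_path = os.path.join(config.outdir, "regulation.tsv")
    pd.DataFrame([dataclasses.asdict(r) for r in regulation]).to_csv(
        reg_path, sep="\t", index=False
    )
    result.outputs["regulation"] = reg_path

    # --- replicate agreement ---------------------------------------------
    r2_rows = []
    for (sample, stage), pset in pileups.items():
        files = list(pset.per_file_totals)
        if len(files) < 2:
            continue
        vectors = []
        for path in files[:2]:
            total = max(pset.per_file_totals[path], 1)
            counts = pset.per_file_transcript_counts[path]
            vectors.append(
                [
                    expression_metrics.compute_rpkm(
                        counts.get(t.transcript_id, 0),
                        exon_lengths[t.transcript_id],
                        total,
                    )
                    for t in transcripts
                ]
            )
        r2_rows.append(
            {
                "sample": sample,
                "stage": stage,
                "r_squared": replicate_agreement(vectors[0], vectors[1]),
            }
        )
    result.replicate_r2 = pd.DataFrame(r2_rows)
    r2_path = os.path.join(config.outdir, "replicate_r2.tsv")
    result.replicate_r2.to_csv(r2_path, sep="\t", index=False)
    result.outputs["replicate_r2"] = r2_path

    # --- manifest ---------------------------------------------------------
    from asepipe import __version__

    inputs = {config.annotation: _sha256(config.annotation)}
    for sample in SAMPLES:
        for stage in STAGES:
            for path in config.sam[sample][stage]:
                inputs[path] = _sha256(path)
    manifest = {
        "asepipe_version": __version__,
        "thresholds": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if not isinstance(v, (dict, list)) and k not in ("annotation", "outdir")
        },
        "inputs": inputs,
        "outputs": sorted(result.outputs.values()),
    }
    manifest_path = os.path.join(config.outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    result.outputs["manifest"] = manifest_path
    return result
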
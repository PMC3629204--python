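import pytest

from asepipe.annotation_io import PileupColumn, SampleLibrary, build_pileups
from asepipe.pipeline import PipelineConfig, run_pipeline
from asepipe.synthetic_data import SimulationConfig, generate_dataset

STAGES = ("tillering", "heading")
SAMPLES = ("parent1", "parent2", "hybrid")


def column(chrom="chr1", pos=100, other=0, **base_counts) -> PileupColumn:
    col = PileupColumn(chrom=chrom, pos=pos, other_count=other)
    for base, n in base_counts.items():
        col.counts[base] = n
    return col


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory):
    """Default-condition synthetic dataset, shared across the session."""
    outdir = tmp_path_factory.mktemp("simdata")
    config = SimulationConfig(seed=1)
    paths = generate_dataset(config, outdir)
    paths["config"] = config
    return paths


@pytest.fixture(scope="session")
def pipeline_run(sim_dataset, tmp_path_factory):
    """Full pipeline run on the shared synthetic dataset."""
    outdir = tmp_path_factory.mktemp("pipeline_out")
    config = PipelineConfig(
        annotation=sim_dataset["annotation"],
        sam={
            sample: {stage: sim_dataset["sam"][(sample, stage)] for stage in STAGES}
            for sample in SAMPLES
        },
        outdir=str(outdir),
    )
    result = run_pipeline(config)
    return {"config": config, "result": result, "dataset": sim_dataset}


@pytest.fixture(scope="session")
def parental_pileups(sim_dataset):
    """Per-stage parental pileups from the shared dataset."""
    out = {}
    for sample in ("parent1", "parent2"):
        out[sample] = {}
        for stage in STAGES:
            lib = SampleLibrary(f"{sample}.{stage}", sample, stage)
            out[sample][stage] = build_pileups(
                sim_dataset["sam"][(sample, stage)],
                sim_dataset["transcripts"],
                lib,
            ).columns
    return out
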
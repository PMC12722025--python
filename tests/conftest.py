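import numpy as np
import pytest

from ibrkit.pipeline import PipelineConfig, run_pipeline
from ibrkit.simulate import SimConfig, SimData, simulate


@pytest.fixture(scope="session")
def sim() -> SimData:
    """Default-condition synthetic dataset shared across the suite."""
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def sim_dir(sim, tmp_path_factory):
    """The same dataset written to disk (GTF/FASTA/BED/TSV)."""
    out = tmp_path_factory.mktemp("simdata")
    sim.write(out)
    return out


@pytest.fixture(scope="session")
def pipeline_result(sim, sim_dir):
    """Full pipeline run on the shared synthetic dataset."""
    cfg = PipelineConfig(
        gtf=sim_dir / "genes.gtf",
        regions_bed=sim_dir / "regions.bed",
        gene_counts=sim_dir / "gene_counts.tsv",
        region_counts=sim_dir / "region_counts.tsv",
        seed=11,
    )
    return run_pipeline(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
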
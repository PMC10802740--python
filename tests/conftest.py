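import pytest

from csefinder.pipeline import PipelineParams, run_pipeline, simulate_scenario
from csefinder.synthetic import (
    AlignmentConfig,
    CohortConfig,
    GeneModelConfig,
    generate_alignments,
    generate_gene_models,
)

SCENARIO_SEED = 11


@pytest.fixture(scope="session")
def models30():
    return generate_gene_models(GeneModelConfig(n_genes=30), seed=7)


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced but fully featured synthetic study (fast)."""
    cfg = CohortConfig(n_planted_gene_level=5, n_planted_as=2)
    return simulate_scenario(seed=5, model_config=GeneModelConfig(n_genes=60), cohort_config=cfg)


@pytest.fixture(scope="session")
def small_run(small_scenario):
    return run_pipeline(small_scenario, PipelineParams(seed=5))


@pytest.fixture(scope="session")
def default_scenario():
    """The default study conditions: 200 genes, 20 gene-level + 5 AS planted."""
    return simulate_scenario(seed=SCENARIO_SEED)


@pytest.fixture(scope="session")
def default_run(default_scenario):
    return run_pipeline(default_scenario, PipelineParams(seed=SCENARIO_SEED))


@pytest.fixture(scope="session")
def sam_fixture(tmp_path_factory, models30):
    path = tmp_path_factory.mktemp("sam") / "sample.sam"
    sam, truth = generate_alignments(models30, AlignmentConfig(), seed=3, out_path=path)
    return path, truth
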
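import numpy as np
import pytest

from promdiver.pipeline import PipelineInputs
from promdiver.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A small but complete synthetic bundle shared across tests."""
    outdir = tmp_path_factory.mktemp("small_cohort")
    config = SyntheticConfig(seed=11, class_sizes=(120, 90, 70, 50), n_datasets=40)
    paths = generate_cohort(config, outdir)
    return config, paths


def inputs_from(paths) -> PipelineInputs:
    return PipelineInputs(
        tss=paths.tss,
        de_matrix=paths.de_matrix,
        gene_models=paths.gene_models,
        disease=paths.disease,
        driver=paths.driver,
        duplicate=paths.duplicate,
        singleton=paths.singleton,
        edges=paths.edges,
    )
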
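import numpy as np
import pytest

from accowave.pipeline import PipelineConfig, run_pipeline
from accowave.population import PopulationSpec, generate_population


@pytest.fixture(scope="session")
def mini_cohort():
    """Deterministic 20-subject raw cohort (the worked reference fixture)."""
    return generate_population(PopulationSpec(n_subjects=20, seed=42))


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full default pipeline run (191 subjects, 1000 generated), shared.

    Session-scoped because the simulate->preprocess->PCA->EM->generate->
    validate chain is the object under test for several modules.
    """
    out = tmp_path_factory.mktemp("pipeline")
    return run_pipeline(PipelineConfig(seed=7, output_dir=str(out / "run")))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
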
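import pytest

from socsafety.fixtures import write_fixture_small
from socsafety.pipeline import InputPaths, PipelineConfig, run_pipeline
from socsafety.simulate import Enrichment, SimulationConfig, simulate_corpus
from socsafety.vocab import load_soc_vocabulary


@pytest.fixture(scope="session")
def vocab():
    return load_soc_vocabulary()


@pytest.fixture()
def micro_paths(tmp_path):
    """The hand-checkable 16-report micro-corpus."""
    return write_fixture_small(tmp_path / "micro")


def pipeline_config_for(paths) -> PipelineConfig:
    return PipelineConfig(
        inputs=InputPaths(
            trials=str(paths["trials"]),
            demo=str(paths["demo"]),
            drug=str(paths["drug"]),
            reac=str(paths["reac"]),
            dictionary=str(paths["dictionary"]),
            lexicon=str(paths["lexicon"]),
        )
    )


@pytest.fixture()
def micro_result(micro_paths):
    return run_pipeline(pipeline_config_for(micro_paths))


@pytest.fixture(scope="session")
def sim_corpus(tmp_path_factory):
    """A mid-size synthetic corpus with corruption and one planted signal."""
    out = tmp_path_factory.mktemp("corpus")
    config = SimulationConfig(
        n_drugs=10,
        n_reports_per_drug=120,
        duplicate_rate=0.06,
        incomplete_rate=0.04,
        enrichments=[Enrichment(drug_id="D004", soc_code="RENAL", factor=6.0)],
        seed=20210603 % (2**31),
    )
    return simulate_corpus(config, out)


@pytest.fixture(scope="session")
def sim_result(sim_corpus):
    return run_pipeline(pipeline_config_for(sim_corpus.paths))
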
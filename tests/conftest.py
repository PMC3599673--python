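from pathlib import Path

import pytest

from condl.pipeline import PipelineConfig, run_pipeline
from condl.synthetic import FixtureConfig, generate

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """The default seed-42 synthetic bundle (200 docs, 30 genes, 5 vaccines)."""
    out = tmp_path_factory.mktemp("bundle")
    return generate(FixtureConfig(seed=42), out)


@pytest.fixture(scope="session")
def pipeline_result(bundle, tmp_path_factory):
    """A full pipeline run over the seed-42 bundle."""
    run_dir = tmp_path_factory.mktemp("run")
    config = PipelineConfig(
        corpus=bundle.corpus,
        lexicon=bundle.lexicon,
        obo=bundle.obo,
        keywords=bundle.keywords,
        conllu=bundle.conllu,
        labeled_paths=bundle.labeled_paths,
        gmt=bundle.gmt,
        ppi=bundle.ppi,
    )
    return run_pipeline(config, run_dir)
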
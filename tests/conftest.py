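import numpy as np
import pytest

from loopamp.classify import KmerBackgroundIndex
from loopamp.io import PipelineConfig
from loopamp.simulate import (
    DEMO_ADAPTER,
    SimulationConfig,
    background_contig,
    demo_assay,
    simulate_run,
)


@pytest.fixture(scope="session")
def assay():
    return demo_assay("synthetic")


@pytest.fixture(scope="session")
def h3f3a_assay():
    return demo_assay("h3f3a")


@pytest.fixture(scope="session")
def grammar(assay):
    from loopamp.assay import build_grammar

    return build_grammar(assay)


@pytest.fixture(scope="session")
def bg_index():
    return KmerBackgroundIndex({"bg1": background_contig()})


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def pipeline_config(**kwargs) -> PipelineConfig:
    kwargs.setdefault("adapters", (DEMO_ADAPTER,))
    kwargs.setdefault("seed", 1)
    return PipelineConfig(**kwargs)


@pytest.fixture(scope="session")
def big_run(assay):
    """2000-read mixed library at 7% aggregate error, true VAF 0.554."""
    cfg = SimulationConfig(
        assay=assay, n_reads=2000, true_vaf=0.554, seed=123,
        sub_rate=0.03, ins_rate=0.02, del_rate=0.02,
    )
    return simulate_run(cfg)


@pytest.fixture(scope="session")
def clean_run(assay):
    """600-read error-free library, true VAF 0.554."""
    cfg = SimulationConfig(
        assay=assay, n_reads=600, true_vaf=0.554, seed=321,
        sub_rate=0.0, ins_rate=0.0, del_rate=0.0,
    )
    return simulate_run(cfg)


def run_through_pipeline(run, assay, bg_index=None, **cfg_kwargs):
    from loopamp.io import Pipeline, ReadRecord

    pipe = Pipeline(assay, pipeline_config(**cfg_kwargs), background_index=bg_index)
    for r in run.reads:
        pipe.process_read(
            ReadRecord(r.read_id, r.sequence, "I" * len(r.sequence), r.start_time)
        )
    return pipe
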
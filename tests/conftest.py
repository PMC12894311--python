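import numpy as np
import pytest

import soymaturity as sm
from soymaturity import synthetic as syn
from soymaturity.evaluation import _split_scenario


@pytest.fixture(scope="session")
def standard_frame():
    """Filtered plot-sample table of the standard shifted scenario."""
    frame = syn.generate_scenario(syn.standard_scenario(seed=1))
    return sm.filter_by_rmd(frame)


@pytest.fixture(scope="session")
def standard_splits(standard_frame):
    return _split_scenario(standard_frame, seed=0)


@pytest.fixture(scope="session")
def pretrained(standard_splits):
    """Source-trained baseline shared across training/evaluation tests."""
    src, _ = standard_splits
    return sm.pretrain(src.train, config=sm.TrainingConfig(seed=0, eval_every=1000))


@pytest.fixture(scope="session")
def tiny_frame():
    """A small two-domain table for fast structural tests."""
    spec = syn.ScenarioSpec(
        source_domains=[
            syn.DomainSpec(domain_id="src", trial="S", year=2019, n_plots=120,
                           check_fraction=0.1)
        ],
        target_domains=[
            syn.DomainSpec(domain_id="tgt", trial="T", year=2020, n_plots=100,
                           check_fraction=0.1)
        ],
        seed=7,
    )
    return sm.filter_by_rmd(syn.generate_scenario(spec))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
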
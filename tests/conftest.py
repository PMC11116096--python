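import logging

import pytest

import pubertyage as pa

logging.getLogger("pubertyage").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """200-observation cohort: 100 singleton families, 2 waves, no missing."""
    cfg = pa.GeneratorConfig(
        n_families=100, sibling_prob=0.0, n_waves=2, missing_rate=0.0, seed=1
    )
    return pa.generate_cohort(cfg)


@pytest.fixture(scope="session")
def medium_prepared():
    """Preprocessed, stratified cohort with TD partition (shared, read-only)."""
    cfg = pa.GeneratorConfig(n_families=1200, n_waves=2, sibling_prob=0.1, seed=7)
    cohort = pa.generate_cohort(cfg)
    strat, part = pa.preprocessing.preprocess(cohort, seed=11)
    return cohort, strat, part
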
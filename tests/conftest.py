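import numpy as np
import pytest

from bactaging import LineageSimConfig, analyze_cohort, simulate_cohort


@pytest.fixture(scope="session")
def default_config():
    return LineageSimConfig()


@pytest.fixture(scope="session")
def cohort500(default_config):
    """500-cell cohort at the default study conditions (shared, read-only)."""
    traces, truths = simulate_cohort(default_config, 500, seed=501)
    return traces, truths


@pytest.fixture(scope="session")
def cohort2000(default_config):
    """2000-cell cohort for phenotype-fraction recovery (shared, read-only)."""
    traces, truths = simulate_cohort(default_config, 2000, seed=2001)
    return traces, truths


@pytest.fixture(scope="session")
def analyzed2000(cohort2000):
    traces, truths = cohort2000
    records, extractions = analyze_cohort(traces)
    return records, extractions, truths
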
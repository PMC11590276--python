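import pytest

from ckdcost import SimConfig, generate_cost_catalog
from ckdcost.pipeline import run_pipeline


@pytest.fixture(scope="session")
def default_catalog():
    return generate_cost_catalog(SimConfig(n_persons=10))


@pytest.fixture(scope="session")
def pipeline_result():
    """Full-size synthetic run with observed (unmodelled) costs.

    Used for the generator→staging→matching→attribution contract checks,
    where the quantity of interest is the recovery of the configured
    component means.
    """
    return run_pipeline(SimConfig(n_persons=10_000, seed=11), use_cost_models=False)


@pytest.fixture(scope="session")
def pipeline_result_modelled():
    """Moderate-size run exercising the GLM cost-transfer route."""
    return run_pipeline(SimConfig(n_persons=4_000, seed=12), use_cost_models=True)
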
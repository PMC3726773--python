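import pytest

from somatrio.casestudy import build_case_study
from somatrio.pipeline import run_trio
from somatrio.simulate import SimConfig, simulate_trio


@pytest.fixture(scope="session")
def case():
    return build_case_study()


@pytest.fixture(scope="session")
def case_result(case):
    return run_trio(case.reference, case.evidence, case.models)


@pytest.fixture(scope="session")
def sim_trio():
    """One seeded synthetic trio at study conditions (VAF floor 0.15)."""
    config = SimConfig(seed=0, vaf_range=(0.15, 0.47))
    reference, truth, evidence = simulate_trio(config)
    return config, reference, truth, evidence


@pytest.fixture(scope="session")
def sim_result(sim_trio):
    _, reference, _, evidence = sim_trio
    return run_trio(reference, evidence, [])
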
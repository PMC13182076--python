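import pytest

from rdnascan.pipeline import run_full
from rdnascan.plan import default_plan
from rdnascan.synth import build_chromosome


@pytest.fixture(scope="session")
def plan():
    return default_plan()


@pytest.fixture(scope="session")
def chrom_truth(plan):
    return build_chromosome(plan, 1)


@pytest.fixture(scope="session")
def full_run(plan):
    """The default end-to-end experiment at seed 1, shared across tests."""
    return run_full(plan, 1)
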
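import pytest

from gffaudit.fixtures import FixtureSpec, generate_fixture
from gffaudit.pipeline import run_audit


@pytest.fixture(scope="session")
def fixture1():
    """One-of-every-category planted fixture (seed 1)."""
    return generate_fixture(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def audit1(fixture1):
    """Full audit of the seed-1 fixture."""
    return run_audit(
        fixture1.genome, fixture1.aset, fixture1.junctions, fixture1.editing_sites
    )
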
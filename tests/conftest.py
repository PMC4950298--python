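import pytest

from wolbsweep import synth
from wolbsweep.model import CytotypeState, ModelParams


@pytest.fixture(scope="session")
def fixtures():
    """Bundled survey tables reproducing the published stratum counts."""
    return synth.paper_fixtures()


@pytest.fixture(scope="session")
def founder():
    """Default initial state: rare HT2-linked doubly infected founder."""
    return CytotypeState.founder(0.01)


@pytest.fixture(scope="session")
def scenario_params():
    return {
        "paternal": ModelParams.paternal_transmission(),
        "heritable": ModelParams.heritable_horizontal(),
        "somatic": ModelParams.somatic_horizontal(),
    }


@pytest.fixture(scope="session")
def amplicon_pair():
    """Synthetic HT1/HT2-like amplicons (one transition apart)."""
    return synth.generate_fixture_amplicons(seed=0)
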
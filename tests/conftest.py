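import pytest

from argus_cua import StructureConfig, default_table1
from argus_cua.markov import resolve_parameters
from argus_cua.parameters import PARAM_NAMES, DistributionSpec, Param


def all_fixed(ps):
    """Degenerate uncertainty: every spec collapsed onto its working value."""
    updates = {}
    for name in PARAM_NAMES:
        v = float(getattr(ps, name))
        updates[name] = Param(v, DistributionSpec("fixed", v, v, v))
    return ps.replace(**updates)


@pytest.fixture(scope="session")
def table1():
    """Published parameter set, printed values verbatim."""
    return default_table1()


@pytest.fixture(scope="session")
def structure():
    """The calibrated default structure."""
    return StructureConfig()


@pytest.fixture(scope="session")
def working(table1, structure):
    """Parameter set with the calibrated working values resolved."""
    return resolve_parameters(table1, structure)
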
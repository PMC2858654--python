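import numpy as np
import pytest

from raoeb.coalsim import SampleConfig
from raoeb.priors import PriorSet, PriorSpec, default_table2_priors
from raoeb.synthetic_data import make_fixture, table3_draw


@pytest.fixture(scope="session")
def toy4():
    return make_fixture("toy4")


@pytest.fixture(scope="session")
def two_pop():
    return make_fixture("two_pop_fst")


@pytest.fixture(scope="session")
def table2():
    return default_table2_priors()


@pytest.fixture(scope="session")
def small_samples():
    """A down-scaled panel for simulation-heavy tests."""
    return SampleConfig((("AFR", 15), ("EUR", 8), ("EAS", 8)))


def fixed_priors(draw, **overrides):
    """A PriorSet pinning every drawable parameter to one draw's values."""
    base = default_table2_priors()
    specs = []
    for name, spec in base.specs.items():
        if spec.kind == "composite":
            specs.append(spec)
        else:
            value = overrides.get(name, getattr(draw, name))
            specs.append(PriorSpec(name, "fixed", value=float(value),
                                   units=spec.units))
    return PriorSet(specs)


@pytest.fixture(scope="session")
def table3_fixed_priors():
    return fixed_priors(table3_draw())
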
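import numpy as np
import pytest

from mitoclock import get_model, table1_parameters


@pytest.fixture(scope="session")
def p1():
    return table1_parameters(1)


@pytest.fixture(scope="session")
def p2():
    return table1_parameters(2)


@pytest.fixture(scope="session")
def p3():
    return table1_parameters(3)


@pytest.fixture(scope="session")
def p4():
    return table1_parameters(4)


@pytest.fixture(scope="session")
def m1():
    return get_model("model1")


@pytest.fixture(scope="session")
def m2():
    return get_model("model2")


@pytest.fixture(scope="session")
def m3():
    return get_model("model3")


@pytest.fixture(scope="session")
def m4():
    return get_model("model4")


def random_state(model, params, rng):
    """A random state inside the physical box of a model."""
    hi = []
    totals = dict(model.conservation)
    for name in model.state_names:
        if name in totals:
            hi.append(getattr(params, totals[name]))
        else:
            hi.append(2.0)
    x = rng.uniform(0.0, 1.0, len(hi)) * np.asarray(hi)
    names = model.state_names
    if "APCPC20" in names:   # Cdc20 binds phospho-APC only
        i_c, i_a = names.index("APCPC20"), names.index("APCP")
        x[i_c] = min(x[i_c], x[i_a])
    if "CycBT" in names:     # active MPF is part of the total cyclin pool
        i_m, i_b = names.index("MPF"), names.index("CycBT")
        x[i_m] = min(x[i_m], x[i_b])
    return x
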
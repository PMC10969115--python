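import pytest

from unionpid import make_distribution


@pytest.fixture(scope="session")
def xor():
    return make_distribution("XOR")


@pytest.fixture(scope="session")
def and_dist():
    return make_distribution("AND")


@pytest.fixture(scope="session")
def copy_dist():
    return make_distribution("COPY")


@pytest.fixture(scope="session")
def tweaked_copy():
    return make_distribution("TWEAKED_COPY")


@pytest.fixture(scope="session")
def boom():
    return make_distribution("BOOM")


@pytest.fixture(scope="session")
def t_eq_y1():
    return make_distribution("T_EQ_Y1")
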
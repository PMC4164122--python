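import pytest

from pulmodpm import build_human_lung, build_sheep_lung, make_fixture_lung


@pytest.fixture(scope="session")
def human():
    return build_human_lung(70.0)


@pytest.fixture(scope="session")
def sheep():
    return build_sheep_lung(40.0)


@pytest.fixture()
def one_segment_lung():
    return make_fixture_lung(1)


@pytest.fixture()
def two_segment_lung():
    return make_fixture_lung(2, symmetric=False, heights=[0.0, 100.0])
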
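import pytest

from mhckit import fixture_catalog, fixture_pool
from mhckit.strtyping import build_str_maps


@pytest.fixture(scope="session")
def pool():
    return fixture_pool()


@pytest.fixture(scope="session")
def catalog():
    return fixture_catalog()


@pytest.fixture(scope="session")
def str_maps(pool):
    return build_str_maps(pool)
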
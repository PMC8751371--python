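import pytest

from ecpdx.core import default_genome, mini_genome
from ecpdx.signatures import synthetic_cosmic_v2_like_catalog


@pytest.fixture(scope="session")
def genome():
    return default_genome()


@pytest.fixture(scope="session")
def small_genome():
    # 3 chromosomes x 200 Mb, centromere mid at 100 Mb
    return mini_genome(n_chroms=3, length_bp=200_000_000)


@pytest.fixture(scope="session")
def sig_catalog():
    return synthetic_cosmic_v2_like_catalog()
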
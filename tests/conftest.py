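import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from enhins.simulate import make_genome


@pytest.fixture(scope="session")
def genome5k():
    return make_genome(11, 1, [5000])


@pytest.fixture(scope="session")
def genome2k():
    return make_genome(13, 1, [2000])


@pytest.fixture(scope="session")
def genome2chrom():
    return make_genome(17, 2, [3000, 2500])
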
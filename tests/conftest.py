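import pytest

from abcoal import LocusConfig


@pytest.fixture(scope="session")
def locus_cfg():
    return LocusConfig(nA=16, nB=16)
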
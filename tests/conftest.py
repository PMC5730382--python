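import pytest

from slamkit.codon import load_dmel_usage


@pytest.fixture(scope="session")
def usage():
    """The shipped D. melanogaster codon-usage table."""
    return load_dmel_usage()
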
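import warnings

import pytest
from hypothesis import HealthCheck, settings

from phagemosaic.io import GenomeRecord

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(autouse=True)
def _quiet_size_warnings():
    # ORF-size divisibility warnings are informational noise in most tests
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*not divisible by 3")
        yield


@pytest.fixture
def toy_trio():
    """12 bp gapless trio with one informative site for each parent."""
    return (
        GenomeRecord("A", "ACGTACGTACGT"),
        GenomeRecord("B", "ACTTACGAACGT"),
        GenomeRecord("R", "ACTTACGTACGT"),
    )
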
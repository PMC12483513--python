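import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rdnscan.panel import load_reference_panel

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_panel():
    return load_reference_panel()


@pytest.fixture(scope="session")
def focal_panel(ref_panel):
    return ref_panel.focal_subset()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def write_fastq(path, reads):
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
    return path
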
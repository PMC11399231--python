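import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from codonlens.seqcore import CODONS, STANDARD_CODE

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SENSE_CODONS = sorted(c for c in CODONS if STANDARD_CODE.table[c] != "*")


def random_cds_string(rng: np.random.Generator, n_codons: int) -> str:
    """A random stop-free frame-valid CDS (helper for many tests)."""
    idx = rng.integers(len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


@pytest.fixture
def rng():
    return np.random.default_rng(20240830)
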
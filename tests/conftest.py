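import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from paleocattle.seqio import AlignedSeqSet, CircularReference, RegionSpec


def make_alignment(rows: dict[str, str], start: int = 1) -> AlignedSeqSet:
    """Alignment over a linear toy reference with columns start..start+L-1."""
    length = len(next(iter(rows.values())))
    ref = CircularReference("toy", start + length + 10)
    region = RegionSpec(start, start + length - 1, ref)
    return AlignedSeqSet(list(rows), region.positions(), list(rows.values()))


@pytest.fixture
def aln_factory():
    return make_alignment


@pytest.fixture
def rng():
    return np.random.default_rng(20230423)
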
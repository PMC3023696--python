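import math

import numpy as np
import pytest
from hypothesis import settings

from ssdraw.fixtures import FixtureSpec, generate_fixture
from ssdraw.junction_solver import JunctionSpec, StemSpec

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def hairpin_aln():
    return generate_fixture(FixtureSpec(template="hairpin", n_seqs=6, seed=11))


@pytest.fixture
def toy_stockholm():
    return (
        "# STOCKHOLM 1.0\n"
        "seqA  GGGAAAACCC\n"
        "seqB  GGGAAAACCC\n"
        "#=GC SS_cons  <<<....>>>\n"
        "//\n"
    )


def symmetric_junction_spec(
    n_stems: int = 4, n_unpaired: int = 3, d_bp: float = 1.6
) -> JunctionSpec:
    """A junction whose stems sit at the symmetric compass directions.

    The enclosing stem enters from below (pointing up into the junction);
    the remaining stems leave outward at equally spaced angles in
    clockwise walk order.
    """
    outward = [(270.0 - 360.0 * (k + 1) / n_stems) % 360.0 for k in range(n_stems - 1)]
    segments = [
        [("nt", 100 + 10 * i + k) for k in range(n_unpaired)] for i in range(n_stems)
    ]
    return JunctionSpec(
        q5=np.array([0.0, 0.0]),
        q3=np.array([d_bp, 0.0]),
        enclosing_dir=math.pi / 2.0,
        stems=[StemSpec(math.radians(d)) for d in outward],
        segments=segments,
        d_bp=d_bp,
    )
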
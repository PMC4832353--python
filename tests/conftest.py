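import numpy as np
import pytest

from cnsfoot import ScoringScheme, solve_karlin_altschul


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def default_scheme() -> ScoringScheme:
    """Solved default scoring scheme (+1/-2/-5/-2, uniform background)."""
    return solve_karlin_altschul(ScoringScheme())
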
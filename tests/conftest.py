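import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ncakit import ConnectivityPattern

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_valid_pattern(seed: int, max_m: int = 8, max_p: int = 4,
                         cover_genes: bool = False) -> ConnectivityPattern:
    """A random valid connectivity pattern (every TF has >= 1 target).

    With ``cover_genes`` every gene also has >= 1 regulator, which is what
    the SIF edge-list format can represent.
    """
    rng = np.random.default_rng(seed)
    m = int(rng.integers(2, max_m + 1))
    p = int(rng.integers(1, min(max_p, m) + 1))
    entries = rng.choice([-1, 0, 0, 1], size=(m, p)).astype(np.int8)
    for j in range(p):
        if not entries[:, j].any():
            entries[rng.integers(m), j] = 1
    if cover_genes:
        for i in range(m):
            if not entries[i].any():
                entries[i, rng.integers(p)] = 1
    known = np.ones((m, p), dtype=bool)
    unknown = (entries == 1) & (rng.random((m, p)) < 0.3)
    known[unknown] = False
    return ConnectivityPattern(
        tuple(f"g{i}" for i in range(m)),
        tuple(f"t{j}" for j in range(p)),
        entries, known)


@pytest.fixture
def block_pattern():
    """p=2 disjoint regulons of two genes each: compliant for any n >= 1."""
    entries = np.array([[1, 0], [1, 0], [0, 1], [0, -1]], dtype=np.int8)
    return ConnectivityPattern(("g1", "g2", "g3", "g4"), ("tA", "tB"), entries)
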
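import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=150,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20230528)


def random_g_enriched(rng, n, p_g=0.35):
    """Random DNA with elevated guanine content (motif-dense regime)."""
    probs = np.array([0.22, 0.20, p_g, 1.0 - 0.42 - p_g])
    cum = np.cumsum(probs)
    bases = np.array(list("ACGT"))
    return "".join(bases[np.searchsorted(cum, rng.random(n))])
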
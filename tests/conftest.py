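import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from skbio.stats.distance import DistanceMatrix

from galtonlex import SimulationConfig, Wordlist, make_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def toy_pair():
    """The two-variety worked example: LDN 0.25, LDND 0.25."""
    w1 = Wordlist("w1", {"c1": [("aa", None)], "c2": [("bb", None)]})
    w2 = Wordlist("w2", {"c1": [("aa", None)], "c2": [("bc", None)]})
    return w1, w2


@pytest.fixture
def coded_trio():
    """Three cognate-coded wordlists with hand-countable codings."""

    def wl(vid, codes):
        return Wordlist(
            vid,
            {
                f"c{i}": [(f"w{vid}{i}", code)]
                for i, code in enumerate(codes, start=1)
            },
        )

    # shared-class pattern: a-b intersect on c1,c2 (2/3); a-c on c1 (1/3);
    # b-c on c1,c3 (2/3)
    a = wl("a", ["k1", "k2", "k3"])
    b = wl("b", ["k1", "k2", "k9"])
    c = wl("c", ["k1", "k8", "k9"])
    return a, b, c


def random_distance_matrix(n, rng, labels=None):
    """Random symmetric hollow matrix with iid uniform off-diagonals."""
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = rng.uniform(size=len(iu[0]))
    m += m.T
    if labels is None:
        labels = [f"l{i}" for i in range(n)]
    return DistanceMatrix(m, labels)


@pytest.fixture
def small_dataset():
    """One small simulated study reused across integration tests."""
    return make_dataset(
        SimulationConfig(n_varieties=12, n_concepts=30, n_groups=4, seed=11)
    )
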
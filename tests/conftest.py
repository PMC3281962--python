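import numpy as np
import pytest
from hypothesis import settings

import uniblue as ub

# deterministic property-test runs (no example database, no shrinking races)
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def noise_free_config():
    """Simulator settings with exact ladder peaks and no noise."""
    return ub.SimConfig(seed=0, mz_jitter_sd=0.0, n_noise_peaks=0)


@pytest.fixture
def wide_window_config():
    """Noise-free settings with an effectively unrestricted m/z window, so
    every theoretical fragment is observable."""
    return ub.SimConfig(seed=0, mz_jitter_sd=0.0, n_noise_peaks=0,
                        scan_range=(1.0, 100000.0))


def random_peptide(rng, min_len=1, max_len=30):
    alphabet = sorted("ACDEFGHIKLMNPQRSTVWY")
    n = int(rng.integers(min_len, max_len + 1))
    return "".join(rng.choice(alphabet) for _ in range(n))


def random_modform(rng, min_len=2, max_len=25):
    """Random peptide with Uniblue A on a random subset of lysines and
    carbamidomethyl on all cysteines."""
    seq = random_peptide(rng, min_len, max_len)
    sites = {}
    for pos, aa in enumerate(seq, start=1):
        if aa == "K" and rng.random() < 0.5:
            sites[pos] = ub.UNIBLUE_A
        elif aa == "C":
            sites[pos] = ub.CARBAMIDOMETHYL_C
    return ub.Modform(seq, sites)
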
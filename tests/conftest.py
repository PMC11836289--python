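import numpy as np
import pytest

from vocevo import sfs as sfsmod
from vocevo import synthetic as syn


@pytest.fixture(scope="session")
def neutral_ensemble():
    """Shared conditioned neutral null (n=20, S=30)."""
    return sfsmod.simulate_neutral_sfs(20, 30, 2000, seed=11)


@pytest.fixture(scope="session")
def small_recording():
    """Synthetic recording with 40 planted syllables at 20 dB SNR."""
    plan = syn.random_plan(40, seed=3, snr_db=20.0)
    samples, rate, truth = syn.gen_usv_recording(plan)
    return samples, rate, truth


def random_spectrum(rng, n=None, max_sites=40):
    """Random unfolded SFS with at least 2 segregating sites."""
    if n is None:
        n = int(rng.integers(4, 30))
    xi = rng.integers(0, 6, size=n - 1).astype(float)
    if xi.sum() < 2:
        xi[int(rng.integers(0, n - 1))] += 2
    return sfsmod.FrequencySpectrum(n=n, xi=xi)
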
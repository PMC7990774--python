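import numpy as np
import pytest

from baraug import EpochSet, Montage, build_split


@pytest.fixture
def montage4():
    return Montage(("C3", "C4", "Fz", "Pz"))


@pytest.fixture
def split4(montage4):
    # parity puts C3 left / C4 right; Fz, Pz alternate LEFT, RIGHT
    return build_split(montage4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_epochs(rng, n_per_class=10, n_channels=4, n_samples=50, fs=100.0, subject=None):
    names = ("C3", "C4", "Fz", "Pz") if n_channels == 4 else tuple(f"C{2 * i + 1}" for i in range(n_channels))
    n = 2 * n_per_class
    return EpochSet(
        data=rng.standard_normal((n, n_channels, n_samples)),
        labels=np.repeat([0, 1], n_per_class),
        channel_names=names,
        fs=fs,
        subject=subject,
    )


@pytest.fixture
def epochs10(rng):
    """Balanced 2-class set, 10 trials per class, 4 channels."""
    return random_epochs(rng)
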
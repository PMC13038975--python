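import numpy as np
import pytest

from polarstates.data_model import EpochSet, Montage, TemplateSet
from polarstates.templates import expand_polarity


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def montage4():
    return Montage(("c1", "c2", "c3", "c4"))


@pytest.fixture
def base3(montage4):
    """Three mutually orthogonal zero-mean unit-norm maps on 4 channels."""
    maps = np.array([
        [1.0, -1.0, 1.0, -1.0],
        [1.0, 1.0, -1.0, -1.0],
        [1.0, -1.0, -1.0, 1.0],
    ]) / 2.0
    return TemplateSet(maps, ("A", "B", "C"), montage4, base_k=3)


@pytest.fixture
def signed3(base3):
    return expand_polarity(base3)


def random_template_set(n_channels: int, base_k: int, seed: int) -> TemplateSet:
    """Random zero-mean unit-norm base maps (not orthogonalized)."""
    r = np.random.default_rng(seed)
    maps = r.standard_normal((base_k, n_channels))
    maps -= maps.mean(axis=1, keepdims=True)
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    names = tuple(chr(ord("A") + i) for i in range(base_k))
    return TemplateSet(maps, names, Montage(tuple(f"ch{i}" for i in range(n_channels))),
                       base_k=base_k)


@pytest.fixture
def tiny_epochs(montage4, rng):
    """10 trials x 4 channels x 100 samples, two classes."""
    data = rng.standard_normal((10, 4, 100))
    classes = np.array(["standard"] * 6 + ["target"] * 4, dtype=object)
    return EpochSet(data, sfreq=100.0, tmin=-0.2, classes=classes, montage=montage4)
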
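import numpy as np
import pytest

from nodulecam import synthetic as syn


@pytest.fixture(scope="session")
def balanced_dataset_100():
    """50 benign + 50 malignant phantoms at full resolution (seeded)."""
    images, manifest = syn.generate_dataset(50, 50, (224, 224), master_seed=7)
    return images, manifest


@pytest.fixture(scope="session")
def small_dataset():
    """Small mixed dataset for fast classifier tests (96x96, seeded)."""
    images, manifest = syn.generate_dataset(20, 20, (96, 96), master_seed=3)
    return images, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def disc_mask(radius: int, pad: int = 6) -> np.ndarray:
    n = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[:n, :n]
    c = radius + pad
    return (yy - c) ** 2 + (xx - c) ** 2 < radius**2


@pytest.fixture(scope="session")
def star_spec():
    """Five-pointed star: amplitude-0.3 harmonic on a circle of radius 60."""
    return syn.NoduleSpec(
        center=(112.0, 112.0), semi_axes=(60.0, 60.0), rotation=0.0,
        perturb_harmonics=(5,), perturb_amplitudes=(0.3,), perturb_phases=(0.0,),
    )
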
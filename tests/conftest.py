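import numpy as np
import pytest

from usborder.metrics import compute_class_weights
from usborder.models import train_small_unet
from usborder.phantom import PhantomSpec, phantom_dataset


@pytest.fixture(scope="session")
def phantom_train_test():
    """Training and held-out phantom sets at the generator's defaults."""
    train = phantom_dataset(32, PhantomSpec(), seed=0)
    test = phantom_dataset(8, PhantomSpec(), seed=999)
    return train, test


@pytest.fixture(scope="session")
def trained_unet(phantom_train_test):
    """A SmallUNet trained once per session on the phantom training set."""
    train, _ = phantom_train_test
    weights = compute_class_weights([c.labels for c in train], 4)
    model, losses = train_small_unet(
        [c.image for c in train], [c.labels for c in train],
        n_classes=4, seed=0, class_weights=weights)
    assert losses[-1] < losses[0]
    return model


def random_label_map(rng, shape, n_classes=3):
    """Random smooth-ish label map with guaranteed nonzero classes."""
    from scipy import ndimage
    field = ndimage.gaussian_filter(rng.normal(size=shape), sigma=3)
    edges_ = np.quantile(field, np.linspace(0, 1, n_classes + 2)[1:-1])
    return np.digitize(field, edges_)
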
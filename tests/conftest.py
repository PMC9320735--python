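"""Shared fixtures: tiny synthetic scenes and helper assertions."""
import numpy as np
import pytest
from scipy import ndimage

from tomseg.synth import SceneParams, generate_dataset, generate_scene


@pytest.fixture(scope="session")
def tiny_params():
    """A 48x64 canvas: big enough for one plant, cheap enough for unit tests."""
    return SceneParams(height=48, width=64, n_stems=1, seed=42)


@pytest.fixture(scope="session")
def tiny_scene(tiny_params):
    return generate_scene(tiny_params)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_params):
    return generate_dataset(5, tiny_params)


def sucker_components_touch_axil(label, reach=2):
    """True iff every sucker component lies within ``reach`` px of both a stem
    and a branch pixel - the axillary-shoot geometry."""
    comp, n = ndimage.label(label == 3, structure=np.ones((3, 3), int))
    size = 2 * reach + 1
    for i in range(1, n + 1):
        grown = ndimage.binary_dilation(comp == i,
                                        structure=np.ones((size, size), bool))
        if not ((label[grown] == 1).any() and (label[grown] == 2).any()):
            return False
    return True
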
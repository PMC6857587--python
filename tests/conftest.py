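import numpy as np
import pytest

from nucpipe import ChannelSpec, HardCore, LabelMask, SceneSpec, make_scene


@pytest.fixture
def small_scene():
    """A compact hard-core scene with one bimodal marker channel."""
    spec = SceneSpec(
        domain_size_um=(20.0, 120.0, 120.0),
        voxel_size_um=(2.0, 1.0, 1.0),
        n_nuclei=60,
        placement=HardCore(10.0),
        nucleus_radii_um=(3.0, 3.5, 3.5),
        radius_jitter=0.1,
        channels=[
            ChannelSpec(
                name="marker",
                positive_fraction=0.5,
                neg_mean=100.0,
                neg_sd=8.0,
                pos_mean=300.0,
                pos_sd=15.0,
                noise_sd=15.0,
            )
        ],
        seed=7,
    )
    mask, stack, truth = make_scene(spec)
    return spec, mask, stack, truth


def make_mask(voxels, voxel_size=(1.0, 1.0, 1.0), **kw):
    return LabelMask(np.asarray(voxels), voxel_size, **kw)
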
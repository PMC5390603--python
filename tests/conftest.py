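import numpy as np
import pytest

from mrupsample import (
    DegradeConfig,
    UpsampleParams,
    baseline_upsample,
    degrade,
    make_phantom,
    upsample_volume,
)

# study conditions of the end-to-end harness: 64^3 phantom, sigma=0.8 blur,
# 2x2x2 block downsampling, default search/regression parameters, stride 2
E2E_SEED = 7
E2E_SHAPE = (64, 64, 64)
E2E_ZOOM = (2, 2, 2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def end_to_end_run():
    """One shared reconstruction of a blurred+downsampled phantom.

    Returns the ground truth, the simulated LR acquisition, the proposed
    reconstruction (stride 2) and the trilinear baseline.
    """
    gt = make_phantom(E2E_SHAPE, seed=E2E_SEED)
    lr = degrade(gt, DegradeConfig(sigma=0.8, factors=E2E_ZOOM, noise_level=0.0))
    hr = upsample_volume(lr, UpsampleParams(stride=2, zoom=E2E_ZOOM))
    tri = baseline_upsample(lr, E2E_ZOOM, order=1)
    return {"gt": gt, "lr": lr, "hr": hr, "tri": tri, "zoom": E2E_ZOOM}
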
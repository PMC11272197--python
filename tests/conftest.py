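import numpy as np
import pytest

from adiposeg.phantom import BlobParams, PhantomSpec, generate_phantom
from adiposeg.segmentation import SegmentationParams, SegmentationResult
from adiposeg.types import MaskStack


def small_phantom_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """A fast 64x64, 6-slice phantom for unit and property tests."""
    kwargs = dict(
        grid_shape=(64, 64),
        n_slices=6,
        pixel_spacing_mm=(3.0, 3.0),
        slice_thickness_mm=10.0,
        torso_semiaxes_mm=(55.0, 80.0),
        sat_ring_thickness_mm=18.0,
        wall_thickness_mm=12.0,
        vat_blob_params=BlobParams(count=4, radius_range_mm=(6.0, 10.0), gap_mm=4.0),
        seed=seed,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = PhantomSpec(seed=11, noise_sigma=0.0, bias_field_amplitude=0.0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = PhantomSpec(seed=12)  # defaults: noise 0.05, bias 0.2
    return generate_phantom(spec)


@pytest.fixture
def handmade_result():
    """A tiny hand-built segmentation result for edit/volumetry unit tests.

    One 40x40 slice repeated 4 times: torso is the 2..37 square, SAT a
    10x10 block, VAT a separate 6x6 block, non-VAT a 4x4 block.
    """
    nz, nr, nc = 4, 40, 40
    torso = np.zeros((nz, nr, nc), bool)
    torso[:, 2:38, 2:38] = True
    sat = np.zeros_like(torso)
    sat[:, 4:14, 4:14] = True
    vat = np.zeros_like(torso)
    vat[:, 20:26, 20:26] = True
    nonvat = np.zeros_like(torso)
    nonvat[:, 30:34, 4:8] = True
    return SegmentationResult(
        sat=MaskStack(sat),
        vat=MaskStack(vat),
        nonvat=MaskStack(nonvat),
        torso=MaskStack(torso),
        params=SegmentationParams(),
    )
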
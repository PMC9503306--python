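import numpy as np
import pytest

from ccfd import EnFaceImage, ScanGeometry


@pytest.fixture
def geom_small() -> ScanGeometry:
    """6 x 6 mm field on a coarse 24 x 24 grid (fast unit fixtures)."""
    return ScanGeometry(6.0, 6.0, 24, 24)


@pytest.fixture
def geom_500() -> ScanGeometry:
    return ScanGeometry(6.0, 6.0, 500, 500)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220914)


def random_image(
    rng: np.random.Generator,
    geometry: ScanGeometry,
    bit_depth: int = 8,
    channel: str = "flow",
) -> EnFaceImage:
    hi = (1 << bit_depth) + 0  # exclusive bound handled below
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    px = rng.integers(0, hi, size=geometry.shape).astype(dtype)
    return EnFaceImage(px, bit_depth, geometry, channel)
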
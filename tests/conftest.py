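import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from sheathkit import synthesis as syn  # noqa: E402

# mask radii used for symmetry searches: 1.1 x sheath outer radius
MASK_RADIUS = {"non_contracted": 1.1 * 120.0, "contracted": 1.1 * 160.0}
TRUTH = {"non_contracted": (20.57, 41.53), "contracted": (27.13, 18.89)}


@pytest.fixture(scope="session")
def nc_map():
    """Noise-free synthetic non-contracted sheath map, 64^3."""
    return syn.simulate_sheath_map("non_contracted", box_voxels=64)


@pytest.fixture(scope="session")
def contracted_map():
    """Noise-free synthetic contracted sheath map, 64^3."""
    return syn.simulate_sheath_map("contracted", box_voxels=64)
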
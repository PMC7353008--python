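import numpy as np
import pytest

from gnpcell import CellModel, DistributionSpec, place_clusters


@pytest.fixture(scope="session")
def cell():
    return CellModel()


@pytest.fixture(scope="session")
def small_clusters(cell):
    """50 perinuclear 200 nm clusters of 100 NPs — shared cheap fixture."""
    spec = DistributionSpec(
        n_clusters=50,
        cluster_diameter_um=0.2,
        n_np_per_cluster=100,
        region="perinuclear",
        shell_width_um=1.0,
        seed=42,
    )
    return place_clusters(spec, cell)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
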
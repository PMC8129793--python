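import numpy as np
import pytest

from bcquant import synthetic


@pytest.fixture
def cluster_spec():
    return synthetic.ClusterSpec(noise_sd=8.0)


@pytest.fixture
def quiet_cluster():
    return synthetic.ClusterSpec(noise_sd=0.0)


@pytest.fixture
def default_protrusions():
    return synthetic.ProtrusionSpec()


@pytest.fixture
def disk_mask():
    """A rasterised disk of radius 30 px in a 101x101 grid."""
    yy, xx = np.mgrid[0:101, 0:101]
    return (xx - 50) ** 2 + (yy - 50) ** 2 <= 30**2
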
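import numpy as np
import pytest
from dataclasses import replace

import voxcast as vc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume():
    """Seeded 2-channel 8^3 blobs volume."""
    return vc.make_synthetic_volume("blobs", dims=(8, 8, 8), num_channels=2, seed=7)


@pytest.fixture
def probe_volume():
    """9^3 volume with a single code-255 voxel at the centre (4,4,4)."""
    return vc.make_synthetic_volume("single_voxel", dims=(9, 9, 9), num_channels=1)


@pytest.fixture
def session_factory():
    def make(vol, viewport=(32, 32)):
        s = vc.Session()
        s.camera = replace(s.camera, viewport=viewport)
        s.set_volume(vol)
        return s

    return make


@pytest.fixture
def http_server():
    """Fresh server on an ephemeral port; torn down after the test."""
    server = vc.start_server(port=0)
    yield server
    server.shutdown()
    server.server_close()


@pytest.fixture
def client(http_server):
    return vc.Client(port=http_server.port, auto_start=False)


def random_rotation(rng):
    """Uniform-ish random rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
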
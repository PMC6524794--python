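import numpy as np
import pytest

import deskmri as dm


@pytest.fixture(scope="session")
def small_gre():
    """16x16 GRE sequence + timelines, shared across tests."""
    g = dm.GlobalParams(matrix_size=16, fov=0.2, receiver_bw=1e5)
    seq = dm.build_gre(g, tr=5e-3)
    table = dm.discretize(seq)
    return {"globals": g, "seq": seq, "table": table,
            "compressed": dm.compress(table)}


@pytest.fixture(scope="session")
def small_disk_phantom():
    return dm.make_cylinder_phantom(0.05, 0.004, 0.012, 0.9, 0.05)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231)
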
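import numpy as np
import pytest

import richclubnet as r


@pytest.fixture(scope="session")
def aal90():
    return r.load_atlas("aal90")


@pytest.fixture
def triangle():
    w = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
    return r.make_connectome(w, subject_id="triangle")


@pytest.fixture
def star_k13():
    w = np.zeros((4, 4))
    w[0, 1:] = 1.0
    w[1:, 0] = 1.0
    return r.make_connectome(w, subject_id="star")


@pytest.fixture
def triangle_with_pendant():
    w = np.zeros((4, 4))
    for i, j in [(0, 1), (0, 2), (1, 2)]:
        w[i, j] = w[j, i] = 1.0
    w[2, 3] = w[3, 2] = 1.0
    return r.make_connectome(w, subject_id="tri_pendant")


@pytest.fixture(scope="session")
def small_template():
    """Connected core-periphery template on 30 nodes (6 rich)."""
    cfg = r.SyntheticConfig(n_nodes=30, n_rich=6, master_seed=42)
    return cfg, r.build_template(cfg)


@pytest.fixture(scope="session")
def tiny_cohort_dir(tmp_path_factory):
    """A small synthetic cohort written to disk in the reader's formats."""
    out = tmp_path_factory.mktemp("cohort")
    cfg = r.SyntheticConfig(n_per_cell=3, n_nodes=30, n_rich=6,
                            master_seed=5)
    r.simulate_cohort(cfg, out_dir=out)
    return out
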
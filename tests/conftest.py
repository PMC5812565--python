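import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import crowddiff as cd


@pytest.fixture
def small_cfg():
    """10x10 lattice at physical step constants."""
    return cd.LatticeConfig.desk(10)


@pytest.fixture
def empty_field(small_cfg):
    return cd.build_obstacle_field(small_cfg, 0.0, 0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_population(cfg, rows, cols, fld, exclusion=True):
    """Hand-built tracer population at explicit sites."""
    rows = np.asarray(rows, dtype=np.int64)
    cols = np.asarray(cols, dtype=np.int64)
    bound = fld.site_kind[rows, cols] == cd.PRO
    return cd.TracerPopulation(
        rows=rows, cols=cols,
        disp_rows=np.zeros(rows.size, dtype=np.int64),
        disp_cols=np.zeros(cols.size, dtype=np.int64),
        bound=bound.astype(np.bool_),
        exclusion=exclusion,
        a_dt=rows.size / cfg.n_sites,
    )
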
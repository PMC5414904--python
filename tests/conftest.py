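import numpy as np
import pytest

from surveygrid import (
    ClusterRecord,
    DesignMatrix,
    GridSpec,
    RasterLayer,
    gen_covariate_fields,
)


@pytest.fixture
def grid50():
    return GridSpec(50, 50, origin_x=0.0, origin_y=50_000.0, cell_size=1000.0)


@pytest.fixture
def stack50(grid50):
    return gen_covariate_fields(grid50, 3, corr_length=5000.0, seed=7)


@pytest.fixture
def ramp_layer():
    """f(x, y) = x / 1000 on a fine 200 m grid spanning 20 km."""
    grid = GridSpec(100, 100, origin_x=0.0, origin_y=20_000.0, cell_size=200.0)
    x, _ = grid.center_mesh()
    return RasterLayer(grid, "ramp", x / 1000.0)


def make_cluster(x, y, stratum="urban", cid="c1", n=25, k=10, **kw):
    return ClusterRecord(
        id=cid,
        true_xy=(x, y),
        reported_xy=(x, y),
        stratum=stratum,
        n_respondents=n,
        n_positive=k,
        **kw,
    )


def make_design(X, names=None, ids=None, **kw):
    X = np.asarray(X, dtype=float)
    names = names or [f"v{j}" for j in range(X.shape[1])]
    ids = ids or [f"c{i}" for i in range(X.shape[0])]
    return DesignMatrix(cluster_ids=ids, covariate_names=names, values=X, **kw)
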
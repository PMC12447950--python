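import numpy as np
import pandas as pd
import pytest
from anndata import AnnData

from regennet import preprocess as pp
from regennet import simulate as sim


@pytest.fixture(scope="session")
def small_study():
    """A compact planted study shared by read-only tests."""
    return sim.simulate_study(n_tfs=10, n_targets=40, hub_out_fraction=0.8,
                              seed=0, n_cells_per_timepoint=30)


@pytest.fixture()
def toy_adata():
    """Hand-built matrix with known QC properties (4 cells x 5 genes)."""
    X = np.array([
        [5, 3, 0, 1, 0],    # 3 genes expressed, no mito
        [0, 0, 0, 0, 0],    # empty cell
        [10, 10, 10, 10, 60],  # mito-heavy (gene mt-a = 60 of 100)
        [2, 2, 2, 0, 1],    # 4 genes expressed, mito 1/7
    ], dtype=float)
    obs = pd.DataFrame({
        "timepoint": [0.0, 1.0, 5.0, 10.0],
        "cell_type": ["central SC"] * 4,
    }, index=[f"c{i}" for i in range(4)])
    var = pd.DataFrame(index=["g1", "g2", "g3", "g4", "mt-a"])
    return AnnData(X=X, obs=obs, var=var)


def scored_study(seed, **kw):
    """Full path up to an edge-score table for a small planted study."""
    from regennet import scoring
    study = sim.simulate_study(n_tfs=kw.pop("n_tfs", 10),
                               n_targets=kw.pop("n_targets", 40),
                               hub_out_fraction=kw.pop("hub_out_fraction", 0.8),
                               seed=seed, **kw)
    adata = study.expression
    pp.normalize(adata)
    traj = pp.assign_pseudotime(adata, pp.subset_trajectory(adata, "SC"))
    table = scoring.score_pairs(traj, adata, study.grn.tfs)
    return study, traj, table
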
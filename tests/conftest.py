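import warnings

import numpy as np
import pytest

import scregflow as sf


@pytest.fixture(scope="session")
def small_fixture():
    """600 cells, 194 genes: the quick dataset for unit tests."""
    return sf.default_fixture(seed=0, n_cells_per_timepoint=100)


@pytest.fixture(scope="session")
def medium_fixture():
    """~2000 cells: the recovery-experiment scale."""
    return sf.default_fixture(seed=0, n_cells_per_timepoint=334)


@pytest.fixture(scope="session")
def medium_activity(medium_fixture):
    """Inferred regulons, AUC activity and RSS on the medium dataset."""
    ds, truth = medium_fixture
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        regs = sf.infer_modules(ds, truth.tfs, min_importance=0.1)
        act = sf.aucell_scores(ds, regs, top_frac=0.05)
        rss = sf.regulon_specificity(act, ds.cell_meta["population"].to_numpy())
    return regs, act, rss


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
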
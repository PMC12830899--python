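import numpy as np
import pytest

import ecdna3d as e
from ecdna3d.matrix import ContactMatrix, ice_normalize_generalized


@pytest.fixture(scope="session")
def small_truth():
    """A 60-bin folded structure with one constriction, no duplication."""
    cfg = e.SimConfig(ne=60, k=1, alpha=-1.2, beta=6.0, seed=3, n_local_folds=6)
    return e.add_local_folds(e.simulate_base_structure(cfg))


@pytest.fixture(scope="session")
def small_system(small_truth):
    """Sampled matrix + binmap + normalized matrix for the 60-bin structure."""
    cfg = small_truth.config
    E = e.sample_hic(small_truth.coords, cfg.alpha, cfg.beta, seed=5)
    binmap = e.binmap_from_duplication_regions(cfg.ne, ())
    C = ContactMatrix(E, kind="collapsed", state="raw",
                      resolution=5000, binmap=binmap)
    N, r = ice_normalize_generalized(C, binmap)
    return {"truth": small_truth, "raw": E, "binmap": binmap,
            "normalized": N.values, "scale_r": r}


@pytest.fixture(scope="session")
def small_fit(small_system):
    cfg = e.FitConfig(n_restarts=1, max_rounds=80)
    return e.fit_structure(small_system["normalized"], small_system["binmap"],
                           cfg, seed=0)


@pytest.fixture(scope="session")
def dup_system():
    """An 80-bin structure with a duplicated region and collapsed matrix."""
    regions = ((10, 8), (50, 8))
    cfg = e.SimConfig(ne=80, k=1, alpha=-1.3, beta=6.0,
                      duplication_regions=regions, seed=11, n_local_folds=8)
    truth = e.add_local_folds(e.simulate_base_structure(cfg))
    E = e.sample_hic(truth.coords, cfg.alpha, cfg.beta, seed=13)
    C, binmap = e.apply_duplication(E, regions)
    return {"truth": truth, "expanded": E, "collapsed": C, "binmap": binmap,
            "regions": regions}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
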
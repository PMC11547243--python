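import numpy as np
import pandas as pd
import pytest

from pdac_cfmethyl.dmr import DmrCriteria
from pdac_cfmethyl.simulate import (SimConfig, generate_cpg_landscape,
                                    plant_dmrs, simulate_tissue_pairs)


@pytest.fixture(scope="session")
def tiny_config():
    """Small but fully-featured simulation config shared by unit tests."""
    return SimConfig(seed=7, n_cpg=6000, n_chrom=2, n_tissue_pairs=12,
                     n_pdac_plasma=40, n_healthy_plasma=40,
                     n_hyper=6, n_hypo=6)


@pytest.fixture(scope="session")
def tiny_tissue(tiny_config):
    landscape = generate_cpg_landscape(tiny_config)
    true_dmrs, profile = plant_dmrs(landscape, tiny_config)
    tumor, nat = simulate_tissue_pairs(landscape, profile, tiny_config)
    return {"landscape": landscape, "true_dmrs": true_dmrs,
            "profile": profile, "tumor": tumor, "nat": nat}


@pytest.fixture()
def criteria():
    return DmrCriteria()


def random_cpg_stats(seed: int, n: int = 50, dm_frac: float = 0.45) -> pd.DataFrame:
    """Random per-CpG stat vector for region-assembly oracle tests."""
    rng = np.random.default_rng(seed)
    pos = np.cumsum(rng.integers(10, 120, size=n)) + 100
    diff = rng.normal(0, 0.25, size=n)
    dm = rng.random(n) < dm_frac
    # make DM CpGs carry a clear sign and magnitude
    diff = np.where(dm, np.sign(diff) * (0.15 + np.abs(diff)), diff * 0.3)
    p = np.where(dm, 0.001, 0.5)
    return pd.DataFrame({
        "chrom": "chr1", "pos": pos, "mu_tumor": 0.5 + diff / 2,
        "mu_nat": 0.5 - diff / 2, "diff": diff,
        "se": 0.05, "z": diff / 0.05, "p": p, "is_dm": dm,
    })
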
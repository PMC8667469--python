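import numpy as np
import pandas as pd
import pytest

from polyqtl.simulate import Chromosome, CrossConfig, simulate_cross


@pytest.fixture(scope="session")
def small_cross():
    """A modest two-chromosome cross with a simplex-class QTL, shared across
    tests that only need *some* realistic simulated data."""
    cfg = CrossConfig(
        n_offspring=120,
        chromosomes=(Chromosome("chr01", 100.0, 150),
                     Chromosome("chr02", 100.0, 150)),
        qtls=(("chr01", 50.0, 0.8),),
        qtl_marker_class=(0, 1),
        depth_model=(45.0, 10.0),
        seed=1234,
    )
    return simulate_cross(cfg)


def make_balanced_obs(effects: dict[str, float], n_blocks: int,
                      sigma_block: float, sigma_e: float, seed: int,
                      mu: float = 0.0, trait: str = "PD") -> pd.DataFrame:
    """Plant-level observation table for a single-batch randomized complete
    block design with known genotype effects on the logit scale."""
    rng = np.random.default_rng(seed)
    rows = []
    for blk in range(1, n_blocks + 1):
        b_eff = rng.normal(0, sigma_block) if sigma_block > 0 else 0.0
        for gid, eff in effects.items():
            latent = mu + eff + b_eff + (rng.normal(0, sigma_e) if sigma_e > 0 else 0.0)
            value = 100.0 / (1.0 + np.exp(-latent))
            rows.append((gid, "test", 1, blk, 1, trait, value))
    return pd.DataFrame(rows, columns=["genotype_id", "genotype_role", "batch",
                                       "block", "plant", "trait", "value_percent"])
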
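import numpy as np
import pandas as pd
import pytest

from alugs import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small but structurally complete study: 60 lines, 4 chromosomes."""
    return SimulationConfig(
        n_lines=60, n_snps=120, n_chromosomes=4,
        n_blocks=8, plots_per_block=11, n_checks=3, check_reps=3,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_data(tiny_cfg):
    return simulate_dataset(tiny_cfg)


def make_blues(truth, cfg, trait="YLD", conditions=("ALU", "LIM"), noise_seed=0,
               reliability_sd=None):
    """BLUE-like table straight from truth + iid noise (skips the REML stage).

    ``reliability_sd`` defaults to each condition's residual SD, i.e. the
    precision of a single unreplicated plot.
    """
    rng = np.random.default_rng(noise_seed)
    rows = []
    for cond in conditions:
        g = truth.true_bv[(trait, cond)]
        sd = reliability_sd if reliability_sd is not None else cfg.residual_sd(trait, cond)
        y = cfg.env_means[(trait, cond)] + g + rng.normal(0.0, sd, len(g))
        rows.append(pd.DataFrame({
            "entry_id": g.index, "condition": cond, "trait": trait,
            "blue": y.to_numpy(), "se": sd, "is_check": False,
        }))
    return pd.concat(rows, ignore_index=True)
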
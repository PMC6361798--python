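import numpy as np
import pandas as pd
import pytest

from gradedrt.model_core import ItemParameters, ModelVariant, PopulationStructure
from gradedrt.synthetic_data import (
    SimulationConfig,
    generate_item_bank,
    generate_persons,
    simulate_dataset,
)


@pytest.fixture
def toy_items():
    return [
        ItemParameters("i1", 1, 1.2, np.array([-0.5, 0.4, 1.1]),
                       lam=2.0, phi=0.8, sigma_omega=0.5),
        ItemParameters("i2", 1, 0.9, np.array([0.0]),
                       lam=2.2, phi=1.1, sigma_omega=0.6),
        ItemParameters("i3", 1, 1.5, np.array([-1.0, 0.8]),
                       lam=1.8, phi=0.7, sigma_omega=0.4),
    ]


@pytest.fixture
def structure_1d():
    return PopulationStructure(H=1, R_theta=np.eye(1), rho=np.array([0.5]))


def small_config(seed=11, N=200, J=12, H=3, P=1, **kw):
    """A scaled-down study configuration for fast fitting tests."""
    defaults = dict(
        seed=seed,
        n_per_batch=(N,),
        unique_per_batch=(0,),
        n_linking=J,
        H=H,
        category_fractions=(0.0, 0.3, 0.7),
        P_per_batch=(P,),
        gamma_per_batch=(tuple([0.0] * P),),
        contamination_fraction=0.0,
        missing_response_rate=0.0,
    )
    if H == 1:
        defaults.update(R_theta=((1.0,),), rho=(0.45,))
    defaults.update(kw)
    return SimulationConfig(**defaults)


def simulate_single_batch(cfg, variant=ModelVariant.MODEL0, gamma=None):
    """One batch drawn from cfg; returns (table, bank, theta, tau, interviewer)."""
    rng = np.random.default_rng(cfg.seed)
    bank = generate_item_bank(cfg, rng)
    N = cfg.n_per_batch[0]
    P = cfg.P_per_batch[0]
    pid, theta, tau, iv = generate_persons(cfg, N, P, rng)
    table = simulate_dataset(bank, pid, theta, tau, iv, cfg,
                             variant=variant, gamma=gamma, rng=rng)
    return table, bank, theta, tau, iv


@pytest.fixture
def long_table():
    """A small raw long-format table with known missingness for preprocessing."""
    rng = np.random.default_rng(5)
    rows = []
    for p in range(10):
        for j in range(20):
            missing = p < 2  # persons 0 and 1 miss everything
            rows.append({
                "person_id": f"p{p:02d}",
                "item_id": f"i{j:02d}",
                "response": np.nan if missing else rng.integers(1, 5),
                "rt": np.nan if missing else float(rng.uniform(4, 20)),
                "interviewer_id": "iv1",
                "batch_id": "b1",
            })
    return pd.DataFrame(rows)
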
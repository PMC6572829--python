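import numpy as np
import pandas as pd
import pytest

from synergybench import synthdata
from synergybench.synthdata import ScreenConfig


@pytest.fixture(scope="session")
def panel():
    return synthdata.make_panel(24, 30, ["breast", "lung", "gi"], 0.25, seed=11)


@pytest.fixture(scope="session")
def drug_lib(panel):
    return synthdata.make_drug_library(8, panel.bem.index, 3, seed=11)


@pytest.fixture(scope="session")
def design(panel, drug_lib):
    return synthdata.make_design(panel, drug_lib, 6, 10, seed=11)


@pytest.fixture(scope="session")
def noise_free_screen(panel, drug_lib, design):
    """Zero-noise, zero-synergy screen plus its ground truth."""
    cfg = ScreenConfig(noise_sd=0.0)
    return synthdata.simulate_screen(panel, drug_lib, design, cfg, seed=7,
                                     delta_override=0.0)


@pytest.fixture(scope="session")
def synergy_table():
    """Deterministic synthetic synergy table for metric fixtures:
    20 combinations x 25 cells with heterogeneous per-combination scale."""
    rng = np.random.default_rng(5)
    rows = []
    for i in range(20):
        mu = rng.normal(0, 15)
        for c in range(25):
            rows.append((f"C{i:02d}", f"cell{c:02d}",
                         mu + rng.normal(0, 20)))
    return pd.DataFrame(rows, columns=["combo_id", "cell_id", "score"])


def make_team(obs: pd.DataFrame, rho: float, seed: int,
              team: str = "team") -> pd.DataFrame:
    """Continuous predictions with population correlation ``rho`` to obs."""
    rng = np.random.default_rng(seed)
    s = obs["score"].to_numpy(float)
    z = (s - s.mean()) / s.std()
    pred = rho * z + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(len(s))
    return pd.DataFrame({"team": team, "combo_id": obs["combo_id"],
                         "cell_id": obs["cell_id"], "prediction": pred})


def make_conditional_teams(n_teams: int, n_exp: int, bacs, prevalence: float,
                           seed: int):
    """Conditionally independent binary teams with given true BACs
    (sensitivity = specificity = BAC).  Returns (tidy predictions, truth)."""
    rng = np.random.default_rng(seed)
    truth = (rng.random(n_exp) < prevalence).astype(int)
    keys = [(f"C{i // 25:03d}", f"cell{i % 25:02d}") for i in range(n_exp)]
    frames = []
    for t in range(n_teams):
        correct = rng.random(n_exp) < bacs[t]
        pred = np.where(correct, truth, 1 - truth)
        frames.append(pd.DataFrame({
            "team": f"team{t:02d}",
            "combo_id": [k[0] for k in keys],
            "cell_id": [k[1] for k in keys],
            "prediction_binary": pred}))
    return pd.concat(frames, ignore_index=True), truth
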
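import numpy as np
import pandas as pd
import pytest

import wcohort as wc


@pytest.fixture(scope="session")
def default_cfg():
    return wc.SimConfig(n_families=150, seed=7)


@pytest.fixture(scope="session")
def ascertained(default_cfg):
    fams = wc.simulate_families(default_cfg)
    cohort = wc.ascertain(fams, default_cfg)
    return fams, cohort


@pytest.fixture(scope="session")
def carrier_records(ascertained):
    _, cohort = ascertained
    res = wc.build_cohort(cohort)
    return res.records[res.records["carrier"] == "carrier"].reset_index(drop=True)


def random_survival_frame(rng, n, n_covs=1, weights=False, max_beta=0.8):
    """Small random survival dataset with known smooth structure, used as a
    generic fixture for the Cox machinery."""
    cols = {f"x{j}": rng.normal(size=n) for j in range(1, n_covs + 1)}
    eta = sum(rng.uniform(-max_beta, max_beta) * v for v in cols.values())
    t_event = rng.exponential(np.exp(-eta))
    t_cens = rng.exponential(1.5, size=n)
    df = pd.DataFrame({
        "exit_age": np.minimum(t_event, t_cens) + 1e-9,
        "event": (t_event <= t_cens).astype(int),
        "family_id": rng.integers(0, max(2, n // 3), size=n),
        **cols,
    })
    if weights:
        df["weight"] = rng.uniform(0.2, 3.0, size=n)
    return df
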
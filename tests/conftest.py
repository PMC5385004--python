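import numpy as np
import pandas as pd
import pytest

import vcmtdm as v


@pytest.fixture(scope="session")
def pop():
    return v.PopulationPKModel()


@pytest.fixture(scope="session")
def tiny_cohort():
    return v.generate_cohort(v.SyntheticConfig(n_patients=8, seed=101)).cohort


@pytest.fixture(scope="session")
def fast_mcmc():
    """Scaled-down sampler settings for simulation-heavy tests."""
    return v.McmcSettings(chains=3, draws=400, warmup=300)


@pytest.fixture(scope="session")
def toy_dataset():
    """Factory for small regression datasets with a controllable truth.

    y = (beta1 + sex_dev)·pmmpv + beta_bun·bun_adjscr + beta_adj·scr_adj_amt
        + noise, plus independent decoy covariates z1..z_k.
    """

    def _make(n=200, seed=0, beta1=1.0, sex_dev=(0.0, 0.0), beta_bun=0.0,
              beta_adj=0.0, resid_sd=2.0, n_noise=2):
        rng = np.random.default_rng(seed)
        pmmpv = rng.uniform(8.0, 20.0, n)
        bun_adjscr = rng.gamma(4.0, 6.0, n)
        scr_adj_amt = np.where(rng.random(n) < 0.3, rng.uniform(0.0, 0.35, n), 0.0)
        sex = np.where(rng.random(n) < 0.5, "female", "male")
        dev = np.where(sex == "female", sex_dev[0], sex_dev[1])
        y = ((beta1 + dev) * pmmpv + beta_bun * bun_adjscr
             + beta_adj * scr_adj_amt + rng.normal(0.0, resid_sd, n))
        cols = {"pmmpv": pmmpv, "bun_adjscr": bun_adjscr,
                "scr_adj_amt": scr_adj_amt, "sex": sex, "bepv": y}
        noise_names = []
        for j in range(n_noise):
            name = f"z{j + 1}"
            cols[name] = rng.normal(0.0, 1.0, n)
            noise_names.append(name)
        table = pd.DataFrame(cols)
        return v.AnalysisDataset(
            table=table,
            continuous=tuple(["pmmpv", "bun_adjscr", "scr_adj_amt"] + noise_names),
            discrete=("sex",))

    return _make
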
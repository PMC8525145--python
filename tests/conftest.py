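import numpy as np
import pandas as pd
import pytest

import poeciloqg as pq


@pytest.fixture(scope="session")
def base_sim():
    """One default-parameter split-brood simulation, shared across tests."""
    return pq.simulate_base_population(pq.SimParams(seed=11))


@pytest.fixture(scope="session")
def recovery_params():
    """Study conditions for sampler parameter-recovery checks: 20 full-sib
    families of 30 (split across salinities), one clutch per individual so
    the per-individual mode call matches the single-liability model, latent
    h2 = 0.9 / (0.9 + 0.1 + 1) = 0.45 with the extra 0.1 carried by dishes."""

    def make(seed: int) -> pq.SimParams:
        return pq.SimParams(
            n_families=20,
            n_per_family_per_env=15,
            Va=0.9,
            Vm=0.0,
            Vdish=0.1,
            Vid=0.0,
            Ve=1.0,
            survival_low=1.0,
            survival_high=1.0,
            p_mixed=0.0,
            relatedness="full_sib_outcrossed",
            eggmass_mean=0.0,
            eggmass_min=1,
            mu_liability=-0.1,
            beta_salinity=0.2,
            seed=seed,
        )

    return make


def binary_table(sim):
    tab = pq.build_phenotype_table(sim.pedigree, sim.records)
    data = tab.frame.dropna(subset=["y"]).copy()
    data["y"] = data["y"].astype(int)
    return data


@pytest.fixture(scope="session")
def small_pedigree_frame():
    """Founder pair, outcrossed child, then a two-step selfing chain."""
    return pd.DataFrame(
        {
            "id": ["f1", "f2", "c1", "s1", "s2"],
            "dam": ["", "", "f1", "c1", "s1"],
            "sire": ["", "", "f2", "c1", "s1"],
            "selfed": [0, 0, 0, 1, 1],
        }
    )
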
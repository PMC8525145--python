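import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import poeciloqg as pq
from poeciloqg.data_model import EggMassRecord, Individual, Pedigree
from poeciloqg.gxe import FamilyReactionNorm


def make_counts_dataset(counts):
    """counts: {(family, salinity): (n_L, n_P)} -> pedigree + records."""
    inds, records = [], []
    for (fam, sal), (n_l, n_p) in counts.items():
        for i in range(n_l + n_p):
            iid = f"{fam}-{sal}-{i}"
            inds.append(
                Individual(id=iid, family=fam, site="s", dish="d0",
                           salinity=sal, generation="P")
            )
            diam = 182.0 if i < n_l else 113.0
            records.append(EggMassRecord(f"{iid}-e1", iid, 1, (diam,)))
    return Pedigree(inds), records


def test_reaction_norm_direct_counts():
    ped, recs = make_counts_dataset(
        {("famA", "low16"): (4, 6), ("famA", "high32"): (6, 4)}
    )
    norms = pq.family_reaction_norms(ped, recs)
    (norm_a,) = norms
    assert norm_a.prop_L_low == pytest.approx(0.4)
    assert norm_a.prop_L_high == pytest.approx(0.6)
    assert norm_a.slope == pytest.approx(0.2)
    assert not norm_a.small  # flag is strict: n < 10, and here n == 10


def test_all_planktotrophic_family():
    ped, recs = make_counts_dataset(
        {("famA", "low16"): (0, 12), ("famA", "high32"): (0, 15)}
    )
    (norm_a,) = pq.family_reaction_norms(ped, recs)
    assert norm_a.prop_L_low == 0.0 and norm_a.prop_L_high == 0.0


def test_single_environment_family_dropped():
    ped, recs = make_counts_dataset({("famA", "low16"): (3, 7)})
    assert pq.family_reaction_norms(ped, recs) == []


def test_reaction_norm_slopes_positive_under_salinity_effect():
    """With a positive salinity shift and Va > 0 the mean family slope is
    positive across replicate simulations."""
    mean_slopes = []
    for seed in range(12):
        sim = pq.simulate_base_population(pq.SimParams(seed=seed))
        norms = pq.family_reaction_norms(sim.pedigree, sim.records)
        mean_slopes.append(np.mean([n.slope for n in norms]))
    assert np.mean(mean_slopes) > 0
    assert np.mean([s > 0 for s in mean_slopes]) >= 0.75


def test_cross_env_identity_line():
    norms = [
        FamilyReactionNorm(f"f{i}", "s", 20, 20, p, p, False)
        for i, p in enumerate([0.1, 0.3, 0.5, 0.8])
    ]
    fit = pq.cross_env_correlation(norms)
    assert fit.slope == pytest.approx(1.0)
    assert fit.intercept == pytest.approx(0.0, abs=1e-12)
    assert fit.r2 == pytest.approx(1.0)
    assert fit.pearson_r == pytest.approx(1.0)


def test_cross_env_zero_variance_predictor_rejected():
    norms = [
        FamilyReactionNorm(f"f{i}", "s", 20, 20, p, 0.4, False)
        for i, p in enumerate([0.1, 0.3, 0.5])
    ]
    with pytest.raises(ValueError, match="zero variance"):
        pq.cross_env_correlation(norms)


def _family_props(rho, n_fam, rng, noise_sd=0.08):
    """Family proportions in two environments with set correlation."""
    g = rng.standard_normal(n_fam)
    g_low = rho * g + np.sqrt(max(1 - rho**2, 0)) * rng.standard_normal(n_fam)
    p_high = np.clip(0.5 + 0.25 * g + noise_sd * rng.standard_normal(n_fam), 0.01, 0.99)
    p_low = np.clip(0.5 + 0.25 * g_low + noise_sd * rng.standard_normal(n_fam), 0.01, 0.99)
    return [
        FamilyReactionNorm(f"f{i}", "s", 30, 30, p_low[i], p_high[i], False)
        for i in range(n_fam)
    ]


def test_cross_env_null_correlation_slope_near_zero():
    rng = np.random.default_rng(3)
    slopes = [pq.cross_env_correlation(_family_props(0.0, 17, rng)).slope
              for _ in range(40)]
    assert abs(np.mean(slopes)) < 0.08


def test_cross_env_high_correlation_recovered():
    rng = np.random.default_rng(4)
    fits = [pq.cross_env_correlation(_family_props(0.9, 17, rng)) for _ in range(25)]
    mean_r = np.mean([f.pearson_r for f in fits])
    assert 0.7 < mean_r < 0.98


def test_cross_env_slope_unbiased_at_large_n():
    rng = np.random.default_rng(5)
    fits = [pq.cross_env_correlation(_family_props(0.8, 200, rng, noise_sd=0.0))
            for _ in range(10)]
    assert np.mean([f.slope for f in fits]) == pytest.approx(0.8, abs=0.04)


def test_maternal_effect_model_cell_means():
    """On a balanced 2x2 design the no-intercept coefficients are the cell
    means in the reference environment plus interaction offsets."""
    cells = pd.DataFrame(
        {
            "prop_L": [0.2, 0.2, 0.4, 0.4, 0.5, 0.5, 0.7, 0.7],
            "generation": ["P", "P", "P", "P", "S1", "S1", "S1", "S1"],
            "rearing_env": ["h", "h", "l", "l", "h", "h", "l", "l"],
        }
    )
    table = pq.maternal_effect_model(cells)
    assert table.loc["gen_P", "coef"] == pytest.approx(0.2)
    assert table.loc["gen_S1", "coef"] == pytest.approx(0.5)
    assert table.loc["gen_P:env_l", "coef"] == pytest.approx(0.2)
    assert table.loc["gen_S1:env_l", "coef"] == pytest.approx(0.2)
    assert table.attrs["r2"] == pytest.approx(1.0)


def test_maternal_effect_model_duplication_shrinks_se():
    rng = np.random.default_rng(0)
    cells = pd.DataFrame(
        {
            "prop_L": rng.random(8),
            "generation": ["P", "P", "S1", "S1"] * 2,
            "rearing_env": ["h", "l"] * 4,
        }
    )
    t1 = pq.maternal_effect_model(cells)
    t2 = pq.maternal_effect_model(pd.concat([cells, cells], ignore_index=True))
    np.testing.assert_allclose(t1["coef"], t2["coef"], atol=1e-10)
    assert (t2["se"] < t1["se"]).all()


def test_maternal_effect_model_rank_deficiency_named():
    # environment perfectly confounded with generation: the S1 interaction
    # column duplicates the S1 main column
    cells = pd.DataFrame(
        {
            "prop_L": [0.1, 0.2, 0.5, 0.6],
            "generation": ["P", "P", "S1", "S1"],
            "rearing_env": ["h", "h", "l", "l"],
        }
    )
    with pytest.raises(ValueError, match="aliased"):
        pq.maternal_effect_model(cells)


def test_maternal_null_p_values_uniform():
    """With no maternal effect the parental-generation coefficient p-value
    is uniform across replicate simulated designs."""
    rng = np.random.default_rng(9)
    pvals = []
    for _ in range(200):
        cells = pd.DataFrame(
            {
                "prop_L": 0.4 + 0.1 * rng.standard_normal(16),
                "generation": ["P"] * 8 + ["S1"] * 8,
                "rearing_env": (["h"] * 4 + ["l"] * 4) * 2,
            }
        )
        table = pq.maternal_effect_model(cells)
        # contrast P vs S1 in the reference environment
        diff = table.loc["gen_P", "coef"] - table.loc["gen_S1", "coef"]
        se = np.sqrt(table.loc["gen_P", "se"] ** 2 + table.loc["gen_S1", "se"] ** 2)
        from scipy.stats import t as tdist

        pvals.append(2 * tdist.sf(abs(diff / se), df=12))
    assert kstest(pvals, "uniform").pvalue > 0.01


def test_survival_regression_cases():
    rng = np.random.default_rng(2)
    fams = pd.DataFrame(
        {
            "family": [f"f{i}" for i in range(20)] * 2,
            "salinity": ["low16"] * 20 + ["high32"] * 20,
            "survival": np.r_[rng.uniform(0.4, 0.9, 20), rng.uniform(0.5, 1.0, 20)],
            "prop_L": rng.uniform(0, 1, 40),
        }
    )
    out = pq.survival_proportion_regression(fams)
    assert set(out) == {"low16", "high32"}
    for r2, p in out.values():
        assert 0 <= r2 <= 1 and 0 <= p <= 1

    collinear = fams[fams["salinity"] == "low16"].copy()
    collinear["prop_L"] = 0.2 + 0.5 * collinear["survival"]
    (r2, p), = pq.survival_proportion_regression(collinear).values()
    assert r2 == pytest.approx(1.0)

    const = fams[fams["salinity"] == "low16"].copy()
    const["survival"] = 0.7
    with pytest.raises(ValueError, match="zero variance"):
        pq.survival_proportion_regression(const)


def test_reaction_norms_conserve_classification(base_sim):
    """Family-by-environment proportions aggregate exactly the L calls."""
    norms = pq.family_reaction_norms(base_sim.pedigree, base_sim.records)
    by_ind = {i.id: i for i in base_sim.pedigree.individuals}
    for nrm in norms[:5]:
        n_l = sum(
            1
            for r in base_sim.records
            if by_ind[r.individual_id].family == nrm.family
            and by_ind[r.individual_id].salinity == "low16"
            and pq.classify_egg_mass(r.capsule_diams_um).mode == "L"
        )
        n_tot = sum(
            1
            for r in base_sim.records
            if by_ind[r.individual_id].family == nrm.family
            and by_ind[r.individual_id].salinity == "low16"
        )
        assert nrm.prop_L_low == pytest.approx(n_l / n_tot)
        assert nrm.n_low == n_tot
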
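import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest, norm

import poeciloqg as pq


def prop_L(records):
    calls = [pq.classify_egg_mass(r.capsule_diams_um).mode for r in records]
    return np.mean([c == "L" for c in calls])


def records_by_env(sim):
    by_ind = {i.id: i for i in sim.pedigree.individuals}
    out = {"low16": [], "high32": []}
    for r in sim.records:
        out[by_ind[r.individual_id].salinity].append(r)
    return out


def test_forced_liability_sign():
    params = pq.SimParams(
        n_families=4, n_per_family_per_env=5, Va=0, Vm=0, Vdish=0, Vid=0,
        Ve=1.0, mu_liability=10.0, beta_salinity=0.0, p_mixed=0.0,
        survival_low=1.0, survival_high=1.0, seed=0,
    )
    sim = pq.simulate_base_population(params)
    assert prop_L(sim.records) == 1.0


def test_symmetric_liability_gives_half():
    params = pq.SimParams(
        n_families=40, n_per_family_per_env=30, Va=0, Vm=0, Vdish=0, Vid=0,
        Ve=1.0, mu_liability=0.0, beta_salinity=0.0, p_mixed=0.0,
        survival_low=1.0, survival_high=1.0, seed=1,
    )
    sim = pq.simulate_base_population(params)
    p = prop_L(sim.records)
    n = len(sim.records)
    assert abs(p - 0.5) < 4 * np.sqrt(0.25 / n)


def test_default_calibration_hits_study_proportions():
    """At large n the realized egg-mass proportions of lecithotrophy match
    the calibration targets (17.6% low, 25.7% high); the tolerance allows
    for family/individual clustering on top of binomial error."""
    params = pq.SimParams(
        n_families=100, n_per_family_per_env=50, survival_low=1.0,
        survival_high=1.0, seed=2,
    )
    sim = pq.simulate_base_population(params)
    env_recs = records_by_env(sim)
    for env, target in (("low16", 0.176), ("high32", 0.257)):
        p = prop_L(env_recs[env])
        assert p == pytest.approx(target, abs=0.03)


def test_marginal_proportion_matches_probit():
    """P(clutch lecithotrophic) equals (1-p_mixed) * Phi(mu_env / sd_total)."""
    params = pq.SimParams(n_families=80, n_per_family_per_env=40,
                          survival_low=1.0, survival_high=1.0, seed=3)
    mu, beta = params.resolved_mu_beta()
    s = np.sqrt(params.total_liability_var)
    sim = pq.simulate_base_population(params)
    env_recs = records_by_env(sim)
    for env, shift in (("low16", 0.0), ("high32", beta)):
        expected = (1 - params.p_mixed) * norm.cdf((mu + shift) / s)
        assert prop_L(env_recs[env]) == pytest.approx(expected, abs=0.035)


def test_latent_h2_identity():
    p = pq.SimParams(Va=1.2, Vm=0.2, Vdish=0.05, Vid=0.2, Ve=1.0)
    assert p.h2_latent_true == pytest.approx(1.2 / 2.65)


def test_seed_determinism_byte_identical(tmp_path):
    pa = tmp_path / "a.csv"
    pb = tmp_path / "b.csv"
    for path in (pa, pb):
        sim = pq.simulate_selection_experiment(pq.SimParams(seed=7, n_generations=3))
        pq.write_phenotypes(path, sim.pedigree, sim.records)
    assert pa.read_bytes() == pb.read_bytes()


def test_selection_increases_proportion_when_heritable():
    """Sign test over replicate simulations: with Va > 0 the proportion of
    lecithotrophic clutches increases from P to S1 nearly always."""
    wins = trials = 0
    for seed in range(50):
        params = pq.SimParams(
            n_families=8, n_per_family_per_env=8, n_generations=2,
            n_offspring_per_selected=6, seed=seed,
        )
        sim = pq.simulate_selection_experiment(params)
        by_ind = {i.id: i for i in sim.pedigree.individuals}
        gens = {"P": [], "S1": []}
        for r in sim.records:
            g = by_ind[r.individual_id].generation
            if g in gens:
                gens[g].append(r)
        if not gens["S1"]:
            continue
        trials += 1
        wins += prop_L(gens["S1"]) > prop_L(gens["P"])
    assert trials >= 40
    assert binomtest(wins, trials, 0.5, alternative="greater").pvalue < 1e-6


def test_selection_no_response_without_additive_variance():
    """With Va = 0 (liability noise only) selection cannot shift the
    expected proportion."""
    diffs = []
    for seed in range(30):
        params = pq.SimParams(
            n_families=10, n_per_family_per_env=10, n_generations=2,
            Va=0.0, Vm=0.0, Vdish=0.0, Vid=0.0, Ve=1.0,
            mu_liability=-0.5, beta_salinity=0.2, p_mixed=0.0,
            n_offspring_per_selected=6, survival_low=1.0, survival_high=1.0,
            seed=seed,
        )
        sim = pq.simulate_selection_experiment(params)
        by_ind = {i.id: i for i in sim.pedigree.individuals}
        gens = {"P": [], "S1": []}
        for r in sim.records:
            g = by_ind[r.individual_id].generation
            if g in gens:
                gens[g].append(r)
        diffs.append(prop_L(gens["S1"]) - prop_L(gens["P"]))
    assert abs(np.mean(diffs)) < 0.03


def test_lineage_terminates_without_lecithotrophic_layers():
    params = pq.SimParams(
        n_families=3, n_per_family_per_env=4, n_generations=3,
        Va=0.0, Vm=0.0, Vdish=0.0, Vid=0.0, Ve=1.0,
        mu_liability=-10.0, beta_salinity=12.0, p_mixed=0.0,
        survival_low=1.0, survival_high=1.0, seed=4,
    )
    # low line can never produce lecithotrophic layers; high line always does
    sim = pq.simulate_selection_experiment(params)
    assert any("low16" in e for e in sim.events)
    gens = {i.generation for i in sim.pedigree.individuals if i.salinity == "high32"}
    assert "S2" in gens


def test_selfing_tracks_inbreeding():
    sim = pq.simulate_selection_experiment(pq.SimParams(seed=5, n_generations=3))
    F = sim.truth["inbreeding"]
    by_gen = {}
    for ind in sim.pedigree.individuals:
        by_gen.setdefault(ind.generation, []).append(F[ind.id])
    assert set(np.unique(by_gen["P"])) == {0.0}
    if "S1" in by_gen:
        assert set(np.round(by_gen["S1"], 6)) == {0.5}
    if "S2" in by_gen:
        assert set(np.round(by_gen["S2"], 6)) <= {0.5, 0.75}


def test_mixed_clutches_have_both_size_classes():
    sim = pq.simulate_base_population(pq.SimParams(seed=6, p_mixed=0.3))
    mixed = [r for r in sim.records if pq.classify_egg_mass(r.capsule_diams_um).mode == "M"]
    assert mixed
    for r in mixed[:20]:
        call = pq.classify_egg_mass(r.capsule_diams_um)
        assert call.n_large > 0 and call.n_small > 0


def test_egg_capsule_pairs_noise_free_and_low_signal():
    noise_free = pq.simulate_egg_capsule_pairs(pq.SimParams(seed=7), 500, r2_target=1.0)
    _, _, r2, _ = pq.capsule_egg_regression(noise_free)
    assert r2 == pytest.approx(1.0)
    weak = pq.simulate_egg_capsule_pairs(pq.SimParams(seed=8), 20_000, r2_target=0.02)
    _, _, r2w, _ = pq.capsule_egg_regression(weak)
    assert r2w < 0.04
    with pytest.raises(ValueError):
        pq.simulate_egg_capsule_pairs(pq.SimParams(seed=9), 1)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        pq.SimParams(Ve=0.0)
    with pytest.raises(ValueError):
        pq.SimParams(p_mixed=1.5)
    with pytest.raises(ValueError):
        pq.SimParams(capsule_mode_L=140.0)
    with pytest.raises(ValueError):
        pq.simulate_selection_experiment(pq.SimParams(n_generations=1))
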
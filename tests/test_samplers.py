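import numpy as np
import pandas as pd
import pytest

import poeciloqg as pq
from poeciloqg.animal_model import (
    LiabilityModelSpec,
    _gibbs,
    categorical_predicted_frequencies,
)
from poeciloqg.data_model import Individual, Pedigree

from conftest import binary_table


def iid_pedigree(n, nf=1, prefix="i"):
    fams = np.repeat(np.arange(nf), int(np.ceil(n / nf)))[:n]
    inds = [
        Individual(
            id=f"{prefix}{i}", family=f"f{fams[i]}", site="s", dish=f"d{i % 7}",
            salinity="high32" if i % 2 else "low16", generation="P",
        )
        for i in range(n)
    ]
    return Pedigree(inds), fams


def test_gaussian_matches_conjugate_posterior():
    """With no random effects the Gibbs chain must reproduce the
    closed-form normal ridge posterior for the coefficients."""
    rng = np.random.default_rng(0)
    n = 300
    x = rng.random(n)
    X = np.column_stack([np.ones(n), x])
    y = X @ np.array([1.0, 2.0]) + 0.5 * rng.standard_normal(n)
    spec = LiabilityModelSpec(
        response="gaussian", n_iter=30_000, burn_in=2_000, thin=5, seed=4
    )
    post = _gibbs(y, X, ["mu", "beta_salinity"], [], spec, np.random.default_rng(4))
    ve = post.draws["Vr"].mean()
    expected = np.linalg.solve(X.T @ X / ve + np.eye(2), X.T @ y / ve)
    got = post.draws[["mu", "beta_salinity"]].mean().to_numpy()
    np.testing.assert_allclose(got, expected, atol=0.03)
    # coefficient posterior SDs match (X'X/ve + I)^(-1) diagonal
    cov = np.linalg.inv(X.T @ X / ve + np.eye(2))
    np.testing.assert_allclose(
        post.draws[["mu", "beta_salinity"]].std().to_numpy(),
        np.sqrt(np.diag(cov)),
        rtol=0.2,
    )


def test_gaussian_animal_model_recovers_h2():
    """Full-sib families with one record each: ensemble posterior mean of
    Va/(Va+Ve) near the generative 0.4, with CI coverage."""
    nf, m = 100, 6
    n = nf * m
    means, covers = [], []
    for seed in range(8):
        rng = np.random.default_rng(seed)
        fams = np.repeat(np.arange(nf), m)
        a = np.sqrt(0.2)[()] * rng.standard_normal(nf)[fams] + np.sqrt(
            0.2
        ) * rng.standard_normal(n)
        y = 0.15 + a + np.sqrt(0.6) * rng.standard_normal(n)
        inds = [
            Individual(id=f"i{i}", family=f"f{fams[i]}", site="s", dish="d0",
                       salinity="high32", generation="P")
            for i in range(n)
        ]
        ped = Pedigree(inds)
        data = pd.DataFrame(
            {"individual_id": [f"i{i}" for i in range(n)],
             "family": [f"f{f}" for f in fams],
             "dish": "d0", "site": "s", "salinity": "high32", "capsule_um": y}
        )
        A = pq.build_relationship_matrix(ped, "full_sib_outcrossed")
        spec = LiabilityModelSpec(
            response="gaussian", random_terms=("animal",),
            n_iter=8_000, burn_in=1_000, thin=5, seed=seed + 99,
        )
        post = pq.fit_gaussian_animal_model(spec, data, A, rescale=1.0)
        h2 = post.draws["Va"] / (post.draws["Va"] + post.draws["Vr"])
        means.append(h2.mean())
        covers.append(h2.quantile(0.025) <= 0.4 <= h2.quantile(0.975))
    assert abs(np.mean(means) - 0.4) < 0.1
    assert np.mean(covers) >= 0.75


def test_gaussian_null_va_concentrates_near_zero():
    rng = np.random.default_rng(5)
    nf, m = 40, 10
    n = nf * m
    fams = np.repeat(np.arange(nf), m)
    y = 1.0 + rng.standard_normal(n)  # no genetic signal
    inds = [
        Individual(id=f"i{i}", family=f"f{fams[i]}", site="s", dish="d0",
                   salinity="high32", generation="P")
        for i in range(n)
    ]
    data = pd.DataFrame(
        {"individual_id": [f"i{i}" for i in range(n)],
         "family": [f"f{f}" for f in fams],
         "dish": "d0", "site": "s", "salinity": "high32", "capsule_um": y}
    )
    A = pq.build_relationship_matrix(Pedigree(inds), "full_sib_outcrossed")
    spec = LiabilityModelSpec(
        response="gaussian", random_terms=("animal",),
        n_iter=6_000, burn_in=1_000, thin=5, seed=8,
    )
    post = pq.fit_gaussian_animal_model(spec, data, A, rescale=1.0)
    vp = (post.draws["Va"] + post.draws["Vr"]).median()
    assert post.draws["Va"].median() < 0.05 * vp


def test_threshold_strong_salinity_effect_excludes_zero(recovery_params):
    """With the mode deterministic in salinity the fixed-effect posterior
    must exclude zero decisively."""
    params = recovery_params(3)
    sim = pq.simulate_base_population(params)
    data = binary_table(sim)
    data["y"] = (data["salinity"] == "high32").astype(int)
    # drop one row so both classes exist in each dish grouping trivially
    A = pq.build_relationship_matrix(sim.pedigree, "full_sib_outcrossed")
    spec = LiabilityModelSpec(
        response="binary", random_terms=("animal", "dish"),
        n_iter=6_000, burn_in=1_000, thin=5, seed=12,
    )
    post = pq.fit_threshold_animal_model(spec, data, A)
    assert post.draws["beta_salinity"].quantile(0.01) > 0
    assert post.pmcmc("beta_salinity") <= 2 / len(post.draws)


def test_threshold_relabel_symmetry(recovery_params):
    """Swapping the 0/1 coding negates location effects and leaves the
    variance components distributionally unchanged."""
    params = recovery_params(4)
    sim = pq.simulate_base_population(params)
    data = binary_table(sim)
    A = pq.build_relationship_matrix(sim.pedigree, "full_sib_outcrossed")
    spec = LiabilityModelSpec(
        response="binary", random_terms=("animal", "dish"),
        n_iter=12_000, burn_in=2_000, thin=5, seed=21,
    )
    post1 = pq.fit_threshold_animal_model(spec, data, A)
    flipped = data.copy()
    flipped["y"] = 1 - flipped["y"]
    post2 = pq.fit_threshold_animal_model(spec, flipped, A)
    assert post1.draws["mu"].mean() == pytest.approx(-post2.draws["mu"].mean(), abs=0.12)
    assert post1.draws["Va"].mean() == pytest.approx(
        post2.draws["Va"].mean(), rel=0.5, abs=0.3
    )


def test_threshold_all_one_response_rejected(recovery_params):
    sim = pq.simulate_base_population(recovery_params(5))
    data = binary_table(sim)
    data["y"] = 1
    A = pq.build_relationship_matrix(sim.pedigree, "full_sib_outcrossed")
    spec = LiabilityModelSpec(response="binary", n_iter=2_000, burn_in=100)
    with pytest.raises(ValueError, match="all-0 or all-1"):
        pq.fit_threshold_animal_model(spec, data, A)


def test_prior_predictive_incidence_matches_probit():
    """Simulating y from the generative liability model reproduces
    P(y=1) = Phi(mu / sqrt(1 + total variance))."""
    rng = np.random.default_rng(9)
    mu, Va, Vd = -0.7, 0.9, 0.3
    n = 200_000
    liab = mu + np.sqrt(Va + Vd) * rng.standard_normal(n) + rng.standard_normal(n)
    from scipy.stats import norm

    expected = norm.cdf(mu / np.sqrt(1 + Va + Vd))
    assert np.mean(liab > 0) == pytest.approx(expected, abs=0.005)


def test_dic_reproducible_and_orders_models(recovery_params):
    """Refitting with a new seed moves DIC by less than Monte-Carlo error;
    on strong-signal data the model with the salinity effect beats the
    intercept-only model decisively."""
    params = recovery_params(6)
    sim = pq.simulate_base_population(params)
    data = binary_table(sim)
    # make salinity a strong determinant
    rng = np.random.default_rng(0)
    strong = data.copy()
    strong["y"] = np.where(
        strong["salinity"] == "high32", rng.random(len(strong)) < 0.9,
        rng.random(len(strong)) < 0.1,
    ).astype(int)
    A = pq.build_relationship_matrix(sim.pedigree, "full_sib_outcrossed")

    def fit(with_salinity, seed):
        spec = LiabilityModelSpec(
            response="binary",
            fixed=("salinity",) if with_salinity else (),
            random_terms=("animal", "dish"),
            n_iter=8_000, burn_in=1_000, thin=5, seed=seed,
        )
        return pq.fit_threshold_animal_model(spec, strong, A)

    full_a = pq.dic(fit(True, 31))
    full_b = pq.dic(fit(True, 32))
    reduced = pq.dic(fit(False, 33))
    assert abs(full_a - full_b) < 20  # Monte-Carlo error bound
    # the dish random effects (nested in family x salinity) can absorb much
    # of the salinity signal, so the margin is modest but strictly positive
    assert full_a < reduced - 5


def test_diagnostics_ess():
    rng = np.random.default_rng(0)
    n = 4000
    wn = rng.standard_normal(n)
    ar = np.empty(n)
    ar[0] = 0.0
    for i in range(1, n):
        ar[i] = 0.9 * ar[i - 1] + rng.standard_normal()
    out = pq.diagnostics(pd.DataFrame({"wn": wn, "ar": ar, "const": np.ones(n)}))
    assert abs(out.loc["wn", "ess"] - n) / n < 0.10
    expected_ar = n * (1 - 0.9) / (1 + 0.9)
    assert abs(out.loc["ar", "ess"] - expected_ar) / expected_ar < 0.25
    assert out.loc["const", "ess"] == 0.0 and out.loc["const", "low_ess"]
    with pytest.raises(ValueError, match="at least 100"):
        pq.diagnostics(np.ones(50))


def test_categorical_rare_category_recovery(recovery_params):
    """A ~5-8% mixed category at n=600 is recovered by the categorical
    model's predicted frequencies within 3 percentage points."""
    params = pq.SimParams(
        **{**recovery_params(7).__dict__, "p_mixed": 0.08, "seed": 7}
    )
    sim = pq.simulate_base_population(params)
    data = binary_table(sim)
    A = pq.build_relationship_matrix(sim.pedigree, "full_sib_outcrossed")
    spec = LiabilityModelSpec(
        response="categorical", random_terms=("animal", "dish"),
        n_iter=10_000, burn_in=2_000, thin=5, seed=71,
    )
    post = pq.fit_categorical_animal_model(spec, data, A)
    pred = categorical_predicted_frequencies(post)
    obs = data["mode"].value_counts(normalize=True)
    for cat in ("L", "P", "M"):
        assert pred[cat] == pytest.approx(obs.get(cat, 0.0), abs=0.03)


def test_categorical_two_category_matches_binary(recovery_params):
    """Two-category data through the categorical model agrees with the
    binary threshold model on the latent heritability."""
    sim = pq.simulate_base_population(recovery_params(5))
    data = binary_table(sim)
    A = pq.build_relationship_matrix(sim.pedigree, "full_sib_outcrossed")
    kw = dict(random_terms=("animal", "dish"), n_iter=14_000, burn_in=2_000,
              thin=5)
    pb = pq.fit_threshold_animal_model(
        LiabilityModelSpec(response="binary", seed=42, **kw), data, A
    )
    pc = pq.fit_categorical_animal_model(
        LiabilityModelSpec(response="categorical", seed=43, **kw), data, A
    )
    h2b = (pb.draws["Va"] / (pb.draws["Va"] + pb.draws["V_dish"] + 1)).mean()
    h2c = (pc.draws["Va_L"] / (pc.draws["Va_L"] + pc.draws["V_dish_L"] + 1)).mean()
    assert h2b == pytest.approx(h2c, abs=0.12)


def test_variance_draws_positive_and_link_fixed(recovery_params):
    sim = pq.simulate_base_population(recovery_params(8))
    data = binary_table(sim)
    A = pq.build_relationship_matrix(sim.pedigree, "full_sib_outcrossed")
    spec = LiabilityModelSpec(
        response="binary", random_terms=("animal", "dish"),
        n_iter=4_000, burn_in=500, thin=5, seed=2,
    )
    post = pq.fit_threshold_animal_model(spec, data, A)
    assert (post.draws[list(post.variance_columns)] > 0).all().all()
    assert "Vr" not in post.draws.columns  # link variance fixed at 1, not drawn
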
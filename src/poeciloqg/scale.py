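"""Heritability conversion between the latent (liability) and observed scales.

A probit-link threshold model estimates variance components on a latent
Gaussian scale; heritability there is Va over the total latent variance
including the probit link variance of 1. On the observed 0/1 (or category
frequency) scale, heritability follows the GLMM conversion: with latent
ℓ ~ N(µ, V) the expected phenotype frequency is p̄ = E[Φ(ℓ)], the average
link derivative is Ψ = E[φ(ℓ)], observed phenotypic variance is p̄(1−p̄),
and h²_obs = Ψ²·Va / (p̄(1−p̄)). Expectations are evaluated by
Gauss–Hermite quadrature, with a Monte-Carlo route kept as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.stats import norm

__all__ = [
    "ScaleResult",
    "h2_latent",
    "binary_observed_scale",
    "binary_observed_scale_mc",
    "categorical_observed_scale",
    "gaussian_h2",
    "posterior_scale_summary",
]

_N_NODES = 64
_NODES, _WEIGHTS = hermegauss(_N_NODES)
_WEIGHTS = _WEIGHTS / np.sqrt(2.0 * np.pi)  # E[f(Z)] = Σ w_i f(x_i), Z ~ N(0,1)


@dataclass(frozen=True)
class ScaleResult:
    h2_latent: float
    h2_observed: float
    p_bar: float
    psi: float


def h2_latent(
    Va: float, other_random_variances, link_variance: float = 1.0
) -> float:
    """Latent-scale heritability Va / (Va + Σ other variances + link variance)."""
    others = [float(v) for v in np.atleast_1d(other_random_variances)]
    if Va < 0 or any(v < 0 for v in others) or link_variance < 0:
        raise ValueError("variance components must be nonnegative")
    denom = Va + sum(others) + link_variance
    if denom == 0:
        raise ValueError("total latent variance is zero")
    return float(Va / denom)


def _gauss_hermite_expectations(mu: float, V: float) -> tuple[float, float]:
    """(E[Φ(ℓ)], E[φ(ℓ)]) for ℓ ~ N(mu, V) by Gauss–Hermite quadrature."""
    ell = mu + np.sqrt(V) * _NODES
    p_bar = float(np.sum(_WEIGHTS * norm.cdf(ell)))
    psi = float(np.sum(_WEIGHTS * norm.pdf(ell)))
    return p_bar, psi


def binary_observed_scale(mu: float, Va: float, Vrand_total: float) -> ScaleResult:
    """Observed-scale heritability of a binary probit trait.

    ``Vrand_total`` is the total variance of the latent predictor excluding
    the unit link variance (all random components: animal plus the
    environmental terms). Degenerate phenotypes (p̄ numerically 0 or 1) are
    an error.
    """
    if not (Vrand_total >= Va >= 0):
        raise ValueError("need Vrand_total >= Va >= 0")
    p_bar, psi = _gauss_hermite_expectations(mu, Vrand_total)
    if not (1e-12 < p_bar < 1 - 1e-12):
        raise ValueError(f"degenerate phenotype frequency p_bar = {p_bar}")
    v_obs = p_bar * (1.0 - p_bar)
    h2_obs = psi**2 * Va / v_obs
    return ScaleResult(
        h2_latent=h2_latent(Va, [Vrand_total - Va]),
        h2_observed=float(h2_obs),
        p_bar=p_bar,
        psi=psi,
    )


def binary_observed_scale_mc(
    mu: float, Va: float, Vrand_total: float, n_draws: int = 1_000_000, seed: int = 0
) -> tuple[ScaleResult, float, float]:
    """Monte-Carlo counterpart of :func:`binary_observed_scale`.

    Returns the result plus the Monte-Carlo standard errors of p̄ and Ψ,
    for use as an independent integration cross-check.
    """
    rng = np.random.default_rng(seed)
    ell = mu + np.sqrt(Vrand_total) * rng.standard_normal(n_draws)
    cdf_vals = norm.cdf(ell)
    pdf_vals = norm.pdf(ell)
    p_bar = float(np.mean(cdf_vals))
    psi = float(np.mean(pdf_vals))
    se_p = float(np.std(cdf_vals, ddof=1) / np.sqrt(n_draws))
    se_psi = float(np.std(pdf_vals, ddof=1) / np.sqrt(n_draws))
    v_obs = p_bar * (1.0 - p_bar)
    res = ScaleResult(
        h2_latent=h2_latent(Va, [Vrand_total - Va]),
        h2_observed=float(psi**2 * Va / v_obs),
        p_bar=p_bar,
        psi=psi,
    )
    return res, se_p, se_psi


def categorical_observed_scale(
    mus,
    Vas,
    Vrand_totals,
    n_draws: int = 200_000,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Observed-scale heritability per category of a 3-category probit trait.

    The model has two latent dimensions (one per non-reference category,
    reference = planktotrophic); an observation falls in the reference
    category when both latents are negative, otherwise in the category of
    the largest positive latent. Per-category frequency and the average
    derivative of the category probability with respect to each latent's
    additive value are estimated by Monte-Carlo integration over the two
    independent latents.

    ``mus``, ``Vas``, ``Vrand_totals`` are length-2 sequences for the
    non-reference categories (by convention ["L", "M"]). Returns a dict
    keyed "L", "P", "M" with ``p_bar`` and ``h2_observed`` per category.
    """
    mus = np.asarray(mus, float)
    Vas = np.asarray(Vas, float)
    Vtot = np.asarray(Vrand_totals, float)
    if mus.shape != (2,) or Vas.shape != (2,) or Vtot.shape != (2,):
        raise ValueError("expect two latent dimensions (non-reference categories)")
    if np.any(Vas < 0) or np.any(Vtot < Vas):
        raise ValueError("need Vrand_total >= Va >= 0 per dimension")
    rng = np.random.default_rng(seed)
    # additive values per dimension; residual link noise N(0,1) integrated
    # analytically / by quadrature via the probit
    a = np.sqrt(Vtot) * rng.standard_normal((n_draws, 2)) + mus

    def category_probs(av: np.ndarray, smooth_in: int) -> np.ndarray:
        """P(category | additive values) integrating the residual of the
        dimension *other than* ``smooth_in`` by quadrature, so that the
        result is a smooth function of ``av[:, smooth_in]`` (the quadrature
        of an indicator is a step function of the variable it thresholds,
        which would corrupt numerical derivatives)."""
        j = 1 - smooth_in  # residual integrated by quadrature
        k = smooth_in
        lj = av[:, [j]] + _NODES[None, :]
        # P(this dim's latent beats max(0, l_j)): smooth in av_k
        p_k_wins = np.sum(_WEIGHTS * norm.cdf(av[:, [k]] - np.maximum(0.0, lj)), axis=1)
        # P(dim j wins): indicator in l_j but smooth in av_k
        p_j_wins = np.sum(_WEIGHTS * (lj > 0) * norm.cdf(lj - av[:, [k]]), axis=1)
        p_ref = norm.cdf(-av[:, 0]) * norm.cdf(-av[:, 1])
        out = np.empty((av.shape[0], 3))
        col = {0: 0, 1: 2}  # latent dim -> column (L, P, M)
        out[:, col[k]] = p_k_wins
        out[:, col[j]] = p_j_wins
        out[:, 1] = p_ref
        return out

    probs = category_probs(a, smooth_in=0)
    p_bar = probs.mean(axis=0)

    # numerical derivative of each category probability w.r.t. each latent
    # additive value, averaged over the latent distribution (Ψ matrix)
    h = 1e-4
    psi = np.zeros((3, 2))
    for j in range(2):
        ap = a.copy()
        ap[:, j] += h
        am = a.copy()
        am[:, j] -= h
        psi[:, j] = (
            category_probs(ap, smooth_in=j).mean(axis=0)
            - category_probs(am, smooth_in=j).mean(axis=0)
        ) / (2 * h)

    out: dict[str, dict[str, float]] = {}
    for k, name in enumerate(("L", "P", "M")):
        v_obs = p_bar[k] * (1 - p_bar[k])
        if v_obs < 1e-12:
            out[name] = {"p_bar": float(p_bar[k]), "h2_observed": float("nan")}
            continue
        # additive variance of the category score: Σ_j Ψ_kj² Va_j (latent
        # dimensions independent)
        v_add = float(np.sum(psi[k] ** 2 * Vas))
        out[name] = {"p_bar": float(p_bar[k]), "h2_observed": v_add / v_obs}
    return out


def gaussian_h2(Va: float, components) -> float:
    """Heritability for an identity-link Gaussian trait: Va / (Va + Σ components)."""
    comps = [float(v) for v in np.atleast_1d(components)]
    if Va < 0 or any(v < 0 for v in comps):
        raise ValueError("variance components must be nonnegative")
    denom = Va + sum(comps)
    if denom == 0:
        raise ValueError("total variance is zero")
    return float(Va / denom)


def posterior_scale_summary(
    mu_draws,
    Va_draws,
    Vrand_total_draws,
    point_estimate: bool = False,
) -> dict[str, float]:
    """Apply the binary conversion per posterior draw and average.

    Per-draw conversion then averaging is the default convention; with
    ``point_estimate=True`` the conversion is instead applied once at the
    posterior means (both are reported by the CLI).
    """
    mu = np.asarray(mu_draws, float)
    Va = np.asarray(Va_draws, float)
    Vt = np.asarray(Vrand_total_draws, float)
    if point_estimate:
        res = binary_observed_scale(float(mu.mean()), float(Va.mean()), float(Vt.mean()))
        return {
            "h2_latent": res.h2_latent,
            "h2_observed": res.h2_observed,
            "p_bar": res.p_bar,
        }
    lat, obs, pb = [], [], []
    for m, a, v in zip(mu, Va, Vt):
        r = binary_observed_scale(float(m), float(a), float(v))
        lat.append(r.h2_latent)
        obs.append(r.h2_observed)
        pb.append(r.p_bar)
    return {
        "h2_latent": float(np.mean(lat)),
        "h2_observed": float(np.mean(obs)),
        "p_bar": float(np.mean(pb)),
    }
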
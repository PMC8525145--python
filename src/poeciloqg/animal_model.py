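"""Bayesian animal models: Gaussian, binary-probit and categorical responses.

The mixed model is

    y* = X b + Z_a a + Z_1 u_1 + ... + e,   a ~ N(0, Va A),  u_k ~ N(0, V_k I)

with A the additive relationship matrix. For the Gaussian response y* is
the observed capsule diameter and e ~ N(0, Ve); for the binary (threshold)
response y* is an augmented latent liability with residual variance fixed
at 1 for identification and the observation is y = 1[y* > 0]; the
categorical response (L/P/M, reference category P) uses two independent
latent liabilities, one per non-reference category, with the observation
falling in the reference category when both are negative and otherwise in
the category of the largest latent.

Sampling is blocked Gibbs with conjugate updates: truncated-normal data
augmentation for latents, multivariate-normal full conditionals for
location effects (the animal term sampled per connected component of A
with batched Cholesky factorizations), and inverse-gamma full conditionals
for variance components. Fixed effects get a zero-mean normal prior
(variance 1 for Gaussian, 1000 for threshold/categorical models);
variance components get weakly-informative inverse-gamma(0.001, 0.001)
priors by default, with an optional parameter-expansion move to improve
mixing when a component sits near zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import ndtr, ndtri

from .data_model import get_logger
from .relationship import RelationshipMatrix

__all__ = [
    "LiabilityModelSpec",
    "PosteriorDraws",
    "fit_gaussian_animal_model",
    "fit_threshold_animal_model",
    "fit_categorical_animal_model",
    "dic",
    "diagnostics",
]

_log = get_logger("animal_model")

_DEFAULT_RANDOM = {
    "gaussian": ("animal", "id", "family", "dish", "family_site"),
    "binary": ("animal", "family", "dish", "family_site"),
    "categorical": ("animal", "family", "dish", "family_site"),
}


@dataclass(frozen=True)
class LiabilityModelSpec:
    """Model definition and chain settings.

    ``random_terms`` defaults per response: the Gaussian model is fitted at
    the egg-mass level with an iid permanent-environment ``id`` term for
    repeated clutches, the binary and categorical models at the level of
    per-individual calls (where an extra iid individual term would be
    confounded with the unit link variance).
    """

    response: str  # gaussian | binary | categorical
    fixed: tuple[str, ...] = ("salinity",)
    random_terms: tuple[str, ...] | None = None
    prior_fixed_variance: float | None = None  # default: 1 gaussian, 1000 otherwise
    variance_prior: tuple[float, float] = (0.001, 0.001)  # inverse-gamma shape, scale
    n_iter: int = 603_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0
    parameter_expansion: bool | None = None  # default: on for threshold/categorical
    px_alpha_variance: float = 1.0  # half-Cauchy scale on each component's SD
    # prior on the additive SD in threshold/categorical models: a probit
    # latent scale has link variance 1, so additive SDs beyond ~3 imply
    # near-deterministic liabilities; a half-normal keeps the posterior
    # proper along the weakly identified latent-scale direction (a
    # half-Cauchy or inverse-gamma tail does not decay fast enough there)
    animal_sd_prior: tuple[str, float] = ("half_normal", 1.0)

    def __post_init__(self) -> None:
        if self.response not in ("gaussian", "binary", "categorical"):
            raise ValueError(f"unknown response {self.response!r}")
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def effective_random_terms(self) -> tuple[str, ...]:
        return (
            self.random_terms
            if self.random_terms is not None
            else _DEFAULT_RANDOM[self.response]
        )

    @property
    def fixed_variance(self) -> float:
        if self.prior_fixed_variance is not None:
            return self.prior_fixed_variance
        return 1.0 if self.response == "gaussian" else 1000.0

    @property
    def px_effective(self) -> bool:
        """Parameter expansion: with one binary record per individual the
        likelihood flattens in the latent scale, and the nearly
        scale-invariant inverse-gamma prior then drags variance components
        to arbitrarily large values; the expanded parameterization (working
        effects times a scalar with a normal prior) gives each component's
        standard deviation a half-Cauchy prior that keeps the posterior
        proper in that direction. On by default for threshold/categorical
        responses, off for Gaussian."""
        if self.parameter_expansion is not None:
            return self.parameter_expansion
        return self.response != "gaussian"


@dataclass
class PosteriorDraws:
    """Retained post-burn-in thinned draws plus what DIC needs.

    ``draws`` has one row per retained draw with fixed effects, variance
    components (all strictly positive; the residual link variance of
    non-Gaussian responses is fixed at 1 and not stored as a draw) and the
    per-draw deviance.
    """

    draws: pd.DataFrame = field(repr=False)
    response: str = "gaussian"
    variance_columns: tuple[str, ...] = ()
    mean_eta: np.ndarray | None = field(default=None, repr=False)
    mean_ve: float = 1.0
    y: np.ndarray | None = field(default=None, repr=False)

    def vrand_total(self) -> pd.Series:
        """Total random-effect variance per draw (all components, no link)."""
        return self.draws[list(self.variance_columns)].sum(axis=1)

    def pmcmc(self, name: str) -> float:
        """Two-tailed MCMC p-value 2*min(P(b>0), P(b<0)) with a 1/n floor."""
        b = self.draws[name].to_numpy()
        n = b.size
        tail = min((b > 0).mean(), (b < 0).mean())
        return float(max(2.0 * tail, 1.0 / n))

    def summary(self) -> pd.DataFrame:
        cols = [c for c in self.draws.columns if c != "deviance"]
        out = self.draws[cols].agg(["mean", "std"]).T
        out["q2.5"] = self.draws[cols].quantile(0.025)
        out["q97.5"] = self.draws[cols].quantile(0.975)
        return out


# ---------------------------------------------------------------------------
# sampler machinery


class _Term:
    """One random-effect term: level index per record plus prior structure."""

    def __init__(self, name: str, g: np.ndarray, q: int, Kinv: np.ndarray | None = None):
        self.name = name
        self.g = np.asarray(g, dtype=np.intp)
        self.q = int(q)
        self.counts = np.bincount(self.g, minlength=self.q).astype(float)
        self.iid = Kinv is None
        if not self.iid:
            n_comp, labels = connected_components(
                csr_matrix(np.abs(Kinv) > 1e-12), directed=False
            )
            groups: dict[int, list[np.ndarray]] = {}
            for c in range(n_comp):
                comp = np.flatnonzero(labels == c)
                groups.setdefault(comp.size, []).append(comp)
            self.block_groups: list[tuple[np.ndarray, np.ndarray]] = []
            for size, comps in groups.items():
                idx = np.stack(comps)  # (m, k)
                Kb = np.stack([Kinv[np.ix_(c, c)] for c in comps])  # (m, k, k)
                self.block_groups.append((idx, Kb))

    def scatter_b(self, resid: np.ndarray) -> np.ndarray:
        return np.bincount(self.g, weights=resid, minlength=self.q)

    def sample(
        self, resid: np.ndarray, ve: float, s2: float, rng, scale: float = 1.0
    ) -> np.ndarray:
        """Draw the term's effects from their multivariate-normal full
        conditional; ``scale`` is the parameter-expansion multiplier on the
        design (identity 1.0 in the plain parameterization)."""
        b = scale * self.scatter_b(resid) / ve
        if self.iid:
            prec = scale**2 * self.counts / ve + 1.0 / s2
            return b / prec + rng.standard_normal(self.q) / np.sqrt(prec)
        u = np.empty(self.q)
        for idx, Kb in self.block_groups:
            m, k = idx.shape
            P = Kb / s2
            r = np.arange(k)
            P[:, r, r] += scale**2 * self.counts[idx] / ve
            cov = np.linalg.inv(P)
            mean = np.einsum("mij,mj->mi", cov, b[idx])
            L = np.linalg.cholesky(cov)
            z = rng.standard_normal((m, k))
            u[idx.ravel()] = (mean + np.einsum("mij,mj->mi", L, z)).ravel()
        return u

    def sample_weighted(
        self, resid: np.ndarray, w: np.ndarray, s2: float, rng, scale: float = 1.0
    ) -> np.ndarray:
        """Heteroscedastic full conditional for an iid term (weights w = 1/var)."""
        if not self.iid:
            raise ValueError("weighted update implemented for iid terms only")
        b = scale * np.bincount(self.g, weights=w * resid, minlength=self.q)
        prec = scale**2 * np.bincount(self.g, weights=w, minlength=self.q) + 1.0 / s2
        return b / prec + rng.standard_normal(self.q) / np.sqrt(prec)

    def quad_form(self, u: np.ndarray) -> float:
        if self.iid:
            return float(u @ u)
        total = 0.0
        for idx, Kb in self.block_groups:
            ub = u[idx]
            total += float(np.einsum("mi,mij,mj->", ub, Kb, ub))
        return total


def _truncated_normal(
    mean: np.ndarray, lower: np.ndarray, upper: np.ndarray, rng, sd=1.0
) -> np.ndarray:
    a = ndtr((lower - mean) / sd)
    b = ndtr((upper - mean) / sd)
    u = a + rng.random(mean.size) * (b - a)
    return mean + sd * ndtri(np.clip(u, 1e-14, 1.0 - 1e-14))


def _block_structure(A: np.ndarray):
    """Detect an equicorrelated-block relationship matrix.

    Returns ``(labels, off, diag)`` with per-component constant off-diagonal
    relatedness and diagonal, or None when A is not block-constant (e.g. a
    multi-generation pedigree), in which case the explicit animal-effect
    sampler must be used.
    """
    n = A.shape[0]
    ncomp, labels = connected_components(csr_matrix(np.abs(A) > 1e-12), directed=False)
    off = np.zeros(ncomp)
    diag = np.ones(ncomp)
    for c in range(ncomp):
        idx = np.flatnonzero(labels == c)
        block = A[np.ix_(idx, idx)]
        d = np.diag(block)
        if np.ptp(d) > 1e-9:
            return None
        diag[c] = d[0]
        if idx.size > 1:
            o = block[~np.eye(idx.size, dtype=bool)]
            if np.ptp(o) > 1e-9:
                return None
            off[c] = o[0]
    return labels, off, diag


class _MarginalAnimal:
    """Animal term for single-record threshold data over a block A.

    The additive value decomposes into a family-shared component
    s_f ~ N(0, off_f Va) and an individual Mendelian part absorbed into the
    link residual, whose variance becomes 1 + (diag_f − off_f) Va. Only the
    shared component is sampled; Va itself is updated by univariate slice
    sampling of its full conditional, which avoids the slow random-walk
    drift of per-observation data augmentation.
    """

    def __init__(self, labels_rec: np.ndarray, off: np.ndarray, diag: np.ndarray):
        self.comp = np.asarray(labels_rec, dtype=np.intp)  # component per record
        self.off = off
        self.diag = diag
        self.w_frac = diag - off
        self.nf = off.size
        self.shared = off > 1e-12  # components with a nonzero shared part
        self.s = np.zeros(self.nf)
        self.Va = 0.1

    def resid_var(self, link_variance: float = 1.0) -> np.ndarray:
        """Per-record residual variance (link plus Mendelian part)."""
        return link_variance + self.w_frac[self.comp] * self.Va

    def eta(self) -> np.ndarray:
        return self.s[self.comp]

    def sample_shared(self, resid: np.ndarray, w: np.ndarray, rng) -> None:
        """resid = ystar minus all other terms; w = 1/residual variance."""
        sw = np.bincount(self.comp, weights=w * resid, minlength=self.nf)
        pw = np.bincount(self.comp, weights=w, minlength=self.nf)
        prior_prec = np.where(self.shared, 1.0 / (self.off * self.Va + 1e-300), np.inf)
        prec = pw + prior_prec
        mean = np.where(self.shared, sw / prec, 0.0)
        sd = np.where(self.shared, 1.0 / np.sqrt(prec), 0.0)
        self.s = mean + sd * rng.standard_normal(self.nf)

    def _log_conditional(self, Va: float, eps_ss: np.ndarray, n_per: np.ndarray,
                         log_prior) -> float:
        if Va <= 0:
            return -np.inf
        lp = log_prior(Va)
        sh = self.shared
        lp += -0.5 * np.sum(np.log(self.off[sh] * Va) + self.s[sh] ** 2 / (self.off[sh] * Va))
        sig2 = 1.0 + self.w_frac * Va
        lp += -0.5 * np.sum(n_per * np.log(sig2) + eps_ss / sig2)
        return float(lp)

    def slice_update_Va(self, eps: np.ndarray, log_prior, rng, width: float = 1.0) -> None:
        """Slice sample log Va given shared effects and residuals eps."""
        eps_ss = np.bincount(self.comp, weights=eps**2, minlength=self.nf)
        n_per = np.bincount(self.comp, minlength=self.nf).astype(float)

        def logp(x: float) -> float:
            # include the log-Jacobian of the log transform
            return self._log_conditional(np.exp(x), eps_ss, n_per, log_prior) + x

        x0 = np.log(self.Va)
        ly = logp(x0) + np.log(rng.random() + 1e-300)
        lo = x0 - width * rng.random()
        hi = lo + width
        for _ in range(50):
            if logp(lo) <= ly:
                break
            lo -= width
        for _ in range(50):
            if logp(hi) <= ly:
                break
            hi += width
        for _ in range(100):
            x1 = lo + rng.random() * (hi - lo)
            if logp(x1) > ly:
                self.Va = float(np.exp(x1))
                return
            if x1 < x0:
                lo = x1
            else:
                hi = x1
        # degenerate shrinkage: keep current value
        self.Va = float(np.exp(x0))


def _build_fixed_design(data: pd.DataFrame, fixed: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    n = len(data)
    cols = [np.ones(n)]
    names = ["mu"]
    for term in fixed:
        if term != "salinity":
            raise ValueError(f"unsupported fixed term {term!r}")
        if data["salinity"].nunique() > 1:
            cols.append((data["salinity"] == "high32").to_numpy(float))
            names.append("beta_salinity")
    return np.column_stack(cols), names


def _build_terms(
    data: pd.DataFrame, term_names: Sequence[str], A: RelationshipMatrix
) -> list[_Term]:
    pos = {v: i for i, v in enumerate(A.ids)}
    missing = set(data["individual_id"]) - set(pos)
    if missing:
        raise ValueError(f"individuals absent from relationship matrix: {sorted(missing)[:5]}")
    terms: list[_Term] = []
    for name in term_names:
        if name == "animal":
            g = data["individual_id"].map(pos).to_numpy()
            Kinv = np.linalg.inv(A.A)
            terms.append(_Term("animal", g, len(A.ids), Kinv))
            continue
        if name == "id":
            codes, _ = pd.factorize(data["individual_id"])
        elif name == "family":
            codes, _ = pd.factorize(data["family"])
        elif name == "dish":
            codes, _ = pd.factorize(data["dish"])
        elif name == "family_site":
            codes, _ = pd.factorize(data["family"].astype(str) + ":" + data["site"].astype(str))
        else:
            raise ValueError(f"unknown random term {name!r}")
        terms.append(_Term(name, codes, int(codes.max()) + 1))
    return terms


def _deviance_gaussian(y: np.ndarray, eta: np.ndarray, ve: float) -> float:
    n = y.size
    return float(n * np.log(2 * np.pi * ve) + np.sum((y - eta) ** 2) / ve)


def _deviance_binary(y: np.ndarray, eta: np.ndarray) -> float:
    p = np.clip(ndtr(eta), 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _var_name(term: str) -> str:
    return {"animal": "Va", "id": "V_id", "family": "V_family",
            "dish": "V_dish", "family_site": "V_family_site"}[term]


def _gibbs(
    y: np.ndarray,
    X: np.ndarray,
    fixed_names: list[str],
    terms: list[_Term],
    spec: LiabilityModelSpec,
    rng,
) -> PosteriorDraws:
    """Shared Gibbs core for the Gaussian and binary responses."""
    n, p = X.shape
    binary = spec.response == "binary"
    px = spec.px_effective
    # under parameter expansion the working variance gets an inverse-gamma
    # with nu=1 (jointly with the normal alpha: half-Cauchy on the SD)
    a0, b0 = (0.5, 0.5) if px else spec.variance_prior
    alpha_v = spec.px_alpha_variance
    XtX = X.T @ X
    v_fix = spec.fixed_variance

    beta = np.zeros(p)
    us = [np.zeros(t.q) for t in terms]  # working effects (eta_k)
    alpha = np.ones(len(terms))
    s2 = np.full(len(terms), 0.1)  # working variances
    ve = 1.0 if binary else float(np.var(y) if np.var(y) > 0 else 1.0)
    ystar = y.astype(float).copy()
    if binary:
        ystar = np.where(y > 0, 0.5, -0.5)
    eta = X @ beta
    for t, u in zip(terms, us):
        eta += u[t.g]

    lower = np.where(y > 0, 0.0, -np.inf) if binary else None
    upper = np.where(y > 0, np.inf, 0.0) if binary else None

    n_keep = (spec.n_iter - spec.burn_in) // spec.thin
    var_names = [_var_name(t.name) for t in terms]
    records = np.empty((n_keep, p + len(terms) + (0 if binary else 1) + 1))
    mean_eta = np.zeros(n)
    kept = 0

    for it in range(spec.n_iter):
        if binary:
            ystar = _truncated_normal(eta, lower, upper, rng)

        # fixed effects
        resid = ystar - (eta - X @ beta)
        prec = XtX / ve + np.eye(p) / v_fix
        bvec = X.T @ resid / ve
        cf = cho_factor(prec, lower=True)
        mean_b = cho_solve(cf, bvec)
        new_beta = mean_b + solve_triangular(
            cf[0], rng.standard_normal(p), lower=True, trans="T"
        )
        eta += X @ (new_beta - beta)
        beta = new_beta

        # random terms (effective contribution alpha_k * Z eta_k)
        for k, t in enumerate(terms):
            contrib = alpha[k] * us[k][t.g]
            resid = ystar - (eta - contrib)
            new_u = t.sample(resid, ve, s2[k], rng, scale=alpha[k])
            eta += alpha[k] * new_u[t.g] - contrib
            us[k] = new_u
            if px:
                zu = us[k][t.g]
                resid = ystar - (eta - alpha[k] * zu)
                denom = zu @ zu / ve + 1.0 / alpha_v
                num = zu @ resid / ve
                new_alpha = num / denom + rng.standard_normal() / np.sqrt(denom)
                eta += (new_alpha - alpha[k]) * zu
                alpha[k] = new_alpha
            s2[k] = 1.0 / rng.gamma(a0 + t.q / 2.0, 1.0 / (b0 + t.quad_form(us[k]) / 2.0))

        if not binary:
            e = ystar - eta
            ve = 1.0 / rng.gamma(a0 + n / 2.0, 1.0 / (b0 + e @ e / 2.0))

        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
            dev = _deviance_binary(y, eta) if binary else _deviance_gaussian(y, eta, ve)
            v_eff = alpha**2 * s2 if px else s2
            row = [*beta, *v_eff] + ([] if binary else [ve]) + [dev]
            records[kept] = row
            mean_eta += eta
            kept += 1

    cols = fixed_names + var_names + ([] if binary else ["Vr"]) + ["deviance"]
    draws = pd.DataFrame(records[:kept], columns=cols)
    return PosteriorDraws(
        draws=draws,
        response=spec.response,
        variance_columns=tuple(var_names),
        mean_eta=mean_eta / max(kept, 1),
        mean_ve=float(draws["Vr"].mean()) if not binary else 1.0,
        y=y.astype(float),
    )


def _make_log_prior(spec: LiabilityModelSpec):
    """Log prior density (in the variance) for the additive variance in the
    marginal threshold sampler, per ``spec.animal_sd_prior``."""
    kind, scale = spec.animal_sd_prior
    if kind == "half_normal":
        c2 = scale**2

        def log_prior(v: float) -> float:
            return -0.5 * np.log(v) - v / (2.0 * c2)

    elif kind == "half_cauchy":
        c2 = scale**2

        def log_prior(v: float) -> float:
            return -0.5 * np.log(v) - np.log1p(v / c2)

    elif kind == "inverse_gamma":
        a0, b0 = spec.variance_prior

        def log_prior(v: float) -> float:
            return -(a0 + 1.0) * np.log(v) - b0 / v

    else:
        raise ValueError(f"unknown animal_sd_prior kind {kind!r}")
    return log_prior


def _gibbs_marginal_binary(
    y: np.ndarray,
    X: np.ndarray,
    fixed_names: list[str],
    anim: _MarginalAnimal,
    terms: list[_Term],
    spec: LiabilityModelSpec,
    rng,
) -> PosteriorDraws:
    """Binary probit sampler with the animal term marginalized to its
    family-shared component (single record per individual, block A)."""
    n, p = X.shape
    px = spec.px_effective
    a0, b0 = (0.5, 0.5) if px else spec.variance_prior
    alpha_v = spec.px_alpha_variance
    v_fix = spec.fixed_variance
    log_prior = _make_log_prior(spec)

    beta = np.zeros(p)
    us = [np.zeros(t.q) for t in terms]
    alpha = np.ones(len(terms))
    s2 = np.full(len(terms), 0.1)
    eta = X @ beta + anim.eta()
    for t, u in zip(terms, us):
        eta += u[t.g]
    lower = np.where(y > 0, 0.0, -np.inf)
    upper = np.where(y > 0, np.inf, 0.0)

    n_keep = (spec.n_iter - spec.burn_in) // spec.thin
    var_names = ["Va"] + [_var_name(t.name) for t in terms]
    records = np.empty((n_keep, p + len(var_names) + 1))
    mean_eta = np.zeros(n)
    mean_sd = np.zeros(n)
    kept = 0

    for it in range(spec.n_iter):
        sig2 = anim.resid_var()
        sd = np.sqrt(sig2)
        w = 1.0 / sig2

        ystar = _truncated_normal(eta, lower, upper, rng, sd=sd)

        # fixed effects (weighted)
        resid = ystar - (eta - X @ beta)
        prec = (X.T * w) @ X + np.eye(p) / v_fix
        cf = cho_factor(prec, lower=True)
        mean_b = cho_solve(cf, X.T @ (w * resid))
        new_beta = mean_b + solve_triangular(
            cf[0], rng.standard_normal(p), lower=True, trans="T"
        )
        eta += X @ (new_beta - beta)
        beta = new_beta

        # iid random terms
        for k, t in enumerate(terms):
            contrib = alpha[k] * us[k][t.g]
            resid = ystar - (eta - contrib)
            new_u = t.sample_weighted(resid, w, s2[k], rng, scale=alpha[k])
            eta += alpha[k] * new_u[t.g] - contrib
            us[k] = new_u
            if px:
                zu = new_u[t.g]
                resid = ystar - (eta - alpha[k] * zu)
                denom = zu @ (w * zu) + 1.0 / alpha_v
                num = zu @ (w * resid)
                new_alpha = num / denom + rng.standard_normal() / np.sqrt(denom)
                eta += (new_alpha - alpha[k]) * zu
                alpha[k] = new_alpha
            s2[k] = 1.0 / rng.gamma(a0 + t.q / 2.0, 1.0 / (b0 + new_u @ new_u / 2.0))

        # family-shared animal component
        s_contrib = anim.eta()
        resid = ystar - (eta - s_contrib)
        anim.sample_shared(resid, w, rng)
        eta += anim.eta() - s_contrib

        # additive variance by slice sampling its full conditional
        anim.slice_update_Va(ystar - eta, log_prior, rng)

        # joint scale move along the latent-scale ridge: propose rescaling
        # every latent-scale quantity by a common factor (locations and
        # latents by sqrt(c), variances by c). The only non-invariant part
        # of the target is the unit link variance, so this Metropolis move
        # traverses the weakly identified scale direction in one step
        # instead of a slow random walk. (Run in the expanded
        # parameterization, where the iid-term priors are scale-invariant.)
        if px:
            delta = 0.5 * rng.standard_normal()
            c = float(np.exp(delta))
            rc = float(np.sqrt(c))
            sh = anim.shared

            def _scale_logtarget(scale_r: float, scale_v: float) -> float:
                beta_ = scale_r * beta
                s_ = scale_r * anim.s
                Va_ = scale_v * anim.Va
                ystar_ = scale_r * ystar
                eta_ = X @ beta_ + s_[anim.comp]
                for t_, u_, a_ in zip(terms, us, scale_r * alpha):
                    eta_ += a_ * u_[t_.g]
                sig2_ = 1.0 + anim.w_frac[anim.comp] * Va_
                lt = -0.5 * np.sum(np.log(sig2_) + (ystar_ - eta_) ** 2 / sig2_)
                if sh.any():
                    lt += -0.5 * np.sum(
                        np.log(anim.off[sh] * Va_) + s_[sh] ** 2 / (anim.off[sh] * Va_)
                    )
                lt += -0.5 * np.sum(beta_**2) / v_fix
                lt += -0.5 * np.sum((scale_r * alpha) ** 2) / alpha_v
                lt += log_prior(Va_)
                return float(lt)

            n_scaled = p + int(sh.sum()) + n + len(terms)
            log_accept = (
                _scale_logtarget(rc, c)
                - _scale_logtarget(1.0, 1.0)
                + 0.5 * delta * n_scaled
                + delta
            )
            if np.log(rng.random() + 1e-300) < log_accept:
                beta = rc * beta
                anim.s = rc * anim.s
                anim.Va = c * anim.Va
                alpha = rc * alpha
                ystar = rc * ystar
                eta = X @ beta + anim.eta()
                for t, u, a in zip(terms, us, alpha):
                    eta += a * u[t.g]

        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
            sd_now = np.sqrt(anim.resid_var())
            pr = np.clip(ndtr(eta / sd_now), 1e-12, 1 - 1e-12)
            dev = float(-2.0 * np.sum(y * np.log(pr) + (1 - y) * np.log(1 - pr)))
            v_eff = alpha**2 * s2 if px else s2
            records[kept] = [*beta, anim.Va, *v_eff, dev]
            mean_eta += eta
            mean_sd += sd_now
            kept += 1

    draws = pd.DataFrame(records[:kept], columns=fixed_names + var_names + ["deviance"])
    post = PosteriorDraws(
        draws=draws,
        response="binary",
        variance_columns=tuple(var_names),
        mean_eta=mean_eta / max(kept, 1),
        mean_ve=1.0,
        y=y.astype(float),
    )
    # deviance at posterior means must use the averaged link SD as well
    post.mean_link_sd = mean_sd / max(kept, 1)  # type: ignore[attr-defined]
    return post


# ---------------------------------------------------------------------------
# public fits


def fit_gaussian_animal_model(
    spec: LiabilityModelSpec,
    data: pd.DataFrame,
    A: RelationshipMatrix,
    response_column: str = "capsule_um",
    rescale: float = 1000.0,
) -> PosteriorDraws:
    """Gaussian animal model for capsule diameter at the egg-mass level.

    ``data`` has one row per egg mass with ``individual_id`` plus the
    grouping columns the random terms need. Diameters are divided by
    ``rescale`` internally (µm -> mm) so variance components are O(1e-3);
    draws are reported on that working scale.
    """
    if spec.response != "gaussian":
        raise ValueError("spec.response must be 'gaussian'")
    y = data[response_column].to_numpy(float) / rescale
    X, fixed_names = _build_fixed_design(data, spec.fixed)
    terms = _build_terms(data, spec.effective_random_terms, A)
    rng = np.random.default_rng(spec.seed)
    return _gibbs(y, X, fixed_names, terms, spec, rng)


def fit_threshold_animal_model(
    spec: LiabilityModelSpec,
    data: pd.DataFrame,
    A: RelationshipMatrix,
    response_column: str = "y",
) -> PosteriorDraws:
    """Binary probit threshold model for developmental mode.

    ``data`` has one row per individual with the 0/1 mode call in
    ``response_column``. The latent residual variance is fixed at 1.
    """
    if spec.response != "binary":
        raise ValueError("spec.response must be 'binary'")
    y = data[response_column].to_numpy(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("binary response must be coded 0/1")
    if y.min() == y.max():
        raise ValueError("all-0 or all-1 response: intercept unidentified")
    X, fixed_names = _build_fixed_design(data, spec.fixed)
    rng = np.random.default_rng(spec.seed)

    term_names = spec.effective_random_terms
    block = _block_structure(A.A) if "animal" in term_names else None
    single_record = data["individual_id"].is_unique
    if block is not None and single_record and "animal" in term_names:
        labels, off, diag = block
        pos = {v: i for i, v in enumerate(A.ids)}
        labels_rec = labels[data["individual_id"].map(pos).to_numpy()]
        anim = _MarginalAnimal(labels_rec, off, diag)
        iid_terms = _build_terms(
            data, tuple(t for t in term_names if t != "animal"), A
        )
        return _gibbs_marginal_binary(y, X, fixed_names, anim, iid_terms, spec, rng)
    # general pedigree A or repeated records: explicit animal-effect sampler
    # (documented as mixing more slowly for single binary records)
    terms = _build_terms(data, term_names, A)
    return _gibbs(y, X, fixed_names, terms, spec, rng)


_CATEGORIES = ("L", "P", "M")  # reference category is P


def _categorical_probs(
    eta: np.ndarray,
    nodes: np.ndarray,
    weights: np.ndarray,
    sds: np.ndarray | None = None,
) -> np.ndarray:
    """Per-record (P(L), P(P), P(M)) given the two latent linear predictors,
    integrating the two link residuals (one by quadrature, one by the
    probit). ``sds`` gives per-record residual SDs per dimension (unit when
    omitted)."""
    if sds is None:
        sds = np.ones_like(eta)
    l1 = eta[:, [0]] + sds[:, [0]] * nodes[None, :]
    p_l = np.sum(
        weights * (l1 > 0) * ndtr((l1 - eta[:, [1]]) / sds[:, [1]]), axis=1
    )
    l2 = eta[:, [1]] + sds[:, [1]] * nodes[None, :]
    p_m = np.sum(
        weights * (l2 > 0) * ndtr((l2 - eta[:, [0]]) / sds[:, [0]]), axis=1
    )
    p_ref = ndtr(-eta[:, 0] / sds[:, 0]) * ndtr(-eta[:, 1] / sds[:, 1])
    probs = np.column_stack([p_l, p_ref, p_m])
    return probs / probs.sum(axis=1, keepdims=True)


def fit_categorical_animal_model(
    spec: LiabilityModelSpec,
    data: pd.DataFrame,
    A: RelationshipMatrix,
    response_column: str = "mode",
) -> PosteriorDraws:
    """Categorical (L/P/M) probit model with two latent dimensions.

    Reference category is planktotrophic (P); dimensions "L" and "M" each
    carry their own fixed effects and variance components with unit link
    residuals and identity residual covariance. A category absent from the
    data drops its contrast with a warning. Per-draw category probabilities
    enter the deviance via quadrature over the link residuals.
    """
    if spec.response != "categorical":
        raise ValueError("spec.response must be 'categorical'")
    modes = data[response_column].astype(str).to_numpy()
    observed = [c for c in _CATEGORIES if (modes == c).any()]
    if len(observed) < 2:
        raise ValueError("need at least 2 observed categories")
    dims = [c for c in ("L", "M") if c in observed]
    for c in ("L", "M"):
        if c not in observed:
            _log.warning("category %r absent: its contrast is dropped", c)

    X, fixed_names = _build_fixed_design(data, spec.fixed)
    n, p = X.shape
    rng = np.random.default_rng(spec.seed)
    px = spec.px_effective
    a0, b0 = (0.5, 0.5) if px else spec.variance_prior
    alpha_v = spec.px_alpha_variance
    v_fix = spec.fixed_variance
    log_prior = _make_log_prior(spec)

    term_names = spec.effective_random_terms
    block = _block_structure(A.A) if "animal" in term_names else None
    marginal = block is not None and data["individual_id"].is_unique
    if marginal:
        labels, off, diag = block
        pos = {v: i for i, v in enumerate(A.ids)}
        labels_rec = labels[data["individual_id"].map(pos).to_numpy()]
        anim = [_MarginalAnimal(labels_rec, off, diag) for _ in dims]
        iid_names = tuple(t for t in term_names if t != "animal")
        terms = [_build_terms(data, iid_names, A) for _ in dims]
    else:
        anim = []
        terms = [_build_terms(data, term_names, A) for _ in dims]

    from numpy.polynomial.hermite_e import hermegauss

    nodes, weights = hermegauss(32)
    weights = weights / np.sqrt(2 * np.pi)

    nd = len(dims)
    beta = [np.zeros(p) for _ in range(nd)]
    us = [[np.zeros(t.q) for t in terms[d]] for d in range(nd)]
    alpha = [np.ones(len(terms[d])) for d in range(nd)]
    s2 = [np.full(len(terms[d]), 0.1) for d in range(nd)]
    eta = np.zeros((n, nd))
    latent = np.where(modes[:, None] == np.array(dims)[None, :], 0.5, -0.5)

    n_keep = (spec.n_iter - spec.burn_in) // spec.thin
    per_dim = p + len(term_names)
    records = np.empty((n_keep, nd * per_dim + 1))
    mean_eta = np.zeros((n, nd))
    mean_sds = np.ones((n, 2))
    mean_sd_acc = np.zeros((n, nd))
    kept = 0
    y_codes = np.array([_CATEGORIES.index(m) for m in modes], float)

    # truncation bounds per dim given the other dim's latent
    def bounds(d: int) -> tuple[np.ndarray, np.ndarray]:
        other = latent[:, 1 - d] if nd == 2 else np.full(n, -np.inf)
        cat = dims[d]
        lo = np.full(n, -np.inf)
        hi = np.full(n, np.inf)
        is_this = modes == cat
        lo[is_this] = np.maximum(0.0, other[is_this]) if nd == 2 else 0.0
        # records in the other non-reference category constrain this latent
        # to lie below that category's (positive) latent, not below 0
        hi[~is_this] = np.where(
            (modes[~is_this] == "P") | (nd == 1), 0.0, other[~is_this]
        )
        return lo, hi

    def dim_sigma2(d: int) -> np.ndarray:
        return anim[d].resid_var() if marginal else np.ones(n)

    for it in range(spec.n_iter):
        for d in range(nd):
            sig2 = dim_sigma2(d)
            sd = np.sqrt(sig2)
            w = 1.0 / sig2
            lo, hi = bounds(d)
            latent[:, d] = _truncated_normal(eta[:, d], lo, hi, rng, sd=sd)
            ystar = latent[:, d]

            resid = ystar - (eta[:, d] - X @ beta[d])
            prec = (X.T * w) @ X + np.eye(p) / v_fix
            cf = cho_factor(prec, lower=True)
            mean_b = cho_solve(cf, X.T @ (w * resid))
            new_beta = mean_b + solve_triangular(
                cf[0], rng.standard_normal(p), lower=True, trans="T"
            )
            eta[:, d] += X @ (new_beta - beta[d])
            beta[d] = new_beta

            for k, t in enumerate(terms[d]):
                contrib = alpha[d][k] * us[d][k][t.g]
                resid = ystar - (eta[:, d] - contrib)
                if t.iid:
                    new_u = t.sample_weighted(resid, w, s2[d][k], rng, scale=alpha[d][k])
                else:
                    new_u = t.sample(resid, 1.0, s2[d][k], rng, scale=alpha[d][k])
                eta[:, d] += alpha[d][k] * new_u[t.g] - contrib
                us[d][k] = new_u
                if px:
                    zu = new_u[t.g]
                    resid = ystar - (eta[:, d] - alpha[d][k] * zu)
                    denom = zu @ (w * zu) + 1.0 / alpha_v
                    num = zu @ (w * resid)
                    new_alpha = num / denom + rng.standard_normal() / np.sqrt(denom)
                    eta[:, d] += (new_alpha - alpha[d][k]) * zu
                    alpha[d][k] = new_alpha
                s2[d][k] = 1.0 / rng.gamma(
                    a0 + t.q / 2.0, 1.0 / (b0 + t.quad_form(new_u) / 2.0)
                )

            if marginal:
                s_contrib = anim[d].eta()
                resid = ystar - (eta[:, d] - s_contrib)
                anim[d].sample_shared(resid, w, rng)
                eta[:, d] += anim[d].eta() - s_contrib
                anim[d].slice_update_Va(ystar - eta[:, d], log_prior, rng)

        # joint scale move across both latent dimensions (the category rule
        # argmax(0, l_L, l_M) is invariant to a common positive rescaling)
        if marginal and px:
            delta = 0.5 * rng.standard_normal()
            c = float(np.exp(delta))
            rc = float(np.sqrt(c))

            def _lt(scale_r: float, scale_v: float) -> float:
                total = 0.0
                for d in range(nd):
                    beta_ = scale_r * beta[d]
                    s_ = scale_r * anim[d].s
                    Va_ = scale_v * anim[d].Va
                    ystar_ = scale_r * latent[:, d]
                    eta_ = X @ beta_ + s_[anim[d].comp]
                    for t_, u_, a_ in zip(terms[d], us[d], scale_r * alpha[d]):
                        eta_ += a_ * u_[t_.g]
                    sig2_ = 1.0 + anim[d].w_frac[anim[d].comp] * Va_
                    total += -0.5 * np.sum(
                        np.log(sig2_) + (ystar_ - eta_) ** 2 / sig2_
                    )
                    sh = anim[d].shared
                    if sh.any():
                        total += -0.5 * np.sum(
                            np.log(anim[d].off[sh] * Va_)
                            + s_[sh] ** 2 / (anim[d].off[sh] * Va_)
                        )
                    total += -0.5 * np.sum(beta_**2) / v_fix
                    total += -0.5 * np.sum((scale_r * alpha[d]) ** 2) / alpha_v
                    total += log_prior(Va_)
                return float(total)

            n_scaled = sum(
                p + int(anim[d].shared.sum()) + n + len(terms[d]) for d in range(nd)
            )
            log_accept = _lt(rc, c) - _lt(1.0, 1.0) + 0.5 * delta * n_scaled + delta * nd
            if np.log(rng.random() + 1e-300) < log_accept:
                for d in range(nd):
                    beta[d] = rc * beta[d]
                    anim[d].s = rc * anim[d].s
                    anim[d].Va = c * anim[d].Va
                    alpha[d] = rc * alpha[d]
                    latent[:, d] = rc * latent[:, d]
                    eta[:, d] = X @ beta[d] + anim[d].eta()
                    for t, u, a in zip(terms[d], us[d], alpha[d]):
                        eta[:, d] += a * u[t.g]

        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
            eta_full = eta if nd == 2 else np.column_stack(
                [eta[:, 0], np.full(n, -1e30)]
            )
            sds_now = np.ones((n, 2))
            for d in range(nd):
                sds_now[:, d] = np.sqrt(dim_sigma2(d))
            probs = _categorical_probs(eta_full, nodes, weights, sds_now)
            pobs = np.clip(probs[np.arange(n), y_codes.astype(int)], 1e-12, 1.0)
            dev = float(-2.0 * np.sum(np.log(pobs)))
            row: list[float] = []
            for d in range(nd):
                row.extend(beta[d])
                if marginal:
                    row.append(anim[d].Va)
                row.extend(alpha[d] ** 2 * s2[d] if px else s2[d])
            row.append(dev)
            records[kept] = row
            mean_eta += eta
            for d in range(nd):
                mean_sd_acc[:, d] += sds_now[:, d]
            kept += 1

    cols: list[str] = []
    var_cols: list[str] = []
    for d, cat in enumerate(dims):
        cols.extend(f"{nm}_{cat}" for nm in fixed_names)
        if marginal:
            names_d = ["Va"] + [_var_name(t.name) for t in terms[d]]
        else:
            names_d = [_var_name(t.name) for t in terms[d]]
        dim_vars = [f"{nm}_{cat}" for nm in names_d]
        cols.extend(dim_vars)
        var_cols.extend(dim_vars)
    cols.append("deviance")
    draws = pd.DataFrame(records[:kept], columns=cols)
    post = PosteriorDraws(
        draws=draws,
        response="categorical",
        variance_columns=tuple(var_cols),
        mean_eta=mean_eta / max(kept, 1),
        mean_ve=1.0,
        y=y_codes,
    )
    if marginal:
        post.mean_link_sd = mean_sd_acc / max(kept, 1)  # type: ignore[attr-defined]
    return post


def categorical_predicted_frequencies(posterior: PosteriorDraws) -> dict[str, float]:
    """Model-predicted L/P/M frequencies at the posterior mean predictors."""
    if posterior.response != "categorical":
        raise ValueError("needs a categorical fit")
    from numpy.polynomial.hermite_e import hermegauss

    nodes, weights = hermegauss(32)
    weights = weights / np.sqrt(2 * np.pi)
    eta = posterior.mean_eta
    sds = getattr(posterior, "mean_link_sd", None)
    if eta.shape[1] == 1:
        eta = np.column_stack([eta[:, 0], np.full(eta.shape[0], -1e30)])
        if sds is not None:
            sds = np.column_stack([sds[:, 0], np.ones(sds.shape[0])])
    probs = _categorical_probs(eta, nodes, weights, sds)
    mean_p = probs.mean(axis=0)
    return {c: float(mean_p[i]) for i, c in enumerate(_CATEGORIES)}


# ---------------------------------------------------------------------------
# model comparison and diagnostics


def dic(posterior: PosteriorDraws) -> float:
    """Deviance information criterion: DIC = D̄ + pD with pD = D̄ − D(θ̄),
    the deviance at the posterior mean linear predictor."""
    d_bar = float(posterior.draws["deviance"].mean())
    if posterior.response == "gaussian":
        d_hat = _deviance_gaussian(posterior.y, posterior.mean_eta, posterior.mean_ve)
    elif posterior.response == "binary":
        eta = posterior.mean_eta
        link_sd = getattr(posterior, "mean_link_sd", None)
        if link_sd is not None:
            eta = eta / link_sd
        d_hat = _deviance_binary(posterior.y, eta)
    else:
        from numpy.polynomial.hermite_e import hermegauss

        nodes, weights = hermegauss(32)
        weights = weights / np.sqrt(2 * np.pi)
        eta = posterior.mean_eta
        sds = getattr(posterior, "mean_link_sd", None)
        if sds is not None and sds.shape[1] == 1:
            sds = np.column_stack([sds[:, 0], np.ones(sds.shape[0])])
        if eta.shape[1] == 1:
            eta = np.column_stack([eta[:, 0], np.full(eta.shape[0], -1e30)])
        probs = _categorical_probs(eta, nodes, weights, sds)
        idx = posterior.y.astype(int)
        d_hat = float(-2 * np.sum(np.log(np.clip(probs[np.arange(len(idx)), idx], 1e-12, 1))))
    return float(2.0 * d_bar - d_hat)


def diagnostics(
    chain: PosteriorDraws | pd.DataFrame | np.ndarray,
    ess_threshold: float = 1000.0,
) -> pd.DataFrame:
    """Autocorrelation-based effective sample size per parameter.

    Returns a frame with ``ess`` and ``low_ess`` flags (ESS below the
    threshold; the conventional adequacy bar is 1000). Constant chains get
    ESS 0 and a flag. Needs at least 100 draws.
    """
    import arviz as az

    if isinstance(chain, PosteriorDraws):
        df = chain.draws.drop(columns=["deviance"], errors="ignore")
    elif isinstance(chain, pd.DataFrame):
        df = chain
    else:
        arr = np.atleast_2d(np.asarray(chain, float))
        if arr.shape[0] == 1:
            arr = arr.T
        df = pd.DataFrame(arr, columns=[f"param_{i}" for i in range(arr.shape[1])])
    if len(df) < 100:
        raise ValueError("need at least 100 post-burn-in draws for diagnostics")
    rows = {}
    for col in df.columns:
        x = df[col].to_numpy(float)
        if np.ptp(x) == 0 or not np.isfinite(x).all():
            rows[col] = 0.0
            continue
        rows[col] = float(az.ess(np.asarray(x)[None, :]))
    out = pd.DataFrame({"ess": pd.Series(rows)})
    out["low_ess"] = out["ess"] < ess_threshold
    for name, row in out[out["low_ess"]].iterrows():
        _log.warning("parameter %s has low ESS (%.0f < %.0f)", name, row["ess"], ess_threshold)
    return out
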
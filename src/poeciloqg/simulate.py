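"""Synthetic split-brood and selection-experiment data with liability structure.

The generator emulates the experimental design the analysis assumes:
maternal families of juvenile sea slugs split between low (16 ppt) and
high (32 ppt) salinity, reared singly in 12-well dishes, laying repeated
egg masses whose capsule diameters are bimodal (planktotrophic mode near
113 µm, lecithotrophic near 182 µm, within-mode SD 9.7 µm), with
occasional mixed clutches, salinity-dependent survival, and generations of
truncation selection for lecithotrophy propagated by self-fertilization.

Each individual carries a latent liability

    ℓ_i = µ + β·1[high salinity] + a_i + m_family + d_dish + id_i

with a clutch-specific residual e ~ N(0, Ve) added per egg mass; the
clutch develops lecithotrophically when its liability is positive. The
additive values a_i are drawn so that within-clutch relatedness matches
the declared assumption (maternal half-sibs by default); under selfing the
offspring breeding value is the parent's plus a Mendelian deviation with
variance Va(1 − F_parent)/2, and inbreeding accumulates as
F_child = (1 + F_parent)/2.

Default sizes and rates follow the study system: 17 families, ~13
individuals per family per salinity, survival 0.63 (low) / 0.81 (high),
~6.5% mixed clutches, and µ and β calibrated so the expected egg-mass
level proportions of lecithotrophy are 17.6% (low) and 25.7% (high).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .data_model import EggMassRecord, Individual, Pedigree, get_logger

__all__ = [
    "SimParams",
    "SimulatedDataset",
    "simulate_base_population",
    "simulate_selection_experiment",
    "simulate_egg_capsule_pairs",
]

_log = get_logger("simulate")

#: shared/independent split of Va implied by each within-clutch relatedness
#: assumption: (variance of family-shared component, variance of the
#: individual Mendelian component), as multiples of Va
_RELATEDNESS_SPLIT = {
    "half_sib": (0.25, 0.75),
    "full_sib_outcrossed": (0.5, 0.5),
    "full_sib_selfed": (1.0, 0.5),  # progeny of one selfing parent, F = 1/2
}


@dataclass(frozen=True)
class SimParams:
    n_families: int = 17
    n_per_family_per_env: int = 13
    mu_liability: float | None = None  # None -> calibrated to target proportions
    beta_salinity: float | None = None
    target_prop_L_low: float = 0.176
    target_prop_L_high: float = 0.257
    Va: float = 1.2
    Vm: float = 0.2
    Vdish: float = 0.05
    Vid: float = 0.2
    Ve: float = 1.0
    p_mixed: float = 0.065
    capsule_mode_P: float = 113.0
    capsule_mode_L: float = 182.0
    capsule_within_sd: float = 9.7
    egg_mean_L: float = 105.0
    egg_sd_L: float = 5.0
    egg_mean_P: float = 68.0
    egg_sd_P: float = 4.0
    survival_low: float = 0.63
    survival_high: float = 0.81
    eggmass_mean: float = 4.5  # Poisson mean clutches per laying individual
    eggmass_min: int = 1
    n_capsules_pure: int = 3
    n_capsules_mixed_per_mode: int = 3
    p_egg_measured: float = 0.25  # fraction of clutches with pre-cleavage egg sizes
    relatedness: str = "half_sib"
    heterogeneous_proportions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    switch_rate: float = 0.0  # optional Markov flip probability between clutches
    n_generations: int = 3
    n_offspring_per_selected: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("Va", "Vm", "Vdish", "Vid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.Ve <= 0:
            raise ValueError("Ve must be > 0")
        for name in ("p_mixed", "survival_low", "survival_high", "p_egg_measured",
                     "switch_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be a probability")
        if not self.capsule_mode_L > 150.0 > self.capsule_mode_P:
            raise ValueError("capsule modes must straddle the 150 µm threshold")
        if self.relatedness not in (*_RELATEDNESS_SPLIT, "heterogeneous"):
            raise ValueError(f"unknown relatedness {self.relatedness!r}")

    @property
    def total_liability_var(self) -> float:
        return self.Va + self.Vm + self.Vdish + self.Vid + self.Ve

    @property
    def h2_latent_true(self) -> float:
        return self.Va / self.total_liability_var

    def resolved_mu_beta(self) -> tuple[float, float]:
        """µ and β, calibrating to the target egg-mass proportions when unset.

        The expected proportion of pure lecithotrophic clutches is
        (1 − p_mixed)·Φ(µ_env/σ) with σ the total liability SD, so targets
        are inverted through that relation.
        """
        s = float(np.sqrt(self.total_liability_var))
        if self.mu_liability is not None and self.beta_salinity is not None:
            return self.mu_liability, self.beta_salinity
        scale = 1.0 - self.p_mixed
        mu = s * norm.ppf(min(self.target_prop_L_low / scale, 1 - 1e-9))
        mu_high = s * norm.ppf(min(self.target_prop_L_high / scale, 1 - 1e-9))
        if self.mu_liability is not None:
            mu = self.mu_liability
        beta = self.beta_salinity if self.beta_salinity is not None else mu_high - mu
        return float(mu), float(beta)


@dataclass
class SimulatedDataset:
    pedigree: Pedigree
    records: list[EggMassRecord] = field(repr=False)
    truth: dict = field(default_factory=dict)
    events: list[str] = field(default_factory=list)


def _family_split(params: SimParams, fam_index: int, rng) -> tuple[float, float]:
    """(shared, independent) variance split of Va for one family's clutch."""
    kind = params.relatedness
    if kind == "heterogeneous":
        kinds = list(_RELATEDNESS_SPLIT)
        kind = kinds[rng.choice(3, p=np.asarray(params.heterogeneous_proportions))]
    sh, ind = _RELATEDNESS_SPLIT[kind]
    return sh * params.Va, ind * params.Va


def _draw_capsules(mode: str, params: SimParams, rng) -> tuple[float, ...]:
    def draw(center: float, k: int) -> np.ndarray:
        out = center + params.capsule_within_sd * rng.standard_normal(k)
        return np.clip(out, 1.0, None)  # truncate at zero (practically: 1 µm)

    if mode == "L":
        vals = draw(params.capsule_mode_L, params.n_capsules_pure)
    elif mode == "P":
        vals = draw(params.capsule_mode_P, params.n_capsules_pure)
    else:  # mixed: both modes interleaved
        k = params.n_capsules_mixed_per_mode
        vals = np.concatenate([draw(params.capsule_mode_L, k), draw(params.capsule_mode_P, k)])
    return tuple(round(float(v), 1) for v in vals)


def _draw_eggs(mode: str, n: int, params: SimParams, rng) -> tuple[float, ...]:
    def draw(mean: float, sd: float, k: int) -> np.ndarray:
        return np.clip(mean + sd * rng.standard_normal(k), 1.0, None)

    if mode == "L":
        vals = draw(params.egg_mean_L, params.egg_sd_L, n)
    elif mode == "P":
        vals = draw(params.egg_mean_P, params.egg_sd_P, n)
    else:
        half = n // 2
        vals = np.concatenate(
            [draw(params.egg_mean_L, params.egg_sd_L, n - half),
             draw(params.egg_mean_P, params.egg_sd_P, half)]
        )
    return tuple(round(float(v), 1) for v in vals)


def _lay_egg_masses(
    ind: Individual,
    perm_liability: float,
    params: SimParams,
    rng,
    records: list[EggMassRecord],
) -> None:
    n_masses = max(params.eggmass_min, int(rng.poisson(params.eggmass_mean)))
    prev_mode: str | None = None
    for j in range(1, n_masses + 1):
        clutch_liab = perm_liability + np.sqrt(params.Ve) * rng.standard_normal()
        if rng.random() < params.p_mixed:
            mode = "M"
        else:
            mode = "L" if clutch_liab > 0 else "P"
        if (
            params.switch_rate > 0
            and prev_mode in ("L", "P")
            and mode in ("L", "P")
            and rng.random() < params.switch_rate
        ):
            mode = "P" if prev_mode == "L" else "L"
        capsules = _draw_capsules(mode, params, rng)
        eggs = (
            _draw_eggs(mode, len(capsules), params, rng)
            if rng.random() < params.p_egg_measured
            else None
        )
        records.append(
            EggMassRecord(
                eggmass_id=f"{ind.id}-em{j}",
                individual_id=ind.id,
                order_index=j,
                capsule_diams_um=capsules,
                egg_diams_um=eggs,
            )
        )
        prev_mode = mode


def simulate_base_population(params: SimParams) -> SimulatedDataset:
    """Simulate the first-generation split-brood design.

    Returns the pedigree (founders with unknown parents; within-family
    relatedness is carried by the declared assumption), the egg-mass
    records of surviving layers, and a truth dict with the generative
    parameters, per-individual liabilities and breeding values.
    """
    rng = np.random.default_rng(params.seed)
    mu, beta = params.resolved_mu_beta()
    individuals: list[Individual] = []
    records: list[EggMassRecord] = []
    liab: dict[str, float] = {}
    breeding: dict[str, float] = {}
    inbreeding: dict[str, float] = {}

    for f in range(params.n_families):
        fam = f"fam{f:02d}"
        v_shared, v_indep = _family_split(params, f, rng)
        a_shared = np.sqrt(v_shared) * rng.standard_normal()
        m_fam = np.sqrt(params.Vm) * rng.standard_normal()
        for env, env_flag in (("low16", 0.0), ("high32", 1.0)):
            n = params.n_per_family_per_env
            n_dishes = int(np.ceil(n / 12))
            dish_effects = np.sqrt(params.Vdish) * rng.standard_normal(n_dishes)
            surv_p = params.survival_low if env == "low16" else params.survival_high
            for k in range(n):
                iid = f"{fam}-{env}-{k:03d}"
                dish = f"{fam}-{env}-d{k // 12}"
                a = a_shared + np.sqrt(v_indep) * rng.standard_normal()
                id_eff = np.sqrt(params.Vid) * rng.standard_normal()
                perm = mu + beta * env_flag + a + m_fam + dish_effects[k // 12] + id_eff
                survived = rng.random() < surv_p
                ind = Individual(
                    id=iid, family=fam, site="synthetic", dish=dish,
                    salinity=env, generation="P", survived_to_lay=survived,
                )
                individuals.append(ind)
                liab[iid] = perm
                breeding[iid] = a
                inbreeding[iid] = 0.0
                if survived:
                    _lay_egg_masses(ind, perm, params, rng, records)

    pedigree = Pedigree(individuals)
    truth = {
        "mu": mu,
        "beta_salinity": beta,
        "Va": params.Va, "Vm": params.Vm, "Vdish": params.Vdish,
        "Vid": params.Vid, "Ve": params.Ve,
        "h2_latent": params.h2_latent_true,
        "liability": liab,
        "breeding_value": breeding,
        "inbreeding": inbreeding,
    }
    return SimulatedDataset(pedigree, records, truth)


def simulate_selection_experiment(params: SimParams) -> SimulatedDataset:
    """Simulate generations of truncation selection for lecithotrophy.

    Generation P is the base split-brood population; the parents of each
    following generation are exactly the lecithotrophic layers (individuals
    that laid at least one pure lecithotrophic clutch), each selfed. A
    salinity line with no lecithotrophic layers terminates with a logged
    event, mirroring how a low-salinity lineage can be lost.
    """
    if params.n_generations < 2:
        raise ValueError("n_generations must be >= 2")
    rng = np.random.default_rng([params.seed, 1])  # distinct from the base stream
    mu, beta = params.resolved_mu_beta()
    base = simulate_base_population(params)
    individuals = list(base.pedigree.individuals)
    records = list(base.records)
    truth = dict(base.truth)
    events: list[str] = []

    modes_by_ind: dict[str, set[str]] = {}
    for r in records:
        modes_by_ind.setdefault(r.individual_id, set()).add(r.mode)

    current: dict[str, list[Individual]] = {
        env: [i for i in individuals if i.salinity == env] for env in ("low16", "high32")
    }

    for g in range(1, params.n_generations):
        gen_label = f"S{g}"
        for env in ("low16", "high32"):
            parents = [
                ind for ind in current[env]
                if ind.survived_to_lay and "L" in modes_by_ind.get(ind.id, set())
            ]
            if not parents:
                msg = f"lineage terminated: no lecithotrophic layers in {env} at {gen_label}"
                events.append(msg)
                _log.info(msg)
                current[env] = []
                continue
            children: list[Individual] = []
            surv_p = params.survival_low if env == "low16" else params.survival_high
            for parent in parents:
                F_p = truth["inbreeding"][parent.id]
                a_p = truth["breeding_value"][parent.id]
                mend_sd = np.sqrt(0.5 * params.Va * (1.0 - F_p))
                m_fam = np.sqrt(params.Vm) * rng.standard_normal()  # maternal redraw
                for k in range(params.n_offspring_per_selected):
                    iid = f"{parent.id}-{gen_label}o{k:02d}"
                    dish = f"{parent.id}-{gen_label}-d{k // 12}"
                    a = a_p + mend_sd * rng.standard_normal()
                    id_eff = np.sqrt(params.Vid) * rng.standard_normal()
                    d_eff = np.sqrt(params.Vdish) * rng.standard_normal()
                    env_flag = 1.0 if env == "high32" else 0.0
                    perm = mu + beta * env_flag + a + m_fam + d_eff + id_eff
                    survived = rng.random() < surv_p
                    child = Individual(
                        id=iid, family=parent.family, site="synthetic", dish=dish,
                        salinity=env, generation=gen_label,
                        dam=parent.id, sire=parent.id, selfed=True,
                        survived_to_lay=survived,
                    )
                    children.append(child)
                    truth["breeding_value"][iid] = a
                    truth["liability"][iid] = perm
                    truth["inbreeding"][iid] = 0.5 * (1.0 + F_p)
                    if survived:
                        before = len(records)
                        _lay_egg_masses(child, perm, params, rng, records)
                        for r in records[before:]:
                            modes_by_ind.setdefault(iid, set()).add(r.mode)
            individuals.extend(children)
            current[env] = children

    pedigree = Pedigree(individuals)
    return SimulatedDataset(pedigree, records, truth, events)


def simulate_egg_capsule_pairs(
    params: SimParams, n: int, r2_target: float = 0.85
) -> np.ndarray:
    """Paired (egg, capsule) diameters with a linear relation of set r².

    Eggs come from the bimodal size distribution; capsule = α + β·egg plus
    Gaussian noise scaled so the population r² equals ``r2_target`` (noise
    is zero when the target is 1).
    """
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    if not 0 < r2_target <= 1:
        raise ValueError("r2_target must be in (0, 1]")
    rng = np.random.default_rng(params.seed)
    is_L = rng.random(n) < 0.5
    egg = np.where(
        is_L,
        params.egg_mean_L + params.egg_sd_L * rng.standard_normal(n),
        params.egg_mean_P + params.egg_sd_P * rng.standard_normal(n),
    )
    slope = (params.capsule_mode_L - params.capsule_mode_P) / (
        params.egg_mean_L - params.egg_mean_P
    )
    intercept = params.capsule_mode_P - slope * params.egg_mean_P
    # population egg variance of the 50:50 mixture
    mean_mix = 0.5 * (params.egg_mean_L + params.egg_mean_P)
    var_mix = (
        0.5 * (params.egg_sd_L**2 + (params.egg_mean_L - mean_mix) ** 2)
        + 0.5 * (params.egg_sd_P**2 + (params.egg_mean_P - mean_mix) ** 2)
    )
    signal_var = slope**2 * var_mix
    noise_var = signal_var * (1.0 - r2_target) / r2_target
    capsule = intercept + slope * egg + np.sqrt(noise_var) * rng.standard_normal(n)
    return np.column_stack([egg, capsule])
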
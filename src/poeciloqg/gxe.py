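"""Reaction norms, cross-environment genetic correlation, maternal effects.

A family reared in two environments can be read as expressing two
correlated traits; the regression of family-mean phenotype in one
environment on the other estimates how a response to selection in one
salinity should carry over to the other. Proportions of lecithotrophic
egg masses are computed at the egg-mass level (with an individual-level
option) and fitted untransformed, mirroring the conventional family-mean
treatment of threshold traits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .classify import classify_egg_mass
from .data_model import EggMassRecord, Pedigree, get_logger

__all__ = [
    "FamilyReactionNorm",
    "CrossEnvFit",
    "family_reaction_norms",
    "cross_env_correlation",
    "maternal_effect_model",
    "survival_proportion_regression",
]

_log = get_logger("gxe")

SMALL_FAMILY_N = 10  # families below this per-environment size get flagged


@dataclass(frozen=True)
class FamilyReactionNorm:
    family: str
    site: str
    n_low: int
    n_high: int
    prop_L_low: float
    prop_L_high: float
    small: bool  # fewer than SMALL_FAMILY_N egg masses in an environment

    @property
    def slope(self) -> float:
        return self.prop_L_high - self.prop_L_low


@dataclass(frozen=True)
class CrossEnvFit:
    slope: float
    intercept: float
    r2: float
    p: float
    pearson_r: float
    n_families: int


def family_reaction_norms(
    pedigree: Pedigree,
    records: Sequence[EggMassRecord],
    level: str = "eggmass",
    min_n: int = SMALL_FAMILY_N,
) -> list[FamilyReactionNorm]:
    """Per-family proportion of lecithotrophic egg masses in each salinity.

    ``level="eggmass"`` counts L calls over all clutches (the default);
    ``level="individual"`` counts lecithotrophic individuals (binary call
    from mean capsule). Families observed in only one environment are
    dropped with a warning; small families are flagged, not dropped.
    """
    if level not in ("eggmass", "individual"):
        raise ValueError("level must be 'eggmass' or 'individual'")
    by_ind = {ind.id: ind for ind in pedigree.individuals}
    rows = []
    for rec in records:
        ind = by_ind[rec.individual_id]
        rows.append(
            {
                "family": ind.family,
                "site": ind.site,
                "salinity": ind.salinity,
                "individual_id": ind.id,
                "is_L": classify_egg_mass(rec.capsule_diams_um).mode == "L",
                "capsules": rec.capsule_diams_um,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return []
    if level == "individual":
        per_ind = (
            df.groupby(["family", "site", "salinity", "individual_id"])["capsules"]
            .apply(lambda caps: np.mean([d for tup in caps for d in tup]) >= 150.0)
            .reset_index(name="is_L")
        )
        df = per_ind

    norms: list[FamilyReactionNorm] = []
    for (fam, site), sub in df.groupby(["family", "site"], sort=True):
        envs = set(sub["salinity"])
        if envs != {"low16", "high32"}:
            _log.warning("family %s observed in one environment only; dropped", fam)
            continue
        low = sub[sub["salinity"] == "low16"]["is_L"]
        high = sub[sub["salinity"] == "high32"]["is_L"]
        norms.append(
            FamilyReactionNorm(
                family=str(fam),
                site=str(site),
                n_low=len(low),
                n_high=len(high),
                prop_L_low=float(low.mean()),
                prop_L_high=float(high.mean()),
                small=min(len(low), len(high)) < min_n,
            )
        )
    return norms


def cross_env_correlation(norms: Sequence[FamilyReactionNorm]) -> CrossEnvFit:
    """Regress family proportion lecithotrophic in low salinity on high.

    The slope estimates the correlated response in low salinity per unit
    direct response in high salinity; the Pearson correlation is reported
    alongside as the direction-free summary.
    """
    if len(norms) < 3:
        raise ValueError("need at least 3 families")
    low = np.array([n.prop_L_low for n in norms])
    high = np.array([n.prop_L_high for n in norms])
    if np.ptp(high) == 0:
        raise ValueError("zero variance in high-salinity proportions (predictor)")
    res = sm.OLS(low, sm.add_constant(high)).fit()
    r = float(np.corrcoef(low, high)[0, 1]) if np.ptp(low) > 0 else 0.0
    return CrossEnvFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2=float(res.rsquared),
        p=float(res.pvalues[1]),
        pearson_r=r,
        n_families=len(norms),
    )


def maternal_effect_model(cells: pd.DataFrame) -> pd.DataFrame:
    """No-intercept OLS of per-cell proportion lecithotrophy on
    generation × rearing environment.

    ``cells`` has columns ``prop_L``, ``generation`` and ``rearing_env``
    (one row per family × generation × rearing cell). The no-intercept
    dummy parameterization makes each generation's coefficient the cell
    mean in the reference environment. Returns the coefficient table
    (coef, se, t, p) with overall F, its p-value and R² in ``.attrs``;
    rank deficiency is an error naming the aliased terms.
    """
    for col in ("prop_L", "generation", "rearing_env"):
        if col not in cells.columns:
            raise ValueError(f"cells table missing column {col!r}")
    gen = pd.get_dummies(cells["generation"], prefix="gen", dtype=float)
    env = pd.get_dummies(cells["rearing_env"], prefix="env", drop_first=True, dtype=float)
    X = gen.copy()
    for ec in env.columns:
        X[ec] = env[ec]
        for gc in gen.columns:
            X[f"{gc}:{ec}"] = gen[gc] * env[ec]
    # interaction dummies plus the environment main effect are collinear;
    # drop the main effect (cell-means coding within each environment)
    X = X.drop(columns=list(env.columns))
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.T @ X
        aliased = [c for c in X.columns if np.isclose(np.linalg.matrix_rank(
            X.drop(columns=[c]).to_numpy()), rank)]
        raise ValueError(f"design matrix rank deficient; aliased terms: {aliased}")
    res = sm.OLS(cells["prop_L"].to_numpy(float), X.to_numpy(float)).fit()
    table = pd.DataFrame(
        {"coef": res.params, "se": res.bse, "t": res.tvalues, "p": res.pvalues},
        index=list(X.columns),
    )
    table.attrs["F"] = float(res.fvalue)
    table.attrs["F_p"] = float(res.f_pvalue)
    table.attrs["r2"] = float(res.rsquared)
    return table


def survival_proportion_regression(
    families: pd.DataFrame,
) -> dict[str, tuple[float, float]]:
    """Per-environment OLS of family proportion lecithotrophic on survival.

    ``families`` has columns ``family``, ``salinity``, ``survival`` and
    ``prop_L``. Returns ``{salinity: (r2, p)}``. Fewer than 3 families or a
    constant survival column within an environment is an error.
    """
    out: dict[str, tuple[float, float]] = {}
    for env, sub in families.groupby("salinity"):
        if len(sub) < 3:
            raise ValueError(f"need at least 3 families in {env}")
        x = sub["survival"].to_numpy(float)
        y = sub["prop_L"].to_numpy(float)
        if np.ptp(x) == 0:
            raise ValueError(f"zero variance in survival in {env}")
        res = sm.OLS(y, sm.add_constant(x)).fit()
        out[str(env)] = (float(res.rsquared), float(res.pvalues[1]))
    return out
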
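"""Developmental-mode classification from egg-capsule diameters.

Capsule diameter is bimodal (small-capsule clutches develop as feeding
planktotrophic larvae, large-capsule clutches as nonfeeding lecithotrophic
larvae) and is used as the proxy for developmental mode: capsules at or
above 150 µm are scored lecithotrophic. A clutch containing both size
classes is a mixed egg mass. Individuals are scored binary from their mean
capsule diameter, with the 150 µm boundary assigned to lecithotrophy at
both levels for consistency.

Also here: the egg-diameter to capsule-diameter regression (capsule size is
measurable throughout development, egg size only before first cleavage),
per-individual lability profiles, and the logistic model for whether an
individual switched egg-mass type.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_model import CAPSULE_THRESHOLD_UM, EggMassRecord, get_logger

__all__ = [
    "ModeCall",
    "LabilityProfile",
    "classify_egg_mass",
    "classify_individual",
    "capsule_egg_regression",
    "lability_profiles",
    "switching_glm",
]

_log = get_logger("classify")


@dataclass(frozen=True)
class ModeCall:
    eggmass_id: str
    mode: str  # "L", "P" or "M"
    n_large: int
    n_small: int


@dataclass(frozen=True)
class LabilityProfile:
    individual_id: str
    modes_laid: frozenset[str]
    switched: bool
    pattern: str  # L_only, P_only, M_only, LP, PM, LM, LPM


def classify_egg_mass(
    capsule_diams_um: Sequence[float], eggmass_id: str = ""
) -> ModeCall:
    """Call a clutch L, P or M from its capsule diameters (µm).

    All capsules >= 150 µm -> lecithotrophic (L); all below -> planktotrophic
    (P); both size classes present -> mixed (M).
    """
    diams = np.asarray(capsule_diams_um, dtype=float)
    if diams.size == 0:
        raise ValueError("classify_egg_mass: empty capsule diameter list")
    if np.any(diams <= 0):
        raise ValueError("classify_egg_mass: capsule diameters must be positive")
    n_large = int(np.sum(diams >= CAPSULE_THRESHOLD_UM))
    n_small = int(diams.size - n_large)
    if n_large and n_small:
        mode = "M"
    elif n_large:
        mode = "L"
    else:
        mode = "P"
    return ModeCall(eggmass_id=eggmass_id, mode=mode, n_large=n_large, n_small=n_small)


def classify_individual(mean_capsule_um: float) -> int:
    """Binary developmental mode from an individual's mean capsule diameter.

    1 = lecithotrophic for means >= 150 µm (the exact boundary is assigned
    to lecithotrophy), 0 = planktotrophic.
    """
    if not mean_capsule_um > 0:
        raise ValueError("mean capsule diameter must be positive")
    return int(mean_capsule_um >= CAPSULE_THRESHOLD_UM)


def capsule_egg_regression(
    pairs: Sequence[tuple[float, float]] | np.ndarray,
) -> tuple[float, float, float, float]:
    """OLS of capsule diameter on egg diameter over (egg, capsule) µm pairs.

    Returns ``(slope, intercept, r2, p)`` where ``p`` is the slope's
    two-sided t-test p-value.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (egg, capsule) pairs")
    egg, capsule = arr[:, 0], arr[:, 1]
    if np.ptp(egg) == 0:
        raise ValueError("zero variance in egg diameter (predictor)")
    res = sm.OLS(capsule, sm.add_constant(egg)).fit()
    slope = float(res.params[1])
    intercept = float(res.params[0])
    r2 = float(res.rsquared)
    p = float(res.pvalues[1])
    return slope, intercept, r2, p


_PATTERNS = {
    frozenset("L"): "L_only",
    frozenset("P"): "P_only",
    frozenset("M"): "M_only",
    frozenset("LP"): "LP",
    frozenset("PM"): "PM",
    frozenset("LM"): "LM",
    frozenset("LPM"): "LPM",
}


def lability_profiles(
    records: Iterable[EggMassRecord],
) -> tuple[list[LabilityProfile], pd.Series]:
    """Per-individual set of egg-mass types laid, and pattern frequencies.

    An individual "switched" when it laid more than one type over the
    experiment. Frequencies are over individuals with at least one clutch
    and sum to one.
    """
    modes_by_ind: dict[str, set[str]] = {}
    for rec in records:
        call = classify_egg_mass(rec.capsule_diams_um, rec.eggmass_id)
        modes_by_ind.setdefault(rec.individual_id, set()).add(call.mode)
    profiles = [
        LabilityProfile(
            individual_id=iid,
            modes_laid=frozenset(modes),
            switched=len(modes) > 1,
            pattern=_PATTERNS[frozenset(modes)],
        )
        for iid, modes in sorted(modes_by_ind.items())
    ]
    counts = pd.Series([p.pattern for p in profiles]).value_counts()
    freqs = counts / counts.sum() if len(counts) else counts.astype(float)
    return profiles, freqs


def switching_glm(
    profiles: Sequence[LabilityProfile],
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Logistic regression of switching (laid >1 egg-mass type) on covariates.

    ``covariates`` is indexed/keyed by ``individual_id`` with categorical
    columns (e.g. salinity, generation, site), dummy-coded with a dropped
    reference level. Returns a coefficient table (coef, se, z, p) whose
    ``.attrs`` carry the model ``aic`` and a ``separation`` flag; complete
    separation is flagged and reported with a warning rather than raised.
    """
    cov = covariates.set_index("individual_id") if "individual_id" in covariates else covariates
    rows = []
    for p in profiles:
        if p.individual_id not in cov.index:
            raise ValueError(f"no covariates for individual {p.individual_id!r}")
        rows.append({"switched": int(p.switched), **cov.loc[p.individual_id].to_dict()})
    df = pd.DataFrame(rows)
    for col in df.columns.drop("switched"):
        if df[col].nunique() < 2:
            raise ValueError(f"covariate {col!r} has fewer than 2 levels")
    X = pd.get_dummies(df.drop(columns="switched"), drop_first=True, dtype=float)
    X = sm.add_constant(X)
    y = df["switched"].to_numpy(dtype=float)

    separation = False
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    try:
        with np.errstate(all="ignore"), _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
            separation = True
        eta = np.abs(fit.predict(X, which="linear"))
        if np.any(~np.isfinite(fit.bse)) or np.max(eta) > 15:
            separation = True
    except Exception:  # perfect separation can abort IRLS outright
        separation = True
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(alpha=1e-8)
    if separation:
        _log.warning("switching_glm: (quasi-)complete separation detected; "
                     "coefficients reported with caution")
    params = np.asarray(fit.params, dtype=float)
    bse = np.asarray(getattr(fit, "bse", np.full_like(params, np.nan)), dtype=float)
    with np.errstate(all="ignore"):
        z = params / bse
        from scipy.stats import norm

        pvals = 2 * norm.sf(np.abs(z))
    table = pd.DataFrame(
        {"coef": params, "se": bse, "z": z, "p": pvals}, index=list(X.columns)
    )
    table.attrs["aic"] = float(getattr(fit, "aic", np.nan))
    table.attrs["separation"] = separation
    return table
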
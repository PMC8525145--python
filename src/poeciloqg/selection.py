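"""Realized heritability from truncation selection.

For the threshold trait (developmental mode) the breeder's equation
R = h²S is applied on the liability scale via a probit transformation:
a proportion q of lecithotrophic layers maps to a liability mean
u = Φ⁻¹(q) (unit-variance liability, threshold at zero), selecting exactly
the upper tail gives a selection differential S = φ(Φ⁻¹(q))/q, and the
response is the change in u across generations. Summed realized
heritability is ΣR/ΣS over consecutive generations.

For the continuous trait (egg-capsule size) S and R are plain mean
differences; computation is in µm and reporting additionally in mm to
match the conventional table scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "SelectionStep",
    "ContinuousSelectionStep",
    "liability_mean",
    "threshold_selection_differential",
    "threshold_response",
    "realized_h2_threshold",
    "realized_h2_continuous",
]


@dataclass(frozen=True)
class SelectionStep:
    """One generation step of truncation selection on the liability scale."""

    generation_from: str
    generation_to: str
    q_pre: float
    q_post: float
    u_pre: float
    u_post: float
    S: float
    R: float
    h2: float


@dataclass(frozen=True)
class ContinuousSelectionStep:
    """One generation step for the continuous capsule-size trait (µm / mm)."""

    generation_from: str
    generation_to: str
    mean_all_um: float
    mean_selected_um: float
    mean_offspring_um: float
    S_um: float
    R_um: float
    S_mm: float
    R_mm: float
    h2: float | None  # None when S == 0 (undefined)


def _check_interior(q: float, name: str = "q") -> None:
    if not 0.0 < q < 1.0:
        raise ValueError(f"{name} must be strictly inside (0, 1); got {q}")


def liability_mean(q: float) -> float:
    """Mean u = Φ⁻¹(q) of a unit-variance liability with P(ℓ > 0) = q."""
    _check_interior(q)
    return float(norm.ppf(q))


def threshold_selection_differential(q: float) -> float:
    """Selection differential S = φ(Φ⁻¹(q))/q for truncating at the upper
    tail of a unit normal so that a fraction q is selected."""
    _check_interior(q)
    return float(norm.pdf(norm.ppf(q)) / q)


def threshold_response(q_pre: float, q_post: float) -> float:
    """Response R = Φ⁻¹(q_post) − Φ⁻¹(q_pre) on the liability scale."""
    _check_interior(q_pre, "q_pre")
    _check_interior(q_post, "q_post")
    return float(norm.ppf(q_post) - norm.ppf(q_pre))


def realized_h2_threshold(
    q_sequence: Sequence[float],
    generations: Sequence[str] | None = None,
) -> tuple[list[SelectionStep], float]:
    """Per-step and summed realized heritability for a threshold trait.

    ``q_sequence`` gives the proportion of lecithotrophic layers in each
    consecutive generation (the selected fraction being exactly the
    above-threshold tail). Summed h² divides the summed responses by the
    summed selection differentials.
    """
    qs = [float(q) for q in q_sequence]
    if len(qs) < 2:
        raise ValueError("need at least two generations of proportions")
    for q in qs:
        _check_interior(q)
    if generations is None:
        generations = ["P"] + [f"S{i}" for i in range(1, len(qs))]
    steps: list[SelectionStep] = []
    for i in range(len(qs) - 1):
        q_pre, q_post = qs[i], qs[i + 1]
        u_pre, u_post = liability_mean(q_pre), liability_mean(q_post)
        S = threshold_selection_differential(q_pre)
        R = u_post - u_pre
        steps.append(
            SelectionStep(
                generation_from=str(generations[i]),
                generation_to=str(generations[i + 1]),
                q_pre=q_pre,
                q_post=q_post,
                u_pre=u_pre,
                u_post=u_post,
                S=S,
                R=R,
                h2=R / S,
            )
        )
    summed_h2 = sum(s.R for s in steps) / sum(s.S for s in steps)
    return steps, float(summed_h2)


def realized_h2_continuous(
    means_per_generation_um: Sequence[float],
    selected_means_um: Sequence[float],
    generations: Sequence[str] | None = None,
) -> tuple[list[ContinuousSelectionStep], float]:
    """Per-step and summed realized heritability for capsule size.

    ``means_per_generation_um`` are the population mean capsule diameters of
    consecutive generations; ``selected_means_um`` the mean of the selected
    parents within each pre-selection generation (one fewer entry). Steps
    with S = 0 have undefined h² and are excluded from the summed ratio.
    A missing generation simply shortens the sequences: summation runs over
    the consecutive steps supplied.
    """
    means = [float(m) for m in means_per_generation_um]
    sel = [float(m) for m in selected_means_um]
    if len(means) < 2:
        raise ValueError("need at least two generations of means")
    if len(sel) != len(means) - 1:
        raise ValueError("need one selected-parent mean per selection step")
    if generations is None:
        generations = ["P"] + [f"S{i}" for i in range(1, len(means))]
    steps: list[ContinuousSelectionStep] = []
    for i in range(len(means) - 1):
        S_um = sel[i] - means[i]
        R_um = means[i + 1] - means[i]
        h2 = (R_um / S_um) if S_um != 0 else None
        steps.append(
            ContinuousSelectionStep(
                generation_from=str(generations[i]),
                generation_to=str(generations[i + 1]),
                mean_all_um=means[i],
                mean_selected_um=sel[i],
                mean_offspring_um=means[i + 1],
                S_um=S_um,
                R_um=R_um,
                S_mm=S_um / 1000.0,
                R_mm=R_um / 1000.0,
                h2=h2,
            )
        )
    usable = [s for s in steps if s.h2 is not None]
    if not usable:
        raise ValueError("all steps have zero selection differential")
    summed_h2 = sum(s.R_um for s in usable) / sum(s.S_um for s in usable)
    return steps, float(summed_h2)
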
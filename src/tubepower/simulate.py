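"""Hierarchical logit-normal binomial simulator for tube bioassays.

Data-generating process for a tube in a given arm on a given day::

    logit(p_tube) = logit(p_arm) + delta_day + eps_tube
    delta_day ~ Normal(0, between_day_sd**2)     (0 when days == 1)
    eps_tube  ~ Normal(0, within_day_sd**2)
    n_dead    ~ Binomial(n_exposed, p_tube)

``p_arm`` is the median tube mortality of the arm (the back-transform of
the logit-scale mean). Arm mortalities of exactly 0 or 1 are degenerate:
the logit is infinite, random effects cannot move the probability, and
counts are produced deterministically.

Day effects are drawn independently for each arm by default
(``day_effect_mode="independent"``): the between-day component then
degrades the two-arm comparison, which is what makes multi-day designs
less powerful. With ``"shared"`` both arms on a day receive the same
draw, and the day effect largely cancels out of the arm contrast.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit, logit

from .design import (
    ARMS,
    REFERENCE,
    TREATMENT,
    AssayDesign,
    EffectSpec,
    TubeObservation,
    VarianceAssumptions,
)

DAY_EFFECT_MODES = ("independent", "shared")


def _as_rng(random_state) -> np.random.Generator:
    if isinstance(random_state, np.random.Generator):
        return random_state
    return np.random.default_rng(random_state)


def simulate_tube_count(
    arm_mortality: float,
    day_effect: float,
    within_day_sd: float,
    n_exposed: int,
    rng,
) -> int:
    """Simulate the number of dead mosquitoes in a single tube.

    Degenerate mortalities (exactly 0 or 1) return 0 or ``n_exposed``
    deterministically without consuming random numbers.
    """
    if not (0.0 <= arm_mortality <= 1.0):
        raise ValueError(f"arm_mortality must lie in [0, 1], got {arm_mortality}")
    if within_day_sd < 0:
        raise ValueError("within_day_sd must be >= 0")
    if n_exposed < 1:
        raise ValueError("n_exposed must be >= 1")
    if arm_mortality == 0.0:
        return 0
    if arm_mortality == 1.0:
        return int(n_exposed)
    rng = _as_rng(rng)
    eps = rng.normal(0.0, within_day_sd) if within_day_sd > 0 else 0.0
    p_tube = expit(logit(arm_mortality) + day_effect + eps)
    return int(rng.binomial(n_exposed, p_tube))


def _arm_day_effects(
    design: AssayDesign,
    variance: VarianceAssumptions,
    rng: np.random.Generator,
    n_replicates: int,
) -> np.ndarray:
    """Day effects, shape (n_replicates, days); zero for single-day designs."""
    if design.days == 1 or variance.between_day_sd == 0:
        return np.zeros((n_replicates, design.days))
    return rng.normal(0.0, variance.between_day_sd, size=(n_replicates, design.days))


def _arm_counts(
    design: AssayDesign,
    arm_mortality: float,
    day_effects: np.ndarray,
    within_day_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-tube dead counts for one arm, shape (n_replicates, tubes_per_arm)."""
    reps = day_effects.shape[0]
    shape = (reps, design.tubes_per_arm)
    if arm_mortality == 0.0:
        return np.zeros(shape, dtype=np.int64)
    if arm_mortality == 1.0:
        return np.full(shape, design.mosquitoes_per_tube, dtype=np.int64)
    eps = (
        rng.normal(0.0, within_day_sd, size=shape)
        if within_day_sd > 0
        else np.zeros(shape)
    )
    eta = logit(arm_mortality) + day_effects[:, design.tube_days()] + eps
    return rng.binomial(design.mosquitoes_per_tube, expit(eta), size=shape)


def simulate_dataset(
    design: AssayDesign,
    effect: EffectSpec,
    variance: VarianceAssumptions,
    rng,
    day_effect_mode: str = "independent",
) -> list[TubeObservation]:
    """Simulate one complete two-arm bioassay dataset.

    Returns ``2 * tubes_per_arm`` observations. Tubes of both arms are
    spread over days per :attr:`AssayDesign.day_allocation`.
    """
    if day_effect_mode not in DAY_EFFECT_MODES:
        raise ValueError(f"day_effect_mode must be one of {DAY_EFFECT_MODES}")
    rng = _as_rng(rng)

    de_ref = _arm_day_effects(design, variance, rng, 1)
    de_treat = (
        de_ref
        if day_effect_mode == "shared"
        else _arm_day_effects(design, variance, rng, 1)
    )
    counts = {
        REFERENCE: _arm_counts(
            design, effect.reference_mortality, de_ref, variance.within_day_sd, rng
        )[0],
        TREATMENT: _arm_counts(
            design, effect.treatment_mortality, de_treat, variance.within_day_sd, rng
        )[0],
    }
    tube_days = design.tube_days()
    observations = []
    for arm in ARMS:
        for j in range(design.tubes_per_arm):
            observations.append(
                TubeObservation(
                    day_id=int(tube_days[j]) + 1,
                    tube_id=f"{arm[:3]}-{j + 1}",
                    arm=arm,
                    n_exposed=design.mosquitoes_per_tube,
                    n_dead=int(counts[arm][j]),
                )
            )
    return observations


def simulate_arm_totals(
    design: AssayDesign,
    effect: EffectSpec,
    variance: VarianceAssumptions,
    n_replicates: int,
    rng,
    day_effect_mode: str = "independent",
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate many datasets at once, returning per-arm death totals.

    The two-arm likelihood-ratio test depends on the data only through
    the arm totals, so the Monte-Carlo power engine works on arrays of
    shape ``(n_replicates,)`` rather than materialising tube records.
    """
    if day_effect_mode not in DAY_EFFECT_MODES:
        raise ValueError(f"day_effect_mode must be one of {DAY_EFFECT_MODES}")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = _as_rng(rng)
    de_ref = _arm_day_effects(design, variance, rng, n_replicates)
    de_treat = (
        de_ref
        if day_effect_mode == "shared"
        else _arm_day_effects(design, variance, rng, n_replicates)
    )
    dead_ref = _arm_counts(
        design, effect.reference_mortality, de_ref, variance.within_day_sd, rng
    ).sum(axis=1)
    dead_treat = _arm_counts(
        design, effect.treatment_mortality, de_treat, variance.within_day_sd, rng
    ).sum(axis=1)
    return dead_ref, dead_treat
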
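"""Domain types for WHO tube synergism bioassay designs.

A synergism experiment compares two treatment arms — pyrethroid-only
(*reference*) and pyrethroid + PBO (*treatment*) — each run as a set of
tubes of ~25 mosquitoes, possibly spread over several testing days. The
types here capture the design (tubes, days, tube size), the effect to be
detected (arm mortalities), the variability assumptions (logit-scale
within-day and between-day SDs), and the unit of observation (one tube's
24 h mortality count).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

REFERENCE = "reference"
TREATMENT = "treatment"
ARMS = (REFERENCE, TREATMENT)


def _check_proportion(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class AssayDesign:
    """Layout of one synergism bioassay.

    Parameters
    ----------
    tubes_per_arm : int
        Number of tubes of each treatment (a "4x4 design" has 4).
    days : int
        Number of testing days the tubes are spread over.
    mosquitoes_per_tube : int
        Mosquitoes exposed per tube (WHO default 25).
    """

    tubes_per_arm: int
    days: int = 1
    mosquitoes_per_tube: int = 25

    def __post_init__(self) -> None:
        if self.tubes_per_arm < 1:
            raise ValueError("tubes_per_arm must be >= 1")
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if self.days > self.tubes_per_arm:
            raise ValueError(
                f"days ({self.days}) cannot exceed tubes_per_arm "
                f"({self.tubes_per_arm}): at least one tube per day group"
            )
        if self.mosquitoes_per_tube < 1:
            raise ValueError("mosquitoes_per_tube must be >= 1")

    @property
    def day_allocation(self) -> tuple[int, ...]:
        """Tubes per day, spread as evenly as possible, remainder to the
        earliest days (5 tubes over 2 days -> (3, 2))."""
        base, rem = divmod(self.tubes_per_arm, self.days)
        return tuple([base + 1] * rem + [base] * (self.days - rem))

    def tube_days(self) -> np.ndarray:
        """Day index (0-based) of each of the ``tubes_per_arm`` tubes."""
        return np.repeat(np.arange(self.days), self.day_allocation)

    @property
    def mosquitoes_per_arm(self) -> int:
        return self.tubes_per_arm * self.mosquitoes_per_tube


@dataclass(frozen=True)
class EffectSpec:
    """Arm mortalities: treatment = reference + difference."""

    reference_mortality: float
    mortality_difference: float

    def __post_init__(self) -> None:
        _check_proportion(self.reference_mortality, "reference_mortality")
        if self.mortality_difference < 0:
            raise ValueError("mortality_difference must be >= 0")
        if self.reference_mortality + self.mortality_difference > 1.0 + 1e-12:
            raise ValueError(
                "reference_mortality + mortality_difference must be <= 1, got "
                f"{self.reference_mortality} + {self.mortality_difference}"
            )

    @property
    def treatment_mortality(self) -> float:
        return min(1.0, self.reference_mortality + self.mortality_difference)


@dataclass(frozen=True)
class VarianceAssumptions:
    """Logit-scale standard deviations of the random effects.

    ``within_day_sd`` is the SD of the per-tube intercept (tube-to-tube
    variation on a day); ``between_day_sd`` the SD of the per-day
    intercept (systematic day-to-day variation).
    """

    within_day_sd: float
    between_day_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.within_day_sd < 0:
            raise ValueError("within_day_sd must be >= 0")
        if self.between_day_sd < 0:
            raise ValueError("between_day_sd must be >= 0")


@dataclass(frozen=True)
class TubeObservation:
    """One tube's 24 h mortality outcome.

    ``extra`` carries pass-through metadata columns (e.g. weights,
    temperature) from a source file; it is never modelled.
    """

    day_id: int
    tube_id: str
    arm: str
    n_exposed: int
    n_dead: int
    extra: Mapping[str, object] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if self.n_exposed < 1:
            raise ValueError("n_exposed must be >= 1")
        if not (0 <= self.n_dead <= self.n_exposed):
            raise ValueError(
                f"n_dead must lie in [0, n_exposed], got {self.n_dead}/{self.n_exposed}"
            )

    @property
    def mortality(self) -> float:
        return self.n_dead / self.n_exposed
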
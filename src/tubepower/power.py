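"""Monte-Carlo power estimation and sample-size guidance.

Power for a given design, effect and variance assumption is estimated by
simulating many two-arm datasets under the hierarchical logit-normal
binomial model and counting the proportion in which the likelihood-ratio
test rejects at the chosen significance level. On top of that single
estimate sit a full parameter-grid evaluator with a persistent CSV
cache, a minimum-detectable-difference scan on the 2.5% grid, and a
minimum-tubes search.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from . import __version__ as _version
from .design import AssayDesign, EffectSpec, VarianceAssumptions
from .inference import lrt_statistic_from_totals
from .simulate import DAY_EFFECT_MODES, _as_rng, simulate_arm_totals

logger = logging.getLogger(__name__)

DEFAULT_DIFFERENCES = tuple(np.round(np.arange(0, 21) * 0.025, 4))
DEFAULT_TUBES = (4, 5, 6, 7, 8, 9, 10)
DEFAULT_DAYS = (1, 2, 3, 4, 5)
DEFAULT_WITHIN_SDS = (0.15, 0.20, 0.25, 0.30, 0.35)
DEFAULT_BETWEEN_SDS = (0.40, 0.50, 0.60, 0.70, 0.80)

_GRID_COLUMNS = [
    "difference",
    "tubes_per_arm",
    "days",
    "within_day_sd",
    "between_day_sd",
    "reference_mortality",
    "mosquitoes_per_tube",
    "alpha",
    "replicates",
    "seed",
    "power",
    "mc_standard_error",
]
_KEY_COLUMNS = _GRID_COLUMNS[:7]


@dataclass(frozen=True)
class PowerEstimate:
    """Estimated power at one parameter combination, with Monte-Carlo error."""

    design: AssayDesign
    effect: EffectSpec
    variance: VarianceAssumptions
    alpha: float
    replicates: int
    power: float
    mc_standard_error: float
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "tubes_per_arm": self.design.tubes_per_arm,
            "days": self.design.days,
            "mosquitoes_per_tube": self.design.mosquitoes_per_tube,
            "reference_mortality": self.effect.reference_mortality,
            "difference": self.effect.mortality_difference,
            "within_day_sd": self.variance.within_day_sd,
            "between_day_sd": self.variance.between_day_sd,
            "alpha": self.alpha,
            "replicates": self.replicates,
            "power": self.power,
            "mc_standard_error": self.mc_standard_error,
            "seed": self.seed,
        }


def estimate_power(
    design: AssayDesign,
    effect: EffectSpec,
    variance: VarianceAssumptions,
    alpha: float = 0.05,
    replicates: int = 10_000,
    random_state=None,
    day_effect_mode: str = "independent",
) -> PowerEstimate:
    """Monte-Carlo power of the two-arm LRT under the simulator's DGP.

    Simulates ``replicates`` datasets, scores each with the
    likelihood-ratio test and returns the rejection proportion together
    with its binomial Monte-Carlo standard error. Deterministic for a
    fixed integer ``random_state``.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = _as_rng(random_state)
    dead_ref, dead_treat = simulate_arm_totals(
        design, effect, variance, replicates, rng, day_effect_mode
    )
    n_arm = design.mosquitoes_per_arm
    stat = lrt_statistic_from_totals(dead_ref, n_arm, dead_treat, n_arm)
    power = float(np.mean(chi2.sf(stat, 1) < alpha))
    return PowerEstimate(
        design=design,
        effect=effect,
        variance=variance,
        alpha=alpha,
        replicates=replicates,
        power=power,
        mc_standard_error=float(np.sqrt(power * (1 - power) / replicates)),
        seed=random_state if isinstance(random_state, (int, np.integer)) else None,
    )


@dataclass(frozen=True)
class SimulationGrid:
    """Cartesian parameter grid for precomputing power estimates."""

    differences: Sequence[float] = DEFAULT_DIFFERENCES
    tubes_per_arm: Sequence[int] = DEFAULT_TUBES
    days: Sequence[int] = DEFAULT_DAYS
    within_day_sds: Sequence[float] = DEFAULT_WITHIN_SDS
    between_day_sds: Sequence[float] = DEFAULT_BETWEEN_SDS
    reference_mortality: float = 0.5
    mosquitoes_per_tube: int = 25
    alpha: float = 0.05
    replicates: int = 10_000
    base_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("differences", "tubes_per_arm", "days", "within_day_sds", "between_day_sds"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be nonempty")
        steps = np.diff(sorted(self.differences))
        if len(steps) and not np.allclose(steps, steps[0]):
            raise ValueError("differences must lie on an evenly spaced grid")
        if not (0 <= self.reference_mortality <= 1):
            raise ValueError("reference_mortality must lie in [0, 1]")

    def combinations(self) -> Iterable[tuple]:
        for diff in self.differences:
            for tubes in self.tubes_per_arm:
                for days in self.days:
                    for sw in self.within_day_sds:
                        for sb in self.between_day_sds:
                            yield (diff, tubes, days, sw, sb)

    @property
    def n_combinations(self) -> int:
        return (
            len(self.differences)
            * len(self.tubes_per_arm)
            * len(self.days)
            * len(self.within_day_sds)
            * len(self.between_day_sds)
        )

    def to_dict(self) -> dict:
        return {
            "differences": list(map(float, self.differences)),
            "tubes_per_arm": list(map(int, self.tubes_per_arm)),
            "days": list(map(int, self.days)),
            "within_day_sds": list(map(float, self.within_day_sds)),
            "between_day_sds": list(map(float, self.between_day_sds)),
            "reference_mortality": self.reference_mortality,
            "mosquitoes_per_tube": self.mosquitoes_per_tube,
            "alpha": self.alpha,
            "replicates": self.replicates,
            "base_seed": self.base_seed,
        }


def combination_seed(base_seed: int, *params) -> int:
    """Stable per-combination seed: CRC32 of the canonical parameter tuple.

    Combined with ``base_seed`` in a :class:`numpy.random.SeedSequence`
    so any grid cell can be reproduced in isolation.
    """
    key = repr(tuple(round(float(p), 10) for p in params)).encode()
    return zlib.crc32((str(int(base_seed)) + ":").encode() + key) & 0x7FFFFFFF


def _cell_rng(base_seed: int, combo_seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(base_seed, spawn_key=(combo_seed,)))


def power_grid(
    grid: SimulationGrid,
    resume_from: pd.DataFrame | None = None,
    day_effect_mode: str = "independent",
    progress_every: int = 0,
) -> pd.DataFrame:
    """Evaluate power over every combination of a :class:`SimulationGrid`.

    Each cell is seeded from ``base_seed`` plus a stable hash of its
    parameters, so a run is bit-reproducible and resumable: rows already
    present in ``resume_from`` (matched on the parameter columns) are
    reused, remaining cells are computed.
    """
    done: dict[tuple, dict] = {}
    if resume_from is not None and len(resume_from):
        for _, row in resume_from.iterrows():
            done[tuple(round(float(row[c]), 10) for c in _KEY_COLUMNS)] = row.to_dict()

    rows = []
    for i, (diff, tubes, days, sw, sb) in enumerate(grid.combinations()):
        key = tuple(
            round(float(v), 10)
            for v in (
                diff,
                tubes,
                days,
                sw,
                sb,
                grid.reference_mortality,
                grid.mosquitoes_per_tube,
            )
        )
        if key in done:
            rows.append(done[key])
            continue
        if grid.reference_mortality + diff > 1:
            logger.warning(
                "skipping combination difference=%s: reference + difference > 1", diff
            )
            continue
        seed = combination_seed(
            grid.base_seed, diff, tubes, days, sw, sb, grid.reference_mortality
        )
        est = estimate_power(
            AssayDesign(tubes, days, grid.mosquitoes_per_tube),
            EffectSpec(grid.reference_mortality, diff),
            VarianceAssumptions(sw, sb),
            alpha=grid.alpha,
            replicates=grid.replicates,
            random_state=_cell_rng(grid.base_seed, seed),
            day_effect_mode=day_effect_mode,
        )
        rows.append(
            {
                "difference": float(diff),
                "tubes_per_arm": int(tubes),
                "days": int(days),
                "within_day_sd": float(sw),
                "between_day_sd": float(sb),
                "reference_mortality": float(grid.reference_mortality),
                "mosquitoes_per_tube": int(grid.mosquitoes_per_tube),
                "alpha": float(grid.alpha),
                "replicates": int(grid.replicates),
                "seed": int(seed),
                "power": est.power,
                "mc_standard_error": est.mc_standard_error,
            }
        )
        if progress_every and (i + 1) % progress_every == 0:
            logger.info("power_grid: %d/%d combinations done", i + 1, grid.n_combinations)
    table = pd.DataFrame(rows, columns=_GRID_COLUMNS)
    int_cols = ["tubes_per_arm", "days", "mosquitoes_per_tube", "replicates", "seed"]
    return table.astype(
        {c: (np.int64 if c in int_cols else np.float64) for c in _GRID_COLUMNS}
    )


def save_grid(table: pd.DataFrame, path, grid: SimulationGrid | None = None) -> None:
    """Persist a grid table as CSV plus a JSON metadata sidecar."""
    path = str(path)
    table.to_csv(path, index=False)
    meta = {"version": _version, "columns": list(table.columns), "n_rows": int(len(table))}
    if grid is not None:
        meta["grid"] = grid.to_dict()
    with open(path + ".meta.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def load_grid(path) -> pd.DataFrame:
    """Load a grid cache written by :func:`save_grid`, validating each row."""
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"grid cache {path!s} is empty or unparsable") from exc
    missing = [c for c in _GRID_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"grid cache {path!s} is missing columns {missing}")
    bad = table.index[(table["power"] < 0) | (table["power"] > 1) | table["power"].isna()]
    if len(bad):
        raise ValueError(f"grid cache {path!s}: invalid power value at row {bad[0] + 2}")
    return table


def lookup_power(table: pd.DataFrame, **params) -> pd.Series:
    """Exact-match lookup of a precomputed grid cell (never interpolates)."""
    mask = np.ones(len(table), dtype=bool)
    for name, value in params.items():
        if name not in table.columns:
            raise KeyError(f"unknown grid column {name!r}")
        mask &= np.isclose(table[name].to_numpy(dtype=float), float(value))
    hits = table[mask]
    if len(hits) == 0:
        raise LookupError(f"combination {params} not precomputed in this grid")
    return hits.iloc[0]


def min_detectable_difference(
    design: AssayDesign,
    variance: VarianceAssumptions,
    reference_mortality: float = 0.5,
    power_target: float = 0.80,
    alpha: float = 0.05,
    replicates: int = 10_000,
    random_state=None,
    differences: Sequence[float] = DEFAULT_DIFFERENCES,
    day_effect_mode: str = "independent",
) -> float | None:
    """Smallest mortality difference on the grid detectable at ``power_target``.

    Scans the difference grid in increasing order and returns the first
    value whose estimated power reaches the target (first-crossing
    rule), or ``None`` when no grid value qualifies. Differences that
    would push the treatment arm past 100% mortality are dropped with a
    warning.
    """
    rng = _as_rng(random_state)
    scan = [d for d in sorted(differences) if reference_mortality + d <= 1 + 1e-12]
    if len(scan) < len(differences):
        logger.warning(
            "difference scan truncated at %.3f (reference mortality %.3f)",
            1 - reference_mortality,
            reference_mortality,
        )
    for diff in scan:
        est = estimate_power(
            design,
            EffectSpec(reference_mortality, diff),
            variance,
            alpha=alpha,
            replicates=replicates,
            random_state=rng,
            day_effect_mode=day_effect_mode,
        )
        if est.power >= power_target:
            return float(diff)
    return None


def min_tubes_for_difference(
    difference: float,
    variance: VarianceAssumptions,
    reference_mortality: float = 0.5,
    days: int = 1,
    power_target: float = 0.80,
    tubes_range: Sequence[int] = DEFAULT_TUBES,
    alpha: float = 0.05,
    replicates: int = 10_000,
    random_state=None,
    mosquitoes_per_tube: int = 25,
    day_effect_mode: str = "independent",
) -> int | None:
    """Smallest tubes-per-arm in range reaching ``power_target``.

    Returns ``None`` when no candidate in the range achieves the target
    (the required sample size lies outside the simulation framework).
    Candidates smaller than the number of days are skipped with a
    warning.
    """
    rng = _as_rng(random_state)
    effect = EffectSpec(reference_mortality, difference)
    for tubes in sorted(tubes_range):
        if tubes < days:
            logger.warning("skipping %d tubes/arm: fewer tubes than days (%d)", tubes, days)
            continue
        est = estimate_power(
            AssayDesign(tubes, days, mosquitoes_per_tube),
            effect,
            variance,
            alpha=alpha,
            replicates=replicates,
            random_state=rng,
            day_effect_mode=day_effect_mode,
        )
        if est.power >= power_target:
            return int(tubes)
    return None


def power_curve(
    design: AssayDesign,
    variance: VarianceAssumptions,
    reference_mortality: float = 0.5,
    differences: Sequence[float] = DEFAULT_DIFFERENCES,
    alpha: float = 0.05,
    replicates: int = 10_000,
    random_state=None,
    day_effect_mode: str = "independent",
) -> pd.DataFrame:
    """Power as a function of mortality difference for one design."""
    rng = _as_rng(random_state)
    rows = []
    for diff in sorted(differences):
        if reference_mortality + diff > 1 + 1e-12:
            continue
        est = estimate_power(
            design,
            EffectSpec(reference_mortality, diff),
            variance,
            alpha=alpha,
            replicates=replicates,
            random_state=rng,
            day_effect_mode=day_effect_mode,
        )
        rows.append(
            {"difference": float(diff), "power": est.power, "mc_standard_error": est.mc_standard_error}
        )
    return pd.DataFrame(rows)


def plot_power_curve(curve: pd.DataFrame, ax=None, power_target: float = 0.80):
    """Plot a power curve (matplotlib required only here)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve["difference"] * 100, curve["power"], marker="o")
    ax.axhline(power_target, color="red", linestyle="--", linewidth=1)
    ax.set_xlabel("mortality difference (%)")
    ax.set_ylabel("power")
    ax.set_ylim(0, 1.02)
    return ax
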
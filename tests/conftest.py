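import numpy as np
import pytest

from tubepower import (
    AssayDesign,
    EffectSpec,
    TubeObservation,
    VarianceAssumptions,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def basic_design():
    return AssayDesign(tubes_per_arm=4, days=1, mosquitoes_per_tube=25)


def make_two_arm(dead_ref, n_ref, dead_treat, n_treat, tubes=1):
    """Build a two-arm observation list with given arm totals, spread
    over `tubes` tubes per arm (last tube takes the remainder)."""
    obs = []
    for arm, dead, n in (("reference", dead_ref, n_ref), ("treatment", dead_treat, n_treat)):
        per_tube_n = n // tubes
        remaining_dead = dead
        for j in range(tubes):
            n_j = per_tube_n if j < tubes - 1 else n - per_tube_n * (tubes - 1)
            d_j = min(remaining_dead, n_j)
            remaining_dead -= d_j
            obs.append(
                TubeObservation(
                    day_id=1, tube_id=f"{arm}-{j}", arm=arm, n_exposed=n_j, n_dead=d_j
                )
            )
    return obs


@pytest.fixture
def scenario_b_variance():
    return VarianceAssumptions(within_day_sd=0.25, between_day_sd=0.60)
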
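"""Monte-Carlo power engine: calibration, monotonicity, grid cache."""

import logging

import numpy as np
import pytest
from scipy.stats import binom, chi2

from tubepower import (
    AssayDesign,
    EffectSpec,
    SimulationGrid,
    VarianceAssumptions,
    estimate_power,
    load_grid,
    lookup_power,
    min_detectable_difference,
    min_tubes_for_difference,
    power_grid,
    save_grid,
)
from tubepower.inference import lrt_statistic_from_totals
from tubepower.power import combination_seed

NO_NOISE = VarianceAssumptions(0.0, 0.0)
SD25 = VarianceAssumptions(0.25, 0.0)


def exact_lrt_size(n_arm, p, alpha=0.05):
    """Exact type-I error of the chi-square LRT for two Binomial(n_arm, p)
    arms, by exhaustive enumeration of the joint outcome lattice."""
    d = np.arange(n_arm + 1)
    pr = binom.pmf(d, n_arm, p)
    stat = lrt_statistic_from_totals(d[:, None], n_arm, d[None, :], n_arm)
    reject = chi2.sf(stat, 1) < alpha
    return float((pr[:, None] * pr[None, :] * reject).sum())


class TestEstimatePower:
    def test_monte_carlo_error_formula(self, basic_design):
        est = estimate_power(
            basic_design, EffectSpec(0.5, 0.3), SD25, replicates=2000, random_state=0
        )
        assert est.mc_standard_error == pytest.approx(
            np.sqrt(est.power * (1 - est.power) / 2000)
        )
        assert 0 <= est.power <= 1

    def test_deterministic_given_seed(self, basic_design):
        a = estimate_power(basic_design, EffectSpec(0.5, 0.2), SD25, replicates=3000, random_state=11)
        b = estimate_power(basic_design, EffectSpec(0.5, 0.2), SD25, replicates=3000, random_state=11)
        assert a.power == b.power

    def test_type_one_error_matches_enumeration_oracle(self, basic_design):
        """At zero SDs the simulated null rejection rate must match the
        exactly enumerated size of the test for the same design."""
        reps = 40_000
        est = estimate_power(
            basic_design, EffectSpec(0.5, 0.0), NO_NOISE, replicates=reps, random_state=5
        )
        exact = exact_lrt_size(100, 0.5)
        se = np.sqrt(exact * (1 - exact) / reps)
        assert est.power == pytest.approx(exact, abs=3 * se)

    def test_type_one_error_near_nominal_for_large_design(self):
        """At 10 tubes (250 mosquitoes per arm) the exact size of the
        discrete chi-square LRT sits within half a point of the nominal
        5%, and the simulation reproduces that exact size."""
        design = AssayDesign(10, 1, 25)
        exact = exact_lrt_size(250, 0.5)
        assert exact == pytest.approx(0.05, abs=0.005)
        reps = 20_000
        est = estimate_power(
            design, EffectSpec(0.5, 0.0), NO_NOISE, replicates=reps, random_state=6
        )
        se = np.sqrt(exact * (1 - exact) / reps)
        assert est.power == pytest.approx(exact, abs=3 * se)

    def test_power_monotone_in_difference(self, basic_design):
        reps = 5000
        powers = [
            estimate_power(
                basic_design, EffectSpec(0.5, d), SD25, replicates=reps, random_state=21
            ).power
            for d in (0.10, 0.20, 0.30)
        ]
        tol = 3 * np.sqrt(0.25 / reps)
        assert powers[0] <= powers[1] + tol <= powers[2] + 2 * tol

    def test_power_monotone_in_tubes(self):
        reps = 5000
        powers = [
            estimate_power(
                AssayDesign(t, 1), EffectSpec(0.5, 0.2), SD25, replicates=reps, random_state=22
            ).power
            for t in (4, 7, 10)
        ]
        tol = 3 * np.sqrt(0.25 / reps)
        assert powers[0] <= powers[1] + tol <= powers[2] + 2 * tol

    def test_splitting_over_days_never_helps(self, scenario_b_variance):
        reps = 8000
        effect = EffectSpec(0.5, 0.25)
        one_day = estimate_power(
            AssayDesign(4, 1), effect, scenario_b_variance, replicates=reps, random_state=23
        ).power
        two_days = estimate_power(
            AssayDesign(4, 2), effect, scenario_b_variance, replicates=reps, random_state=24
        ).power
        assert two_days <= one_day + 3 * np.sqrt(0.5 / reps)

    def test_boundary_mortality_easier_than_midrange(self):
        """A 10% difference against a 100% arm is far easier to detect than
        the same difference centred at 50% (proportions near the boundary
        have almost no variance)."""
        reps = 5000
        at_boundary = estimate_power(
            AssayDesign(4, 1), EffectSpec(0.90, 0.10), SD25, replicates=reps, random_state=25
        ).power
        midrange = estimate_power(
            AssayDesign(4, 1), EffectSpec(0.45, 0.10), SD25, replicates=reps, random_state=26
        ).power
        assert at_boundary > midrange + 3 * np.sqrt(0.5 / reps)

    def test_invalid_inputs(self, basic_design):
        with pytest.raises(ValueError):
            estimate_power(basic_design, EffectSpec(0.5, 0.2), SD25, alpha=1.5)
        with pytest.raises(ValueError):
            estimate_power(basic_design, EffectSpec(0.5, 0.2), SD25, replicates=0)


class TestGrid:
    def test_default_grid_size_matches_parameter_table(self):
        assert SimulationGrid().n_combinations == 21 * 7 * 5 * 5 * 5 == 18_375

    def test_uneven_difference_grid_rejected(self):
        with pytest.raises(ValueError):
            SimulationGrid(differences=(0.0, 0.1, 0.15))

    def small_grid(self, reps=200, seed=9):
        return SimulationGrid(
            differences=(0.0, 0.25),
            tubes_per_arm=(4, 6),
            days=(1,),
            within_day_sds=(0.25,),
            between_day_sds=(0.60,),
            replicates=reps,
            base_seed=seed,
        )

    def test_shape_contract(self):
        table = power_grid(self.small_grid())
        assert len(table) == 4
        assert ((table["power"] >= 0) & (table["power"] <= 1)).all()
        expected_se = np.sqrt(table["power"] * (1 - table["power"]) / table["replicates"])
        assert np.allclose(table["mc_standard_error"], expected_se)

    def test_bit_reproducible_and_cell_isolated(self):
        grid = self.small_grid()
        a = power_grid(grid)
        b = power_grid(grid)
        assert a.equals(b)
        # any cell is reproducible in isolation from base_seed + params
        row = a.iloc[2]
        from tubepower.power import _cell_rng

        seed = combination_seed(
            grid.base_seed,
            row["difference"], row["tubes_per_arm"], row["days"],
            row["within_day_sd"], row["between_day_sd"], row["reference_mortality"],
        )
        est = estimate_power(
            AssayDesign(int(row["tubes_per_arm"]), int(row["days"])),
            EffectSpec(row["reference_mortality"], row["difference"]),
            VarianceAssumptions(row["within_day_sd"], row["between_day_sd"]),
            replicates=int(row["replicates"]),
            random_state=_cell_rng(grid.base_seed, seed),
        )
        assert est.power == row["power"]

    def test_extreme_effect_saturates(self):
        grid = SimulationGrid(
            differences=(0.5,), tubes_per_arm=(10,), days=(1,),
            within_day_sds=(0.25,), between_day_sds=(0.40,),
            replicates=2000, base_seed=3,
        )
        table = power_grid(grid)
        assert (table["power"] >= 0.99).all()

    def test_resume_reuses_rows(self):
        grid = self.small_grid()
        full = power_grid(grid)
        partial = full.iloc[:2]
        resumed = power_grid(grid, resume_from=partial)
        assert resumed.reset_index(drop=True).equals(full.reset_index(drop=True))

    def test_save_load_roundtrip(self, tmp_path):
        table = power_grid(self.small_grid())
        path = tmp_path / "grid.csv"
        save_grid(table, path, self.small_grid())
        loaded = load_grid(path)
        assert np.allclose(loaded["power"], table["power"])
        assert (path.parent / "grid.csv.meta.json").exists()

    def test_load_empty_file_errors(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            load_grid(path)

    def test_lookup_never_interpolates(self):
        table = power_grid(self.small_grid())
        hit = lookup_power(table, difference=0.25, tubes_per_arm=4)
        assert hit["power"] == table.iloc[2]["power"]
        with pytest.raises(LookupError, match="not precomputed"):
            lookup_power(table, difference=0.125)


class TestSearches:
    def test_mdd_degenerate_target_is_zero(self, basic_design):
        assert (
            min_detectable_difference(
                basic_design, SD25, power_target=0.0, replicates=10, random_state=0
            )
            == 0.0
        )

    def test_mdd_truncates_scan_with_warning(self, basic_design, caplog):
        with caplog.at_level(logging.WARNING, logger="tubepower.power"):
            min_detectable_difference(
                basic_design,
                SD25,
                reference_mortality=0.8,
                power_target=1.1,  # unreachable -> scans everything
                replicates=10,
                random_state=0,
            )
        assert "truncated" in caplog.text

    def test_mdd_returns_none_when_unreachable(self, basic_design):
        assert (
            min_detectable_difference(
                basic_design, SD25, power_target=1.1, replicates=10, random_state=0
            )
            is None
        )

    def test_min_tubes_extreme_difference(self):
        assert (
            min_tubes_for_difference(
                0.5, SD25, reference_mortality=0.5, replicates=2000, random_state=1
            )
            == 4
        )

    def test_min_tubes_skips_candidates_smaller_than_days(self, caplog):
        with caplog.at_level(logging.WARNING, logger="tubepower.power"):
            result = min_tubes_for_difference(
                0.5,
                VarianceAssumptions(0.25, 0.6),
                days=5,
                tubes_range=range(4, 7),
                replicates=2000,
                random_state=2,
            )
        assert "skipping" in caplog.text
        assert result in (5, 6)

    def test_min_tubes_returns_none_when_out_of_range(self):
        assert (
            min_tubes_for_difference(
                0.02, SD25, tubes_range=range(4, 6), replicates=500, random_state=3
            )
            is None
        )
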
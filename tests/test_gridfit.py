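"""Brute-force grid search: loss, acceptance, and two-phase summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cscplasticity import (
    FitData,
    GridSpec,
    ModelParameters,
    PopulationState,
    brute_force_search,
    fit_two_phase_dedifferentiation,
    loss,
)
from cscplasticity.gridfit import _model_fractions
from oracles import expm_solution

FIXED = {"alpha_S": 0.8, "delta_S": 0.1, "alpha_D": 0.9, "delta_D": 0.1}


def noiseless_data(params, days=(0, 1, 2, 3, 4, 5, 6, 7, 8)):
    f = _model_fractions(params, np.asarray(days, dtype=float))
    return FitData(pd.DataFrame({"time": days, "fraction": f, "n": np.inf}))


class TestLoss:
    def test_zero_on_self_generated_data(self):
        p = ModelParameters(k_SD=0.1, k_DS=0.002, **FIXED)
        assert loss(p, noiseless_data(p)) < 1e-10

    def test_zero_fraction_data_with_no_dedifferentiation(self):
        p = ModelParameters(k_SD=0.1, k_DS=0.0, **FIXED)
        data = FitData(pd.DataFrame({"time": [0, 2, 4], "fraction": [0.0, 0.0, 0.0]}))
        assert loss(p, data) == 0.0

    def test_equals_independent_residual_recomputation(self):
        rng = np.random.default_rng(5)
        p = ModelParameters(k_SD=0.07, k_DS=0.004, **FIXED)
        days = np.array([0.0, 1.5, 3.0, 6.0])
        obs = rng.uniform(0, 0.2, days.size)
        obs[0] = 0.0
        data = FitData(pd.DataFrame({"time": days, "fraction": obs}))
        ref = expm_solution(PopulationState(0, 0.0, 1.0), p, days)
        with np.errstate(invalid="ignore"):
            f_ref = np.where(ref.sum(axis=1) > 0, ref[:, 0] / ref.sum(axis=1), 0.0)
        expected = np.max(np.abs(f_ref - obs))
        assert loss(p, data) == pytest.approx(expected, rel=1e-8)


class TestBruteForceSearch:
    grid = GridSpec(
        axes={"k_SD": [0.05, 0.1, 0.2], "k_DS": [0.001, 0.002, 0.004]},
        fixed=FIXED,
    )

    def test_generate_then_recover_on_grid(self):
        truth = ModelParameters(k_SD=0.1, k_DS=0.002, **FIXED)
        res = brute_force_search(self.grid, noiseless_data(truth), tolerance=1e-6)
        assert res.success
        assert len(res.accepted) == 1
        assert res.means == pytest.approx({"k_SD": 0.1, "k_DS": 0.002})
        assert res.sds == pytest.approx({"k_SD": 0.0, "k_DS": 0.0})

    def test_infinite_tolerance_accepts_whole_grid(self):
        truth = ModelParameters(k_SD=0.1, k_DS=0.002, **FIXED)
        res = brute_force_search(self.grid, noiseless_data(truth), tolerance=math.inf)
        assert len(res.accepted) == self.grid.size
        # balanced product: per-axis mean is the arithmetic mean of its values
        assert res.means["k_SD"] == pytest.approx(np.mean([0.05, 0.1, 0.2]))
        assert res.means["k_DS"] == pytest.approx(np.mean([0.001, 0.002, 0.004]))

    def test_matches_manual_enumeration(self):
        truth = ModelParameters(k_SD=0.1, k_DS=0.002, **FIXED)
        data = noiseless_data(truth)
        tol = 0.002
        res = brute_force_search(self.grid, data, tolerance=tol)
        manual = set()
        for ksd, kds in itertools.product([0.05, 0.1, 0.2], [0.001, 0.002, 0.004]):
            p = ModelParameters(k_SD=ksd, k_DS=kds, **FIXED)
            if loss(p, data) <= tol:
                manual.add((ksd, kds))
        got = set(map(tuple, res.accepted[["k_SD", "k_DS"]].to_numpy()))
        assert got == manual

    def test_acceptance_monotone_in_tolerance(self):
        truth = ModelParameters(k_SD=0.1, k_DS=0.002, **FIXED)
        data = noiseless_data(truth)
        sets = []
        for tol in (1e-4, 1e-3, 1e-2, 1e-1):
            res = brute_force_search(self.grid, data, tolerance=tol)
            sets.append(set(map(tuple, res.accepted[["k_SD", "k_DS"]].to_numpy())))
        for small, big in zip(sets, sets[1:]):
            assert small <= big

    def test_invariant_to_axis_enumeration_order(self):
        truth = ModelParameters(k_SD=0.1, k_DS=0.002, **FIXED)
        data = noiseless_data(truth)
        permuted = GridSpec(
            axes={"k_DS": [0.001, 0.002, 0.004], "k_SD": [0.05, 0.1, 0.2]},
            fixed=FIXED,
        )
        a = brute_force_search(self.grid, data, tolerance=0.01)
        b = brute_force_search(permuted, data, tolerance=0.01)
        assert a.means == pytest.approx(b.means)
        sa = a.accepted.sort_values(["k_SD", "k_DS"]).reset_index(drop=True)
        sb = b.accepted.sort_values(["k_SD", "k_DS"]).reset_index(drop=True)
        assert sa[["k_SD", "k_DS", "loss"]].equals(sb[["k_SD", "k_DS", "loss"]])

    def test_no_fit_within_tolerance_is_explicit(self):
        data = FitData(pd.DataFrame({"time": [0, 4, 8], "fraction": [0.0, 0.9, 0.9]}))
        res = brute_force_search(self.grid, data, tolerance=1e-4)
        assert not res.success
        assert res.means is None
        assert math.isfinite(res.min_loss) and res.min_loss > 1e-4
        assert "no fit within tolerance" in res.summary()


class TestTwoPhase:
    def two_phase_grid(self, early, late):
        return GridSpec(
            axes={"k_DS_early": early, "k_DS_late": late},
            fixed={**FIXED, "k_SD": 0.1},
            switch_day=3.0,
        )

    def test_no_planted_switch_gives_unit_ratio(self):
        truth = ModelParameters(k_SD=0.1, k_DS=0.004, **FIXED)
        grid = self.two_phase_grid([0.002, 0.004, 0.008], [0.002, 0.004, 0.008])
        res = fit_two_phase_dedifferentiation(grid, noiseless_data(truth), tolerance=1e-6)
        assert res.success
        assert res.ratio_late_early == pytest.approx(1.0)

    def test_recovers_planted_switch(self):
        truth = ModelParameters(
            k_SD=0.1, k_DS=[[0.0, 0.002], [3.0, 0.02]], **FIXED
        )
        grid = self.two_phase_grid(
            [0.0005, 0.001, 0.002, 0.004], [0.005, 0.01, 0.02, 0.04]
        )
        res = fit_two_phase_dedifferentiation(grid, noiseless_data(truth), tolerance=1e-6)
        assert res.success
        assert res.k_DS_early_mean == pytest.approx(0.002)
        assert res.k_DS_late_mean == pytest.approx(0.02)
        assert res.ratio_late_early == pytest.approx(10.0)

    def test_degenerate_grid_has_zero_spread(self):
        truth = ModelParameters(
            k_SD=0.1, k_DS=[[0.0, 0.002], [3.0, 0.02]], **FIXED
        )
        grid = self.two_phase_grid([0.002], [0.02])
        res = fit_two_phase_dedifferentiation(grid, noiseless_data(truth), tolerance=0.05)
        assert res.success
        assert all(sd == 0.0 for sd in res.sds.values())

    def test_zero_early_rate_reports_infinite_ratio(self):
        truth = ModelParameters(k_SD=0.1, k_DS=[[0.0, 0.0], [3.0, 0.02]], **FIXED)
        grid = self.two_phase_grid([0.0], [0.02])
        with pytest.warns(RuntimeWarning, match="inf"):
            res = fit_two_phase_dedifferentiation(
                grid, noiseless_data(truth), tolerance=0.05
            )
        assert math.isinf(res.ratio_late_early)


class TestGridSpecValidation:
    def test_missing_dedifferentiation_axis(self):
        with pytest.raises(ValueError, match="dedifferentiation"):
            GridSpec(axes={"k_SD": [0.1]}, fixed=FIXED)

    def test_unsorted_axis_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            GridSpec(axes={"k_DS": [0.2, 0.1], "k_SD": [0.1]}, fixed=FIXED)

    def test_conflicting_axes_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(
                axes={"k_DS": [0.1], "k_DS_early": [0.1], "k_DS_late": [0.1], "k_SD": [0.1]},
                fixed=FIXED,
            )

    def test_fit_data_validation(self):
        with pytest.raises(ValueError):
            FitData(pd.DataFrame({"time": [0.0], "fraction": [1.5]}))
        with pytest.raises(ValueError):
            FitData(
                pd.DataFrame({"time": [0.0], "fraction": [0.5]}),
                mammosphere=(5, 3),
            )
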
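import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import _oracles as oracles
from gaitpattern import (
    SynthConfig,
    compare_running_speed,
    friedman,
    generate_cohort,
    holm_correct,
    kruskal_wallis,
    mann_whitney_effect,
    pairwise_mann_whitney,
    symmetry_index,
    symmetry_table,
)
from gaitpattern.errors import InsufficientDataError, ParameterError
from gaitpattern.symmetry_stats import effect_label


class TestSymmetryIndex:
    def test_identical_sides_give_zero(self, rng):
        trials = [rng.normal(size=18) for _ in range(3)]
        assert symmetry_index(trials, [t.copy() for t in trials]) == pytest.approx(0.0)

    def test_hand_worked_two_point_example(self):
        # 1 angle, 2 time points: L = {(1,3),(3,5)}, R = {(0,2),(2,4)}
        # mean diff = (-1,-1); pooled SD per point = sqrt((2+2)/2) = sqrt(2)
        # index = |(-1 - 1)/sqrt(2)| = sqrt(2)
        left = [np.array([1.0, 3.0]), np.array([3.0, 5.0])]
        right = [np.array([0.0, 2.0]), np.array([2.0, 4.0])]
        assert symmetry_index(left, right) == pytest.approx(1.4142, abs=1e-4)

    def test_side_swap_invariance(self, rng):
        left = rng.normal(size=(4, 12))
        right = rng.normal(size=(4, 12))
        assert symmetry_index(left, right) == pytest.approx(
            symmetry_index(right, left)
        )

    def test_constant_offset_shifts_index_analytically(self, rng):
        base = rng.normal(size=(5, 10))
        right = base + rng.normal(0, 0.5, size=(5, 10))
        s0_signed = np.sum(
            (right.mean(0) - base.mean(0))
            / np.sqrt((base.var(0, ddof=1) + right.var(0, ddof=1)) / 2)
        )
        c = 3.0
        pooled = np.sqrt((base.var(0, ddof=1) + right.var(0, ddof=1)) / 2)
        expected = abs(s0_signed + np.sum(c / pooled))
        assert symmetry_index(base, right + c) == pytest.approx(expected)

    def test_single_trial_side_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            symmetry_index(rng.normal(size=(1, 5)), rng.normal(size=(3, 5)))


class TestSymmetryTable:
    def test_shape_and_alpha_ordering(self):
        cfg = SynthConfig(
            n_subjects=5, n_conditions=4, n_trials=4, n_time=41,
            alpha_neutral=3.0, alpha_splint=0.3, seed=4,
        )
        trials, _ = generate_cohort(cfg)
        table = symmetry_table(trials, n_time=cfg.n_time)
        assert table.values.shape == (5, 4)
        assert (table.values >= 0).all().all()
        meds = table.medians
        assert meds["Neutral"] > meds[["Centric", "DPS", "Max"]].max()

    def test_missing_side_leaves_cell_empty(self):
        cfg = SynthConfig(n_subjects=2, n_conditions=2, n_trials=3, n_time=21, seed=1)
        trials, _ = generate_cohort(cfg)
        broken = trials.subset(
            lambda t: not (t.subject == "S01" and t.condition == "Neutral" and t.side == "L")
        )
        with pytest.warns(UserWarning, match="S01/Neutral"):
            table = symmetry_table(broken, n_time=21)
        assert np.isnan(table.values.loc["S01", "Neutral"])
        assert np.isfinite(table.values.loc["S02", "Neutral"])


class TestRankTests:
    def test_kruskal_identical_groups_is_zero(self):
        res = kruskal_wallis([[1.0, 1.0], [1.0], [1.0, 1.0]])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_kruskal_matches_direct_formula(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(oracles.kruskal_wallis_direct(groups))
        assert res.df == 2 and res.n == 9

    def test_kruskal_agrees_with_oracle_on_all_small_inputs(self, rng):
        # exhaustive-ish scan: random integer-valued groups of total size <= 8
        for _ in range(60):
            sizes = rng.integers(1, 4, size=rng.integers(2, 4))
            if sizes.sum() < 3:
                continue
            groups = [rng.integers(0, 4, size=s).astype(float) for s in sizes]
            pooled = np.concatenate(groups)
            if np.all(pooled == pooled[0]):
                continue
            res = kruskal_wallis(groups)
            assert res.statistic == pytest.approx(
                oracles.kruskal_wallis_direct(groups), abs=1e-10
            )

    def test_friedman_identical_columns_is_zero(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0],
                              "c": [1.0, 2.0, 3.0]})
        res = friedman(table)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_friedman_matches_hand_rank_formula(self):
        table = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 1.0], [1.0, 3.0, 2.0]])
        res = friedman(table)
        assert res.statistic == pytest.approx(oracles.friedman_direct(table))
        assert res.df == 2 and res.n == 3

    def test_friedman_drops_incomplete_blocks(self):
        table = pd.DataFrame(
            {"a": [1.0, 2.0, np.nan], "b": [2.0, 1.0, 2.0], "c": [3.0, 3.0, 1.0]}
        )
        with pytest.warns(UserWarning, match="incomplete"):
            res = friedman(table)
        assert res.n == 2

    def test_mann_whitney_identical_samples_sub_low(self):
        res = mann_whitney_effect([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.effect_size_r == pytest.approx(0.0)
        assert res.effect == "sub-low"

    def test_mann_whitney_matches_enumeration(self):
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = mann_whitney_effect(x, y)
        u_obs, null_mean, null_sd = oracles.mann_whitney_enumeration(x, y)
        assert res.statistic == u_obs == 0.0
        z_expected = (u_obs - null_mean) / null_sd
        assert res.effect_size_r == pytest.approx(abs(z_expected) / np.sqrt(6))
        assert res.p == pytest.approx(2 * sps.norm.sf(abs(z_expected)))

    def test_mann_whitney_u_agrees_with_scipy_under_ties(self, rng):
        for _ in range(30):
            x = rng.integers(0, 4, size=rng.integers(2, 5)).astype(float)
            y = rng.integers(0, 4, size=rng.integers(2, 5)).astype(float)
            res = mann_whitney_effect(x, y)
            u_scipy = sps.mannwhitneyu(x, y, alternative="two-sided").statistic
            assert res.statistic == pytest.approx(float(u_scipy))

    def test_effect_labels_at_thresholds(self):
        assert effect_label(0.05) == "sub-low"
        assert effect_label(0.1) == "low"
        assert effect_label(0.3) == "medium"
        assert effect_label(0.5) == "large"


class TestHolm:
    def test_single_small_p_rejected(self):
        reject, p_adj = holm_correct([0.04], alpha=0.05)
        assert reject[0] and p_adj[0] == pytest.approx(0.04)

    def test_step_down_sequence_matches_hand_application(self):
        # sorted: 0.01 <= 0.05/3 rejects; 0.03 > 0.05/2 stops the step-down,
        # so only the smallest p survives
        p = [0.01, 0.04, 0.03]
        reject, _ = holm_correct(p, alpha=0.05)
        assert np.array_equal(reject, oracles.holm_decisions_direct(p, 0.05))
        assert list(reject) == [True, False, False]

    def test_stops_at_first_failure(self):
        p = [0.01, 0.5, 0.02]
        reject, _ = holm_correct(p, alpha=0.05)
        assert np.array_equal(reject, oracles.holm_decisions_direct(p, 0.05))

    def test_all_ones_never_rejected(self):
        reject, p_adj = holm_correct([1.0, 1.0, 1.0], alpha=0.05)
        assert not reject.any()
        assert np.allclose(p_adj, 1.0)

    def test_random_p_match_hand_step_down(self, rng):
        for _ in range(25):
            p = rng.uniform(size=rng.integers(1, 7))
            reject, _ = holm_correct(p, alpha=0.05)
            assert np.array_equal(reject, oracles.holm_decisions_direct(p, 0.05))


class TestRunningSpeed:
    @staticmethod
    def _speed_frame(values):
        rows = []
        for subject, conds in values.items():
            for cond, speeds in conds.items():
                rows += [(subject, cond, s) for s in speeds]
        return pd.DataFrame(rows, columns=["subject", "condition", "speed"])

    def test_identical_speeds_give_p_one(self):
        df = self._speed_frame(
            {f"s{i}": {c: [3.0, 3.0] for c in "ABCD"} for i in range(4)}
        )
        res = compare_running_speed(df)
        assert res["anova"].p == 1.0 and res["anova"].statistic == 0.0
        assert not res["posthoc"]["significant"].any()

    def test_shifted_condition_detected_after_holm(self, rng):
        values = {}
        for i in range(8):
            base = 3.4 + rng.normal(0, 0.05)
            values[f"s{i}"] = {
                "A": list(base + rng.normal(0, 0.02, 3)),
                "B": list(base + rng.normal(0, 0.02, 3)),
                "C": list(base + 0.5 + rng.normal(0, 0.02, 3)),  # ~10 SD shift
            }
        res = compare_running_speed(self._speed_frame(values))
        assert res["anova"].p < 0.01
        posthoc = res["posthoc"].set_index("comparison")
        assert posthoc.loc["A vs C", "significant"]
        assert posthoc.loc["B vs C", "significant"]
        assert not posthoc.loc["A vs B", "significant"]

    def test_missing_columns_rejected(self):
        with pytest.raises(ParameterError):
            compare_running_speed(pd.DataFrame({"subject": [], "speed": []}))


def test_pairwise_mann_whitney_covers_all_condition_pairs(rng):
    table = pd.DataFrame(
        rng.normal(size=(8, 3)), columns=["Neutral", "Centric", "Max"]
    )
    out = pairwise_mann_whitney(table)
    assert len(out) == 3
    assert set(out["comparison"]) == {
        "Neutral vs Centric", "Neutral vs Max", "Centric vs Max"
    }
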
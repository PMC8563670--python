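"""Stay-switch behavior, MF/MB indices, paired tests, RM-ANOVA."""

import numpy as np
import pandas as pd
import pytest

from twostep.agent import AgentParams, simulate_session
from twostep.metrics import (
    CELLS,
    DegenerateInputError,
    StayTable,
    classify_trials,
    mf_mb_indices,
    paired_t,
    points_earned,
    rm_anova_2x2x2,
    stay_probabilities,
)
from twostep.task import TaskConfig, simulate_reward_walk


def table(cr, rr, cu, ru, n=10):
    return StayTable(
        p_stay={"CR": cr, "RR": rr, "CU": cu, "RU": ru},
        n={c: n for c in CELLS},
    )


class TestClassification:
    def test_basic_cells_and_stay(self, make_session):
        s = make_session(
            [
                (1, "A", 3, 1),  # common rewarded
                (1, "A", 4, 0),  # stay after CR; this trial: common unrewarded
                (2, "B", 5, 1),  # switch after CU; rare? no: choice 2 -> B common... rewarded
                (2, "A", 3, 0),  # stay after CR(2); this trial rare unrewarded
                (1, "B", 6, 1),  # switch after RU
            ]
        )
        labeled = classify_trials(s)
        assert list(labeled["cell"]) == ["CR", "CU", "CR", "RU"]
        assert list(labeled["stay"]) == [True, False, True, False]

    def test_pairs_with_missed_trial_dropped(self, make_session):
        s = make_session([(1, "A", 3, 1), None, (1, "A", 3, 1), (1, "A", 3, 1)])
        labeled = classify_trials(s)
        # pair (1,2) and (2,3) both involve the missed trial -> only (3,4) left
        assert len(labeled) == 1
        assert labeled.iloc[0]["trial"] == 4

    def test_always_repeat_gives_unit_probabilities(self, make_session):
        specs = [(1, "A", 3, r) for r in (1, 0, 1, 0, 1, 0)]
        # vary transition by moving to state B sometimes while repeating choice 1
        specs[2] = (1, "B", 5, 1)
        specs[4] = (1, "B", 6, 1)
        tab = stay_probabilities(make_session(specs))
        for c in CELLS:
            if tab.n[c]:
                assert tab.p_stay[c] == 1.0

    def test_hand_counted_five_trial_session(self, make_session):
        s = make_session(
            [
                (1, "A", 3, 1),  # prev for t2: CR
                (2, "B", 5, 1),  # switch | CR ; prev for t3: CR
                (2, "B", 6, 0),  # stay | CR ; prev for t4: CU
                (2, "A", 4, 0),  # stay | CU ; prev for t5: RU
                (1, "A", 3, 0),  # switch | RU
            ]
        )
        tab = stay_probabilities(s)
        assert tab.n["CR"] == 2 and tab.p_stay["CR"] == pytest.approx(0.5)
        assert tab.n["CU"] == 1 and tab.p_stay["CU"] == 1.0
        assert tab.n["RU"] == 1 and tab.p_stay["RU"] == 0.0
        assert tab.n["RR"] == 0 and np.isnan(tab.p_stay["RR"])

    def test_relabeling_rockets_preserves_indices(self, default_config):
        """Swapping stimulus labels 1<->2, A<->B, (3,4)<->(5,6) leaves the
        stay pattern, hence MF/MB indices, unchanged."""
        walk = simulate_reward_walk(default_config, 4)
        p = AgentParams(0.5, 0.5, 0.5, 2.0, 2.0, 3.0, 0.2)
        s = simulate_session(p, walk, default_config, seed=9)
        t = s.trials.copy()
        t["choice1"] = 3 - t["choice1"]
        t["state2"] = t["state2"].map({"A": "B", "B": "A"})
        t["choice2"] = t["choice2"].map({3: 5, 4: 6, 5: 3, 6: 4})
        swapped = type(s)(s.subject_id, s.condition, t, s.config)
        assert mf_mb_indices(stay_probabilities(s)) == pytest.approx(
            mf_mb_indices(stay_probabilities(swapped))
        )

    def test_block_boundary_pairs_retained_by_default(self, make_session):
        from twostep.task import TaskConfig

        cfg = TaskConfig(n_trials=4, n_blocks=2, block_length=2)
        s = make_session([(1, "A", 3, 1)] * 4, config=cfg)
        assert len(classify_trials(s)) == 3
        dropped = classify_trials(s, drop_block_boundaries=True)
        assert len(dropped) == 2
        assert 3 not in dropped["trial"].tolist()  # the pair spanning the break

    def test_cell_counts_sum_to_valid_pairs(self, default_config):
        walk = simulate_reward_walk(default_config, 4)
        s = simulate_session(AgentParams(0.5, 0.5, 0.5, 1, 1, 1, 0), walk, default_config, seed=10)
        tab = stay_probabilities(s)
        assert sum(tab.n.values()) == default_config.n_trials - 1


class TestIndices:
    def test_flat_table_gives_zero_indices(self):
        assert mf_mb_indices(table(0.5, 0.5, 0.5, 0.5)) == (0.0, 0.0)

    def test_reward_main_effect_is_mf(self):
        mf, mb = mf_mb_indices(table(0.9, 0.9, 0.5, 0.5))
        assert (mf, mb) == (pytest.approx(0.8), pytest.approx(0.0))

    def test_crossover_is_mb(self):
        mf, mb = mf_mb_indices(table(0.9, 0.5, 0.5, 0.9))
        assert (mf, mb) == (pytest.approx(0.0), pytest.approx(0.8))

    def test_empty_cell_raises(self):
        bad = table(0.9, float("nan"), 0.5, 0.5)
        with pytest.raises(DegenerateInputError):
            mf_mb_indices(bad)


class TestPoints:
    def test_counts_rewards_excluding_missed(self, make_session):
        s = make_session([(1, "A", 3, 1), None, (2, "B", 5, 1), (1, "A", 4, 0), (1, "A", 3, 1)])
        assert points_earned(s) == 3

    def test_zero_when_never_rewarded(self, make_session):
        s = make_session([(1, "A", 3, 0)] * 4)
        assert points_earned(s) == 0


class TestPairedT:
    def test_identical_samples(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (res.t, res.p, res.d) == (0.0, 1.0, 0.0)

    def test_textbook_hand_computation(self):
        # diffs (2, 4, 6, 8): mean 5, sd sqrt(20/3) = 2.5820, t = 5*2/2.582
        res = paired_t([3, 5, 7, 9], [1, 1, 1, 1])
        assert res.t == pytest.approx(5 * 2 / 2.581988897, rel=1e-6)
        assert res.df == 3
        assert res.d == pytest.approx(5 / 2.581988897, rel=1e-6)

    def test_constant_nonzero_difference_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])

    def test_near_constant_difference_excludes_zero(self):
        rng = np.random.default_rng(0)
        x = np.arange(4, dtype=float)
        y = x + 1.0 + rng.normal(0, 1e-3, 4)
        res = paired_t(y, x)
        assert res.d > 100
        assert res.ci_low > 0


def _random_tables(rng, n_subjects):
    tables = {}
    for i in range(n_subjects):
        tables[f"S{i}"] = {
            c: table(*rng.uniform(0.2, 0.9, size=4)) for c in ("hungry", "sated")
        }
    return tables


class TestRmAnova:
    def test_identical_conditions_null_condition_effects(self):
        rng = np.random.default_rng(1)
        tables = {}
        for i in range(8):
            one = table(*rng.uniform(0.2, 0.9, size=4))
            tables[f"S{i}"] = {"hungry": one, "sated": one}
        out = rm_anova_2x2x2(tables, ["hungry", "sated"]).set_index("effect")
        for effect in out.index:
            if "condition" in effect:
                assert out.loc[effect, "statistic"] == 0.0
                assert out.loc[effect, "p"] == 1.0

    def test_matches_statsmodels_anova_rm(self):
        """Independent oracle: statsmodels AnovaRM on the same long table."""
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(7)
        tables = _random_tables(rng, 10)
        ours = rm_anova_2x2x2(tables, ["hungry", "sated"]).set_index("effect")

        rows = []
        for subj, per_cond in tables.items():
            for cond, tab in per_cond.items():
                for cell in CELLS:
                    rows.append(
                        {
                            "subject": subj,
                            "cond": cond,
                            "trans": "common" if cell[0] == "C" else "rare",
                            "rew": "yes" if cell[1] == "R" else "no",
                            "value": tab.p_stay[cell],
                        }
                    )
        long = pd.DataFrame(rows)
        oracle = AnovaRM(long, "value", "subject", within=["cond", "trans", "rew"]).fit()
        mapping = {
            "cond": "condition",
            "trans": "transition",
            "rew": "reward",
            "cond:trans": "condition x transition",
            "cond:rew": "condition x reward",
            "trans:rew": "transition x reward",
            "cond:trans:rew": "condition x transition x reward",
        }
        for sm_name, our_name in mapping.items():
            f_oracle = oracle.anova_table.loc[sm_name, "F Value"]
            assert ours.loc[our_name, "statistic"] == pytest.approx(f_oracle, rel=1e-6)
            assert ours.loc[our_name, "p"] == pytest.approx(
                oracle.anova_table.loc[sm_name, "Pr > F"], abs=1e-9
            )

    def test_main_effect_equals_squared_paired_t(self):
        rng = np.random.default_rng(11)
        tables = _random_tables(rng, 9)
        out = rm_anova_2x2x2(tables, ["hungry", "sated"]).set_index("effect")
        # condition main effect vs paired t on per-condition cell means
        a = [np.mean([tables[s]["hungry"].p_stay[c] for c in CELLS]) for s in tables]
        b = [np.mean([tables[s]["sated"].p_stay[c] for c in CELLS]) for s in tables]
        res = paired_t(a, b)
        assert out.loc["condition", "statistic"] == pytest.approx(res.t**2, rel=1e-9)
        assert out.loc["condition", "p"] == pytest.approx(res.p, abs=1e-12)

    def test_subject_missing_condition_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        tables = _random_tables(rng, 5)
        del tables["S0"]["sated"]
        with pytest.warns(UserWarning, match="missing a condition"):
            out = rm_anova_2x2x2(tables, ["hungry", "sated"])
        assert (out["df2"] == 3).all()

    def test_pure_mf_group_shows_reward_main_effect(self, long_config):
        """Sessions simulated from model-free agents: large reward effect,
        no reward-by-transition interaction."""
        cfg = long_config(600)
        mf_params = AgentParams(0.6, 0.6, 0.6, 0.0, 4.0, 4.0, 0.0)
        tables = {}
        for i in range(10):
            per_cond = {}
            for j, cond in enumerate(("hungry", "sated")):
                walk = simulate_reward_walk(cfg, 100 + 2 * i + j)
                s = simulate_session(mf_params, walk, cfg, seed=500 + 2 * i + j)
                per_cond[cond] = stay_probabilities(s)
            tables[f"S{i}"] = per_cond
        out = rm_anova_2x2x2(tables, ["hungry", "sated"]).set_index("effect")
        assert out.loc["reward", "p"] < 1e-4
        assert out.loc["transition x reward", "p"] > 0.01
        assert out.loc["reward", "statistic"] > 20 * out.loc["transition x reward", "statistic"]
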
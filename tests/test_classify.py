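import numpy as np
import pandas as pd
import pytest

from hfdeeg import (
    ClassifierConfig,
    GreedyChannelSelector,
    greedy_select,
    majority_vote,
    nested_loso_evaluate,
    transfer_evaluate,
    trial_vectors,
)
from hfdeeg.classify import _cv_accuracy

from .conftest import synthetic_feature_table

FAST = ClassifierConfig(nu_grid=(0.3,), offset_grid=(0.0,))


class TestTrialVectors:
    def test_one_row_per_trial(self):
        table = synthetic_feature_table(n_participants_per_group=10,
                                        n_trials=60, channels=("A", "B"))
        x, y, parts = trial_vectors(table, "LH", ["A", "B"], 0.0)
        assert x.shape == (1200, 2)
        assert len(np.unique(parts)) == 20
        assert sorted(np.unique(y)) == ["a", "b"]

    def test_single_channel_gives_one_column(self):
        table = synthetic_feature_table()
        x, _, _ = trial_vectors(table, "LH", ["B"], 0.0)
        assert x.shape[1] == 1

    def test_channel_order_reversal_permutes_columns_only(self):
        table = synthetic_feature_table()
        x_ab, y_ab, _ = trial_vectors(table, "LH", ["A", "B"], 0.0)
        x_ba, y_ba, _ = trial_vectors(table, "LH", ["B", "A"], 0.0)
        assert np.array_equal(x_ab, x_ba[:, ::-1])
        assert np.array_equal(y_ab, y_ba)

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="Z"):
            trial_vectors(synthetic_feature_table(), "LH", ["Z"], 0.0)

    def test_trials_with_missing_features_dropped(self):
        table = synthetic_feature_table()
        table.loc[table.index[0], "hfd"] = np.nan
        x, _, _ = trial_vectors(table, "LH", ["A", "B", "C"], 0.0)
        assert x.shape[0] == len(table) // 3 - 1


class TestGreedySelection:
    def test_informative_channel_selected_first(self):
        table = synthetic_feature_table(informative=("B",), effect=3.0, seed=1)
        sel = greedy_select(table, "LH", 0.0, nu=0.3)
        assert sel.channels[0] == "B"
        assert sel.accuracy_trace[0] > 0.8

    def test_first_pick_matches_exhaustive_single_channel_oracle(self):
        # the greedy start must equal the argmax over single-channel inner-CV
        for seed in range(3):
            table = synthetic_feature_table(informative=("C",), effect=1.0,
                                            noise_sd=1.5, seed=seed)
            channels = ["A", "B", "C"]
            accs = []
            for ch in channels:
                x, y, parts = trial_vectors(table, "LH", [ch], 0.0)
                accs.append(_cv_accuracy(x, y, parts, 0.3, 1e-3, True))
            sel = greedy_select(table, "LH", 0.0, nu=0.3)
            assert sel.channels[0] == channels[int(np.argmax(accs))]

    def test_all_noise_halts_quickly_near_chance(self):
        # selection over noise channels overfits a little by construction
        # (it maximises a noisy inner-CV estimate) but must stay near chance
        table = synthetic_feature_table(n_participants_per_group=8,
                                        n_trials=20, seed=2)
        sel = greedy_select(table, "LH", 0.0, nu=0.3)
        assert len(sel.channels) <= 2
        assert sel.accuracy_trace[-1] < 0.7

    def test_tie_between_identical_channels_breaks_by_order(self):
        table = synthetic_feature_table(informative=("A",), effect=3.0, seed=3)
        # make channel C a bit-identical copy of A; A precedes C
        wide = table.pivot_table(index=["group", "participant", "trial",
                                        "task", "window_offset"],
                                 columns="channel", values="hfd",
                                 aggfunc="first")
        wide["C"] = wide["A"]
        table = wide.stack().rename("hfd").reset_index()
        sel = greedy_select(table, "LH", 0.0, nu=0.3, channels=["A", "B", "C"])
        assert sel.channels[0] == "A"

    def test_trace_strictly_increasing(self):
        table = synthetic_feature_table(informative=("A", "C"), effect=0.8,
                                        noise_sd=1.0, seed=4)
        sel = greedy_select(table, "LH", 0.0, nu=0.3)
        trace = sel.accuracy_trace
        assert all(b > a for a, b in zip(trace, trace[1:]))

    def test_single_class_rejected(self):
        table = synthetic_feature_table()
        table = table[table["group"] == "a"]
        with pytest.raises(ValueError, match="class|group"):
            greedy_select(table, "LH", 0.0, nu=0.3)

    def test_sklearn_estimator_contract(self):
        sel = GreedyChannelSelector(nu=0.25, channel_names=["A", "B"])
        params = sel.get_params()
        assert params["nu"] == 0.25
        sel.set_params(nu=0.4)
        assert sel.nu == 0.4
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 2))
        y = np.repeat(["u", "v"], 20)
        x[y == "u", 1] += 3.0
        groups = np.tile(np.repeat(["p1", "p2", "p3", "p4"], 5), 2)
        sel.fit(x, y, groups=groups)
        assert sel.selected_channels_[0] == "B"
        assert set(sel.predict(x)) <= {"u", "v"}


class TestMajorityVote:
    def test_majority_carries_participant(self):
        preds = pd.DataFrame({
            "participant": ["p"] * 60,
            "true": ["a"] * 60,
            "predicted": ["a"] * 40 + ["b"] * 20,
        })
        frame, pct = majority_vote(preds)
        assert frame.loc[0, "correct"]
        assert pct == 100.0

    def test_exact_tie_counts_incorrect(self):
        preds = pd.DataFrame({
            "participant": ["p"] * 60,
            "true": ["a"] * 60,
            "predicted": ["a"] * 30 + ["b"] * 30,
        })
        frame, pct = majority_vote(preds)
        assert not frame.loc[0, "correct"]
        assert pct == 0.0

    def test_percentage_over_participants(self):
        rows = []
        for i in range(10):
            correct = i < 9
            rows += [{"participant": f"p{i}", "true": "a",
                      "predicted": "a" if correct else "b"}] * 3
        _, pct = majority_vote(pd.DataFrame(rows))
        assert pct == pytest.approx(90.0)

    def test_bare_majority_31_of_60(self):
        preds = pd.DataFrame({
            "participant": ["p"] * 60,
            "true": ["a"] * 60,
            "predicted": ["a"] * 31 + ["b"] * 29,
        })
        frame, _ = majority_vote(preds)
        assert frame.loc[0, "correct"]


class TestNestedLoso:
    def test_separated_groups_classified_almost_perfectly(self):
        table = synthetic_feature_table(n_participants_per_group=4, n_trials=10,
                                        informative=("B",), effect=4.0,
                                        noise_sd=0.5, seed=5)
        rep = nested_loso_evaluate(table, "LH", FAST)
        assert rep.accuracy_mean >= 0.95
        assert rep.participants_correct == 100.0
        assert rep.sensitivity >= 0.9 and rep.specificity >= 0.9
        assert rep.modal_config["channels"][0] == "B"

    def test_report_determinism(self):
        table = synthetic_feature_table(seed=6)
        r1 = nested_loso_evaluate(table, "LH", FAST)
        r2 = nested_loso_evaluate(table, "LH", FAST)
        assert r1.accuracy_mean == r2.accuracy_mean
        assert r1.predictions.equals(r2.predictions)
        assert r1.fold_winners == r2.fold_winners

    def test_no_participant_leakage_into_inner_folds(self):
        table = synthetic_feature_table(seed=7)
        audit = []
        nested_loso_evaluate(table, "LH", FAST, audit=audit)
        assert audit, "audit must record inner splits"
        for inner_train, inner_held, outer_held in audit:
            assert outer_held not in inner_train
            assert inner_held != outer_held

    def test_one_fold_winner_per_participant(self):
        table = synthetic_feature_table(seed=8)
        rep = nested_loso_evaluate(table, "LH", FAST)
        assert len(rep.fold_winners) == 6
        held = {w["held_out"] for w in rep.fold_winners}
        assert held == set(table["participant"].unique())

    def test_more_than_two_groups_rejected(self):
        table = synthetic_feature_table(seed=9)
        extra = table.head(30).copy()
        extra["group"] = "c"
        extra["participant"] = "c0"
        with pytest.raises(ValueError, match="two groups"):
            nested_loso_evaluate(pd.concat([table, extra]), "LH", FAST)


class TestTransfer:
    def test_identity_transfer_matches_restricted_nested(self):
        table = synthetic_feature_table(informative=("B",), effect=3.0,
                                        noise_sd=0.5, seed=10)
        native = nested_loso_evaluate(table, "LH", FAST, channels=["B"])
        transferred = transfer_evaluate(table, "LH", ["B"], 0.0, FAST)
        assert transferred.accuracy_mean == pytest.approx(native.accuracy_mean)
        assert transferred.predictions["predicted"].equals(
            native.predictions["predicted"])

    def test_uninformative_channel_near_chance(self):
        table = synthetic_feature_table(n_participants_per_group=5,
                                        n_trials=20, informative=("B",),
                                        effect=3.0, seed=11)
        rep = transfer_evaluate(table, "LH", ["A"], 0.0, FAST)
        assert 0.25 <= rep.accuracy_mean <= 0.75

    def test_shared_marker_transfers_between_cohorts(self):
        src = synthetic_feature_table(informative=("B",), effect=2.5,
                                      noise_sd=0.8, seed=12)
        tgt = synthetic_feature_table(informative=("B",), effect=2.5,
                                      noise_sd=0.8, seed=13)
        sel = greedy_select(src, "LH", 0.0, nu=0.3)
        native = nested_loso_evaluate(tgt, "LH", FAST)
        transferred = transfer_evaluate(tgt, "LH", list(sel.channels), 0.0, FAST)
        assert abs(transferred.accuracy_mean - native.accuracy_mean) <= 0.10

    def test_nu_grid_validation(self):
        with pytest.raises(ValueError, match="nu"):
            ClassifierConfig(nu_grid=(0.0, 0.5))
        with pytest.raises(ValueError, match="non-empty"):
            ClassifierConfig(nu_grid=())
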
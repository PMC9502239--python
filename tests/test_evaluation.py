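import numpy as np
import pandas as pd
import pytest

from walkpd.cnn import CNNConfig
from walkpd.evaluation import (
    FoldPlan,
    LeakageError,
    WindowDataset,
    daily_decisions,
    daily_majority_vote,
    holdout_days,
    make_logo_folds,
    run_logo_cv,
    walk_duration_summary,
)


class TestLogoFolds:
    def test_eleven_subjects_eleven_folds(self):
        subjects = {f"s{i:02d}": ("HC" if i < 4 else "PD") for i in range(11)}
        plan = make_logo_folds(subjects)
        assert len(plan.folds) == 11

    def test_each_subject_validates_exactly_once(self):
        subjects = {f"s{i}": ("HC" if i % 2 else "PD") for i in range(6)}
        plan = make_logo_folds(subjects)
        vals = [v for _, v in plan.folds]
        assert sorted(vals) == sorted(subjects)
        for train, val in plan.folds:
            assert val not in train
            assert set(train) | {val} == set(subjects)

    def test_matches_exhaustive_enumeration(self):
        subjects = {"a": "HC", "b": "PD", "c": "PD"}
        plan = make_logo_folds(subjects)
        expected = {
            (("b", "c"), "a"),
            (("a", "c"), "b"),
            (("a", "b"), "c"),
        }
        assert set(plan.folds) == expected

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            make_logo_folds({"only": "PD"})
        with pytest.raises(ValueError):
            make_logo_folds({"a": "PD", "b": "PD"})


class TestDailyVote:
    def _preds(self, labels, sid="s1", day=0):
        return pd.DataFrame(
            {
                "subject_id": sid,
                "day_index": day,
                "start_time": np.arange(len(labels)),
                "p_pd": [1.0 if l == "PD" else 0.0 for l in labels],
                "predicted": labels,
            }
        )

    def test_majority_wins(self):
        d = daily_majority_vote(self._preds(["PD"] * 3 + ["HC"] * 2))
        assert d.decided == "PD"
        assert d.n_events == 5
        assert d.pd_vote_fraction == pytest.approx(0.6)

    def test_tie_votes_pd(self):
        assert daily_majority_vote(self._preds(["PD", "HC"])).decided == "PD"

    def test_empty_day_rejected(self):
        with pytest.raises(ValueError):
            daily_majority_vote(self._preds([]))

    def test_mixed_days_rejected(self):
        a = self._preds(["PD"], day=0)
        b = self._preds(["PD"], day=1)
        with pytest.raises(ValueError):
            daily_majority_vote(pd.concat([a, b]))

    def test_majority_amplification(self):
        # if per-day event accuracy exceeds 0.5 on every day, all votes correct
        rng = np.random.default_rng(0)
        frames = []
        for day in range(6):
            n = 21
            correct = rng.integers(11, 21)  # > half
            labels = ["PD"] * correct + ["HC"] * (n - correct)
            frames.append(self._preds(labels, day=day))
        votes = daily_decisions(pd.concat(frames, ignore_index=True))
        assert (votes["decided"] == "PD").all()


def _toy_dataset(recorded=None, n_days=12, seed=0):
    rng = np.random.default_rng(seed)
    rows, Xs = [], []
    subjects = {"h1": "HC", "h2": "HC", "p1": "PD", "p2": "PD"}
    days = recorded if recorded is not None else list(range(n_days))
    for sid in subjects:
        for day in days:
            for k in range(3):
                rows.append((sid, day, day * 86_400_000 + k * 5000))
                Xs.append(rng.normal(size=(6, 100)).astype(np.float32))
    meta = pd.DataFrame(rows, columns=["subject_id", "day_index", "start_time"])
    return WindowDataset(X=np.stack(Xs), meta=meta, diagnosis=subjects)


class TestLeakageGuards:
    def test_validation_subject_never_in_training(self):
        ds = _toy_dataset()
        plan = FoldPlan(folds=((("h1", "h2", "p1"), "h1"),), train_day_limit=10)
        with pytest.raises(LeakageError):
            run_logo_cv(ds, CNNConfig(max_epochs=1, warmup_epochs=0), plan)

    def test_holdout_overlapping_training_rejected(self):
        # sparse recording: the subject's first 10 recorded days reach day 31,
        # so a month-1 holdout block would overlap the training interval
        ds = _toy_dataset(recorded=[0, 1, 2, 3, 4, 5, 6, 7, 8, 31, 32, 33])
        plan = FoldPlan(
            folds=((("h2", "p1", "p2"), "h1"),), train_day_limit=10
        )
        with pytest.raises(LeakageError):
            run_logo_cv(
                ds, CNNConfig(max_epochs=1, warmup_epochs=0), plan, holdout_months=(1,)
            )

    def test_missing_holdout_reported_absent(self):
        ds = _toy_dataset(n_days=10)  # no data a month out
        assert holdout_days(ds, "h1", month=1).size == 0
        res = run_logo_cv(
            ds, CNNConfig(max_epochs=1, warmup_epochs=0), holdout_months=(1,)
        )
        assert set(res["events"]["period"]) == {"validation"}


class TestWalkDurationSummary:
    def _annotations(self, n_walk_by_day, sid="s1", label_other=120):
        frames = []
        for day, n_walk in enumerate(n_walk_by_day):
            labels = ["walk_like"] * n_walk + ["static"] * label_other
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": sid,
                        "day_index": day,
                        "start_time": np.arange(len(labels)),
                        "label": labels,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def test_720_windows_is_one_hour(self):
        ann = self._annotations([720])
        s = walk_duration_summary(ann, {"s1": "HC"})
        assert s.daily_hours["hours"].iloc[0] == pytest.approx(1.0)
        assert s.p_value is None  # single group: no test

    def test_identical_groups_null(self):
        a = self._annotations([60, 80, 100], sid="hc")
        b = self._annotations([60, 80, 100], sid="pd")
        s = walk_duration_summary(pd.concat([a, b]), {"hc": "HC", "pd": "PD"})
        assert s.group_means["HC"] == pytest.approx(s.group_means["PD"])
        assert s.p_value == pytest.approx(1.0)

    def test_simulated_hc_walks_more(self, small_cohort):
        s = walk_duration_summary(
            small_cohort.annotations, small_cohort.dataset.diagnosis
        )
        assert s.group_means["HC"] > s.group_means["PD"]


def test_sensor_subset_runs_identical_folds(small_cohort):
    ds = small_cohort.dataset
    plan = make_logo_folds(ds.diagnosis)
    cfg = CNNConfig(max_epochs=2, warmup_epochs=0, seed=0)
    res_both = run_logo_cv(ds, cfg, plan, sensors="both")
    res_acc = run_logo_cv(ds, cfg, plan, sensors="acc")
    assert res_both["plan"] == res_acc["plan"]
    assert res_acc["sensors"] == "acc"
    # same events scored, only the channel mask differs
    pd.testing.assert_frame_equal(
        res_both["events"][["subject_id", "day_index", "start_time"]],
        res_acc["events"][["subject_id", "day_index", "start_time"]],
    )
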
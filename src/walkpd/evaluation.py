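"""Leave-one-subject-out evaluation, daily majority voting, and summaries.

Protocol: every subject is held out once (leave-one-group-out, subject =
group). Within each fold the model trains on the training subjects' first 10
recorded days and is validated on the held-out subject's first 10 recorded
days; temporal stability is then tested on 5-day holdout blocks starting 30,
60 and 90 days after the subject's first recording day. The final per-day
diagnosis is the majority vote over that day's single-event classifications
(ties vote PD, favouring sensitivity).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import har
from .cnn import CNNConfig, EventClassifier
from .io import downsample, segment_windows, windows_to_array
from .synthetic import SimulationConfig, iter_subject_days, subject_ids

ANALYSIS_RATE = 20.0
WINDOW_SECONDS = 5.0


@dataclass(frozen=True)
class FoldPlan:
    """LOGO folds: one (train subjects, validation subject) pair per subject."""

    folds: tuple[tuple[tuple[str, ...], str], ...]
    train_day_limit: int = 10


@dataclass(frozen=True)
class DailyDecision:
    subject_id: str
    day_index: int
    n_events: int
    pd_vote_fraction: float
    decided: str  # "PD" | "HC"


class LeakageError(RuntimeError):
    """Train/validation subject or time overlap detected."""


def make_logo_folds(
    subjects: Mapping[str, str], train_day_limit: int = 10
) -> FoldPlan:
    """One fold per subject; requires >= 2 subjects and both classes overall."""
    ids = sorted(subjects)
    if len(ids) < 2:
        raise ValueError("LOGO needs at least two subjects")
    if len(set(subjects.values())) < 2:
        raise ValueError("both diagnosis classes must be present")
    folds = tuple(
        (tuple(s for s in ids if s != held_out), held_out) for held_out in ids
    )
    return FoldPlan(folds=folds, train_day_limit=train_day_limit)


def daily_majority_vote(preds: pd.DataFrame) -> DailyDecision:
    """Majority vote over one subject-day of event predictions (tie -> PD)."""
    if len(preds) == 0:
        raise ValueError("no events in day: no decision possible")
    sids = preds["subject_id"].unique()
    days = preds["day_index"].unique()
    if len(sids) != 1 or len(days) != 1:
        raise ValueError("daily_majority_vote expects a single subject-day")
    frac = float((preds["predicted"] == "PD").mean())
    return DailyDecision(
        subject_id=str(sids[0]),
        day_index=int(days[0]),
        n_events=len(preds),
        pd_vote_fraction=frac,
        decided="PD" if frac >= 0.5 else "HC",
    )


def daily_decisions(preds: pd.DataFrame) -> pd.DataFrame:
    """Daily majority votes for every subject-day present in *preds*."""
    rows = [
        daily_majority_vote(g).__dict__
        for _, g in preds.groupby(["subject_id", "day_index"], sort=True)
    ]
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# window dataset
# --------------------------------------------------------------------------


@dataclass
class WindowDataset:
    """Walk-like windows pooled across the cohort, ready for modelling."""

    X: np.ndarray  # (N, 6, L) float32 at the analysis rate
    meta: pd.DataFrame  # subject_id, day_index, start_time
    diagnosis: dict[str, str]  # subject -> "HC" | "PD"
    sample_rate: float = ANALYSIS_RATE
    #: all recorded days per subject (walk events or not); defaults to the
    #: days that produced walk-like windows when no fuller source is known
    recorded_days: dict[str, np.ndarray] | None = None

    def labels(self) -> np.ndarray:
        return (
            self.meta["subject_id"].map(self.diagnosis).eq("PD").to_numpy().astype(int)
        )

    def days(self, subject: str) -> np.ndarray:
        if self.recorded_days is not None and subject in self.recorded_days:
            return np.asarray(self.recorded_days[subject])
        return np.unique(self.meta.loc[self.meta["subject_id"] == subject, "day_index"])

    def first_days(self, subject: str, k: int) -> np.ndarray:
        return self.days(subject)[:k]

    def select(self, subject: str, days: np.ndarray) -> np.ndarray:
        m = self.meta
        return np.flatnonzero(
            (m["subject_id"] == subject).to_numpy() & m["day_index"].isin(days).to_numpy()
        )


SENSOR_CHANNELS = {"both": (0, 1, 2, 3, 4, 5), "acc": (0, 1, 2), "gyro": (3, 4, 5)}


def holdout_days(
    dataset: WindowDataset, subject: str, month: int, block_days: int = 5
) -> np.ndarray:
    """First *block_days* recorded days starting 30*month days after day 0."""
    days = dataset.days(subject)
    first = days[0] if days.size else 0
    sel = days[(days >= first + 30 * month) & (days < first + 30 * (month + 1))]
    return sel[:block_days]


def _inner_val_subjects(
    train_ids: Sequence[str], diagnosis: Mapping[str, str]
) -> tuple[str, ...]:
    """Early-stopping subjects held out of the gradient set, one per class.

    Monitoring generalization on subjects the optimizer never sees keeps model
    selection honest: the leave-one-out test subject plays no role in training
    at all. Deterministic (last subject of each class in sorted order). If a
    class would be emptied, returns () and the caller monitors training loss.
    """
    by_class: dict[str, list[str]] = {}
    for s in sorted(train_ids):
        by_class.setdefault(diagnosis[s], []).append(s)
    if len(by_class) == 2 and all(len(v) >= 2 for v in by_class.values()):
        return tuple(v[-1] for v in by_class.values())
    return ()


def run_logo_cv(
    dataset: WindowDataset,
    cnn_cfg: CNNConfig,
    plan: FoldPlan | None = None,
    sensors: str = "both",
    holdout_months: Sequence[int] = (),
    holdout_block_days: int = 5,
) -> dict:
    """Train the event classifier under LOGO-CV and collect predictions.

    Returns a dict with ``events`` (validation + holdout predictions with
    truth and a period tag), ``daily`` (majority votes), ``per_subject``
    (event/daily accuracies per period), and the fitted fold classifiers.
    """
    if plan is None:
        plan = make_logo_folds(dataset.diagnosis)
    chans = list(SENSOR_CHANNELS[sensors])
    y = dataset.labels()
    all_events = []
    models: dict[str, EventClassifier] = {}
    for train_ids, val_id in plan.folds:
        if val_id in train_ids:
            raise LeakageError(f"validation subject {val_id} present in training set")
        inner_val = _inner_val_subjects(train_ids, dataset.diagnosis)
        grad_ids = [s for s in train_ids if s not in inner_val]
        tr_idx = np.concatenate(
            [
                dataset.select(s, dataset.first_days(s, plan.train_day_limit))
                for s in grad_ids
            ]
        )
        iv_idx = (
            np.concatenate(
                [
                    dataset.select(s, dataset.first_days(s, plan.train_day_limit))
                    for s in inner_val
                ]
            )
            if inner_val
            else np.array([], dtype=int)
        )
        val_days = dataset.first_days(val_id, plan.train_day_limit)
        va_idx = dataset.select(val_id, val_days)
        touched = set(dataset.meta.loc[tr_idx, "subject_id"]) | set(
            dataset.meta.loc[iv_idx, "subject_id"]
        )
        if val_id in touched:
            raise LeakageError("validation subject windows leaked into training")
        L = dataset.X.shape[2]
        selector = EventClassifier(replace(cnn_cfg), in_channels=len(chans), input_length=L)
        selector.fit(
            dataset.X[tr_idx][:, chans, :],
            y[tr_idx],
            dataset.X[iv_idx][:, chans, :] if iv_idx.size else None,
            y[iv_idx] if iv_idx.size else None,
        )
        n_epochs = selector.history.best_epoch + 1
        if inner_val and n_epochs > 0:
            # select-then-refit: the inner-val run only chooses the epoch
            # budget; the fold model retrains on every training subject
            all_idx = np.concatenate([tr_idx, iv_idx])
            clf = EventClassifier(
                replace(cnn_cfg, max_epochs=n_epochs, patience=n_epochs + 1),
                in_channels=len(chans),
                input_length=L,
            )
            clf.fit(dataset.X[all_idx][:, chans, :], y[all_idx])
        else:
            # no inner validation possible, or no epoch beat the abstaining
            # baseline (no transferable signal): keep the selector's weights
            clf = selector
        models[val_id] = clf

        def _collect(idx: np.ndarray, period: str) -> None:
            if idx.size == 0:
                return
            ev = clf.predict_events(dataset.X[idx][:, chans, :], dataset.meta.iloc[idx])
            ev["truth"] = np.where(y[idx] == 1, "PD", "HC")
            ev["period"] = period
            all_events.append(ev)

        _collect(va_idx, "validation")
        for month in holdout_months:
            hdays = holdout_days(dataset, val_id, month, holdout_block_days)
            if hdays.size == 0:
                continue  # reported as absent
            if np.intersect1d(hdays, val_days).size:
                raise LeakageError("holdout block overlaps the training interval")
            _collect(dataset.select(val_id, hdays), f"month{month}")

    events = pd.concat(all_events, ignore_index=True)
    events["correct"] = events["predicted"] == events["truth"]
    daily = (
        events.groupby("period", sort=True)
        .apply(lambda g: daily_decisions(g), include_groups=False)
        .reset_index(level=0)
        .reset_index(drop=True)
    )
    daily["truth"] = daily["subject_id"].map(dataset.diagnosis)
    daily["correct"] = daily["decided"] == daily["truth"]
    per_subject = (
        events.groupby(["period", "subject_id"], sort=True)
        .agg(event_accuracy=("correct", "mean"), n_events=("correct", "size"))
        .reset_index()
    )
    per_subject["diagnosis"] = per_subject["subject_id"].map(dataset.diagnosis)
    dd = (
        daily.groupby(["period", "subject_id"], sort=True)["correct"]
        .mean()
        .rename("daily_accuracy")
        .reset_index()
    )
    per_subject = per_subject.merge(dd, on=["period", "subject_id"], how="left")
    return {
        "events": events,
        "daily": daily,
        "per_subject": per_subject,
        "models": models,
        "plan": plan,
        "sensors": sensors,
    }


def class_mean_accuracy(per_subject: pd.DataFrame, period: str = "validation") -> dict:
    """Mean per-subject event accuracy by diagnosis class, as fractions."""
    sub = per_subject[per_subject["period"] == period]
    out = sub.groupby("diagnosis")["event_accuracy"].mean()
    return {k: float(v) for k, v in out.items()}


# --------------------------------------------------------------------------
# walk-duration summary
# --------------------------------------------------------------------------


@dataclass
class WalkDurationSummary:
    daily_hours: pd.DataFrame  # subject_id, day_index, hours, diagnosis
    group_means: dict[str, float]
    t_statistic: float | None
    p_value: float | None


def walk_duration_summary(
    annotations: pd.DataFrame,
    diagnosis: Mapping[str, str],
    window_seconds: float = WINDOW_SECONDS,
) -> WalkDurationSummary:
    """Daily walk-like hours per subject plus a Welch t-test between groups."""
    counts = (
        annotations[annotations["label"] == "walk_like"]
        .groupby(["subject_id", "day_index"])
        .size()
        .rename("n_walk")
    )
    all_days = annotations.groupby(["subject_id", "day_index"]).size().rename("n_all")
    df = pd.concat([all_days, counts], axis=1).fillna(0).reset_index()
    df["hours"] = df["n_walk"] * window_seconds / 3600.0
    df["diagnosis"] = df["subject_id"].map(diagnosis)
    groups = {g: sub["hours"].to_numpy() for g, sub in df.groupby("diagnosis")}
    means = {g: float(v.mean()) for g, v in groups.items()}
    t_stat = p_val = None
    if len(groups) == 2:
        a, b = (groups.get("HC"), groups.get("PD"))
        res = stats.ttest_ind(a, b, equal_var=False)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    return WalkDurationSummary(
        daily_hours=df[["subject_id", "day_index", "hours", "diagnosis"]],
        group_means=means,
        t_statistic=t_stat,
        p_value=p_val,
    )


# --------------------------------------------------------------------------
# end-to-end pipeline on simulated cohorts
# --------------------------------------------------------------------------


@dataclass
class CohortWindows:
    """HAR output for a simulated cohort: all annotated windows plus truth."""

    dataset: WindowDataset  # walk-like windows only
    annotations: pd.DataFrame  # every window's HAR annotation
    window_truth: pd.DataFrame  # per-window ground-truth walk fraction
    thresholds: dict[str, har.SubjectThresholds]


def prepare_cohort_windows(cfg: SimulationConfig) -> CohortWindows:
    """Simulate, down-sample to 20 Hz, window, threshold, and annotate a cohort.

    Memory stays bounded: raw 100 Hz days are discarded once windowed.
    """
    diag = dict(subject_ids(cfg))
    thresholds: dict[str, har.SubjectThresholds] = {}
    ann_parts, truth_parts, walk_X, walk_meta = [], [], [], []
    factor = int(round(cfg.sample_rate / ANALYSIS_RATE))
    L = int(round(ANALYSIS_RATE * WINDOW_SECONDS))
    day0 = min(cfg.day_indices)
    for si, sid, diagnosis, day, sd in iter_subject_days(cfg):
        rec = downsample(sd.recording, ANALYSIS_RATE)
        windows = segment_windows(rec, WINDOW_SECONDS, day0=day0)
        if not windows:
            continue
        act20 = sd.activity[::factor][: len(rec)]
        if sid not in thresholds:  # first recorded day defines the thresholds
            thresholds[sid] = har.compute_subject_thresholds(windows)
        ann = har.annotate_windows(windows, thresholds[sid])
        ann_parts.append(ann)
        # ground-truth walk fraction per window, aligned by sample index
        frac = np.empty(len(windows))
        t0 = rec.timestamps[0]
        dt = 1000.0 / ANALYSIS_RATE
        for j, w in enumerate(windows):
            i0 = int(round((w.start_time - t0) / dt))
            seg = act20[i0 : i0 + L]
            frac[j] = float(np.mean(seg == 2)) if seg.size else 0.0
        tp = ann[["subject_id", "day_index", "start_time"]].copy()
        tp["walk_fraction"] = frac
        truth_parts.append(tp)
        is_walk = ann["label"].to_numpy() == "walk_like"
        if is_walk.any():
            X, meta = windows_to_array([w for w, k in zip(windows, is_walk) if k])
            walk_X.append(X)
            walk_meta.append(meta)
    X = np.concatenate(walk_X) if walk_X else np.zeros((0, 6, L), dtype=np.float32)
    meta = (
        pd.concat(walk_meta, ignore_index=True)
        if walk_meta
        else pd.DataFrame(columns=["subject_id", "day_index", "start_time"])
    )
    annotations = pd.concat(ann_parts, ignore_index=True)
    recorded = {
        sid: np.unique(sub["day_index"])
        for sid, sub in annotations.groupby("subject_id")
    }
    return CohortWindows(
        dataset=WindowDataset(X=X, meta=meta, diagnosis=diag, recorded_days=recorded),
        annotations=annotations,
        window_truth=pd.concat(truth_parts, ignore_index=True),
        thresholds=thresholds,
    )


def walk_detector_metrics(cohort: CohortWindows) -> dict[str, float]:
    """Sensitivity/specificity of the walk-like gate against simulator truth.

    Positives are windows lying fully inside a walk bout; negatives contain
    no walking at all. Boundary windows are ambiguous by construction and are
    not scored.
    """
    ann = cohort.annotations.merge(
        cohort.window_truth, on=["subject_id", "day_index", "start_time"]
    )
    pos = ann[ann["walk_fraction"] >= 1.0]
    neg = ann[ann["walk_fraction"] <= 0.0]
    sens = float((pos["label"] == "walk_like").mean())
    spec = float((neg["label"] != "walk_like").mean())
    return {
        "sensitivity": sens,
        "specificity": spec,
        "n_positive": len(pos),
        "n_negative": len(neg),
    }
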
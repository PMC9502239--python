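"""Comparison classifiers trained on the 35 hand-crafted window features.

Four methods mirror the study's comparison table: logistic regression,
random forest, gradient-boosted trees, and elastic net (realised as
elastic-net-penalized logistic classification, since the outcome is binary).
Linear methods standardize features with training-set statistics; tree
ensembles consume them raw. Each is evaluated under the identical
leave-one-subject-out folds as the convolutional model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .evaluation import FoldPlan, WindowDataset, make_logo_folds
from .features import extract_feature_matrix

BASELINE_METHODS = (
    "logistic_regression",
    "random_forest",
    "gradient_boosted_trees",
    "elastic_net",
)


@dataclass(frozen=True)
class BaselineSpec:
    method: str
    params: Mapping = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.method not in BASELINE_METHODS:
            raise ValueError(f"unknown baseline method {self.method!r}")


def _make_estimator(spec: BaselineSpec):
    p = dict(spec.params)
    if spec.method == "logistic_regression":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(max_iter=2000, **p)),
            ]
        )
    if spec.method == "elastic_net":
        defaults = dict(solver="saga", l1_ratio=0.5, max_iter=5000)
        defaults.update(p)
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(random_state=spec.seed, **defaults)),
            ]
        )
    if spec.method == "random_forest":
        return RandomForestClassifier(random_state=spec.seed, **p)
    return GradientBoostingClassifier(random_state=spec.seed, **p)


def fit_baseline(spec: BaselineSpec, features: np.ndarray, labels: np.ndarray):
    """Fit one baseline; deterministic given the spec's seed."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    est = _make_estimator(spec)
    est.fit(np.asarray(features, dtype=float), labels)
    return est


def evaluate_baselines(
    specs: list[BaselineSpec],
    dataset: WindowDataset,
    plan: FoldPlan | None = None,
) -> pd.DataFrame:
    """Per-method, per-class mean accuracies under shared LOGO folds.

    Accuracy is averaged per validation subject, then across subjects of each
    diagnosis class (one row per method, columns hc/pd mean accuracy).
    """
    if plan is None:
        plan = make_logo_folds(dataset.diagnosis)
    F = extract_feature_matrix(dataset.X, dataset.sample_rate)
    y = dataset.labels()
    rows = []
    for spec in specs:
        subj_acc: dict[str, float] = {}
        for train_ids, val_id in plan.folds:
            tr = np.concatenate(
                [
                    dataset.select(s, dataset.first_days(s, plan.train_day_limit))
                    for s in train_ids
                ]
            )
            va = dataset.select(val_id, dataset.first_days(val_id, plan.train_day_limit))
            if va.size == 0:
                continue
            est = fit_baseline(spec, F[tr], y[tr])
            subj_acc[val_id] = float(np.mean(est.predict(F[va]) == y[va]))
        acc = pd.Series(subj_acc)
        diag = acc.index.map(dataset.diagnosis)
        rows.append(
            {
                "method": spec.method,
                "hc_mean_accuracy": float(acc[diag == "HC"].mean()),
                "pd_mean_accuracy": float(acc[diag == "PD"].mean()),
            }
        )
    return pd.DataFrame(rows)


def default_specs(seed: int = 0) -> list[BaselineSpec]:
    return [BaselineSpec(method=m, seed=seed) for m in BASELINE_METHODS]
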
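"""Within-reader leave-one-case-out prediction of decisions.

For each reader and lag depth the current decision is predicted from
current/lagged FD, density group and prior decisions under
leave-one-case-out cross-validation, scored by the support-weighted
f-score, and compared with a marginal random-guessing baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import LeaveOneOut

from .errors import DegenerateLabelsError, SpecificationError
from .sequence_context import (
    DECISION_ORDER,
    DENSITY_GROUP_ORDER,
    DECISION_GROUPS,
    LagPairDataset,
    build_lag_pairs,
)

MODEL_FAMILIES = ("random-forest", "majority", "stratified-random")


@dataclass
class ModelSpec:
    family: str = "random-forest"
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise SpecificationError(
                f"unknown model family {self.family!r}; choose from {MODEL_FAMILIES}"
            )


def _make_estimator(spec: ModelSpec):
    if spec.family == "random-forest":
        params = {
            "n_estimators": 500,
            "max_features": "sqrt",
            "max_depth": None,
            "random_state": spec.seed,
            "n_jobs": 1,
        }
        params.update(spec.hyperparams)
        return RandomForestClassifier(**params)
    if spec.family == "majority":
        return DummyClassifier(strategy="most_frequent")
    return DummyClassifier(strategy="stratified", random_state=spec.seed)


def feature_matrix(frame: pd.DataFrame, target_groups: bool = False) -> np.ndarray:
    """One-hot lagged categoricals, FD raw; fixed category sets keep the
    column layout stable across folds."""
    cols = []
    for name in frame.columns:
        if name == "D0":
            continue
        if name.startswith("F"):
            cols.append(frame[name].to_numpy(dtype=float)[:, None])
        else:
            categories = DENSITY_GROUP_ORDER if name.startswith("P") else DECISION_ORDER
            values = frame[name]
            cols.append(
                np.column_stack(
                    [(values == c).to_numpy(dtype=float) for c in categories]
                )
            )
    return np.column_stack(cols)


def response_vector(frame: pd.DataFrame, target: str = "category") -> np.ndarray:
    """Response labels: raw 7-category ratings or their 3-level group."""
    if target == "category":
        return frame["D0"].to_numpy(dtype=object)
    if target == "group":
        return frame["D0"].map(DECISION_GROUPS).to_numpy(dtype=object)
    raise SpecificationError(f"unknown target {target!r}")


def loocv_predict(dataset, spec: ModelSpec, target: str = "category") -> np.ndarray:
    """One held-out prediction per row; fresh model fit per fold."""
    frame = dataset.frame if isinstance(dataset, LagPairDataset) else dataset
    if len(frame) < 10:
        raise ValueError(f"need at least 10 rows for LOOCV, got {len(frame)}")
    y = response_vector(frame, target)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("dataset holds a single response class")
    X = feature_matrix(frame)
    base = _make_estimator(spec)
    preds = np.empty(len(frame), dtype=object)
    for train_idx, test_idx in LeaveOneOut().split(X):
        model = clone(base)
        model.fit(X[train_idx], y[train_idx])
        preds[test_idx] = model.predict(X[test_idx])
    return preds


def weighted_f_score(truth, predicted) -> float:
    """Support-weighted mean of per-class F1 (0 where P + R = 0)."""
    truth = np.asarray(truth, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted lengths differ")
    if len(truth) == 0:
        raise ValueError("empty inputs")
    return float(
        f1_score(
            truth,
            predicted,
            labels=np.unique(truth),
            average="weighted",
            zero_division=0,
        )
    )


def random_chance_baseline(truth, reps: int = 1000, seed: int = 0) -> float:
    """Mean weighted f-score of guesses drawn from the empirical label
    distribution of ``truth``."""
    truth = np.asarray(truth, dtype=object)
    if len(truth) == 0:
        raise ValueError("empty truth sequence")
    if reps < 100:
        raise ValueError("reps must be >= 100")
    rng = np.random.default_rng(seed)
    scores = [
        weighted_f_score(truth, rng.choice(truth, size=len(truth), replace=True))
        for _ in range(reps)
    ]
    return float(np.mean(scores))


def tier_average(values) -> float:
    """Arithmetic mean rounded to 2 decimals (display convention)."""
    return round(float(np.mean(np.asarray(values, dtype=float))), 2)


def percent_improvement(score: float, baseline: float) -> int:
    """100 * (score - baseline) / baseline, rounded to nearest integer."""
    return int(round(100.0 * (score - baseline) / baseline))


def _tier_of(reader_id: str, tiers: dict | None) -> str:
    if tiers and reader_id in tiers:
        return tiers[reader_id]
    return str(reader_id)[0]


def sweep_lags(
    readings: pd.DataFrame,
    spec: ModelSpec,
    lags=range(6),
    target: str = "category",
    baseline_reps: int = 1000,
    tiers: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """LOOCV f-score per reader x lag plus per-tier averages.

    ``readings`` holds all readers (columns reader_id, order_index,
    session_segment, decision, density, fd).  Returns ``(report,
    tier_report)``; the chance baseline is computed once per reader from
    the lag-0 labels.
    """
    rows = []
    for reader_id, sub in readings.groupby("reader_id", sort=True):
        tier = _tier_of(reader_id, tiers)
        baseline = None
        for lag in lags:
            dataset = build_lag_pairs(sub, lag)
            truth = response_vector(dataset.frame, target)
            if baseline is None:
                baseline = random_chance_baseline(
                    truth, reps=baseline_reps, seed=spec.seed
                )
            preds = loocv_predict(dataset, spec, target)
            rows.append(
                {
                    "reader_id": reader_id,
                    "tier": tier,
                    "lag": int(lag),
                    "f_weighted": weighted_f_score(truth, preds),
                    "baseline": baseline,
                    "n": dataset.m,
                }
            )
    report = pd.DataFrame(rows)
    tier_report = (
        report.groupby(["tier", "lag"], sort=True)
        .agg(
            f_weighted=("f_weighted", tier_average),
            baseline=("baseline", tier_average),
            n_readers=("reader_id", "count"),
        )
        .reset_index()
    )
    return report, tier_report
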
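"""Polynomial-kernel SVM risk stratification.

A degree-3 polynomial-kernel SVM is trained on standardized feature
vectors (melanoma = positive class, class-balanced weights).  Two
operating points are then placed on the single decision axis: a
high-sensitivity threshold (the largest cutoff keeping at least the
target fraction of training melanomas above it) and a high-specificity
threshold (the smallest cutoff keeping at least the target fraction of
training naevi below it).  A lesion scoring below both is *low* risk,
above both *high*, and between them *middle* — the two cutoffs play the
role of two classifiers whose agreement or disagreement is reported.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .config import PipelineConfig

__all__ = [
    "LabeledSet",
    "TrainedModel",
    "RiskReport",
    "train",
    "predict_risk",
    "cross_validate",
    "kfold_balanced_accuracy",
    "model_to_json",
    "model_from_json",
]

NAEVUS, MELANOMA = "naevus", "melanoma"


@dataclass
class LabeledSet:
    vectors: np.ndarray  # (n_samples, n_features)
    labels: list         # "naevus" / "melanoma"
    ids: list

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if len(self.vectors) != len(self.labels) or len(self.labels) != len(self.ids):
            raise ValueError("vectors/labels/ids length mismatch")
        bad = set(self.labels) - {NAEVUS, MELANOMA}
        if bad:
            raise ValueError(f"unknown labels: {bad}")

    def __len__(self):
        return len(self.labels)

    def subset(self, idx):
        idx = np.asarray(idx)
        return LabeledSet(
            vectors=self.vectors[idx],
            labels=[self.labels[i] for i in idx],
            ids=[self.ids[i] for i in idx],
        )

    @property
    def y(self):
        return np.array([1 if l == MELANOMA else 0 for l in self.labels])


@dataclass
class TrainedModel:
    """Standardization + poly-3 SVM decision function + two thresholds.

    The decision axis is oriented so that larger means more melanoma-like;
    ``threshold_high_sens <= threshold_high_spec`` always holds.
    """

    mean: np.ndarray
    scale: np.ndarray
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma: float
    coef0: float
    degree: int
    threshold_high_sens: float
    threshold_high_spec: float
    config: dict = field(default_factory=dict)

    def decision_values(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != len(self.mean):
            raise ValueError(
                f"feature length {X.shape[1]} != expected {len(self.mean)}"
            )
        Z = (X - self.mean) / self.scale
        K = (self.gamma * (Z @ self.support_vectors.T) + self.coef0) ** self.degree
        return K @ self.dual_coef + self.intercept


@dataclass
class RiskReport:
    id: object
    decision_value: float
    call_sensitive: str
    call_specific: str
    risk: str


def _standardize_fit(X):
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    return mean, scale


def _sens_threshold(mel_scores, target):
    # Largest cutoff t with at least ceil(target * n) melanomas scoring >= t.
    k = int(math.ceil(target * len(mel_scores)))
    return float(np.sort(mel_scores)[::-1][k - 1])

def _spec_threshold(all_scores, naevi_scores, target):
    # Smallest observed cutoff t with at least ceil(target * n) naevi
    # scoring strictly below t.
    need = int(math.ceil(target * len(naevi_scores)))
    srt = np.sort(naevi_scores)
    cands = np.concatenate([np.unique(all_scores), [all_scores.max() + 1.0]])
    for t in cands:
        if np.searchsorted(srt, t, side="left") >= need:
            return float(t)
    return float(cands[-1])


def train(data: LabeledSet, config: PipelineConfig | None = None, seed: int = 0) -> TrainedModel:
    """Fit the standardized poly-3 SVM and place the two operating points.

    Deterministic given the data order (the SMO solver has no random
    component for a fixed problem; ``seed`` is accepted for interface
    uniformity).
    """
    config = config or PipelineConfig()
    y = data.y
    n_mel, n_nav = int(y.sum()), int((1 - y).sum())
    if n_mel == 0 or n_nav == 0:
        raise ValueError("training data must contain both classes")
    if n_mel < 5 or n_nav < 5:
        raise ValueError("need at least 5 samples per class")
    X = data.vectors
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    mean, scale = _standardize_fit(X)
    Z = (X - mean) / scale
    svc = SVC(
        C=config.svm_c,
        kernel="poly",
        degree=config.svm_degree,
        gamma=config.svm_gamma,
        coef0=config.svm_coef0,
        class_weight="balanced",
        tol=1e-8,  # tight SMO tolerance: reproducible decision values
        random_state=seed,
    )
    svc.fit(Z, y)
    model = TrainedModel(
        mean=mean,
        scale=scale,
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_.ravel().copy(),
        intercept=float(svc.intercept_[0]),
        gamma=config.svm_gamma,
        coef0=config.svm_coef0,
        degree=config.svm_degree,
        threshold_high_sens=0.0,
        threshold_high_spec=0.0,
        config={"svm_c": config.svm_c},
    )
    scores = model.decision_values(X)
    t_sens = _sens_threshold(scores[y == 1], config.target_sensitivity)
    t_spec = _spec_threshold(scores, scores[y == 0], config.target_specificity)
    model.threshold_high_sens = t_sens
    model.threshold_high_spec = max(t_spec, t_sens)
    return model


def predict_risk(model: TrainedModel, v, id=None) -> RiskReport:
    """Risk report for one feature vector: the two calls and their
    agreement (low/middle/high)."""
    dv = float(model.decision_values(np.asarray(v, dtype=float).reshape(1, -1))[0])
    call_s = MELANOMA if dv >= model.threshold_high_sens else NAEVUS
    call_p = MELANOMA if dv >= model.threshold_high_spec else NAEVUS
    if call_s == NAEVUS and call_p == NAEVUS:
        risk = "low"
    elif call_s == MELANOMA and call_p == MELANOMA:
        risk = "high"
    else:
        risk = "middle"
    return RiskReport(
        id=id, decision_value=dv, call_sensitive=call_s, call_specific=call_p, risk=risk
    )


def _fold_metrics(model, test: LabeledSet, threshold=0.0):
    scores = model.decision_values(test.vectors)
    y = test.y
    pred = scores >= threshold
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    sens = tp / max(int(y.sum()), 1)
    spec = tn / max(int((1 - y).sum()), 1)
    fpr, tpr, thr = roc_curve(y, scores)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "roc": {"fpr": fpr.tolist(), "tpr": tpr.tolist(), "thresholds": thr.tolist()},
        "auc": float(auc(fpr, tpr)),
        "n_test": len(test),
    }


def cross_validate(
    data: LabeledSet,
    scheme: str = "H",
    seed: int = 0,
    config: PipelineConfig | None = None,
    train_counts=None,
):
    """Hold-out evaluation under two splitting schemes.

    Scheme ``"H"`` assigns every second sample (in id order) to the
    training set; scheme ``"R"`` draws a random training set with
    ``train_counts = (n_naevi, n_melanomas)`` (default: half of each
    class) and tests on the complement.  Returns sensitivity, specificity
    at the zero cutoff, and the full ROC of the test scores.
    """
    config = config or PipelineConfig()
    y = data.y
    if int(y.sum()) < 10 or int((1 - y).sum()) < 10:
        raise ValueError("need at least 10 samples per class")
    n = len(data)
    if scheme == "H":
        train_idx = np.arange(0, n, 2)
        test_idx = np.arange(1, n, 2)
    elif scheme == "R":
        rng = np.random.default_rng(seed)
        nav = np.nonzero(y == 0)[0]
        mel = np.nonzero(y == 1)[0]
        if train_counts is None:
            k_nav, k_mel = len(nav) // 2, len(mel) // 2
        else:
            k_nav, k_mel = train_counts
        if k_nav < 1 or k_mel < 1 or k_nav >= len(nav) or k_mel >= len(mel):
            raise ValueError("infeasible train_counts for scheme R")
        train_idx = np.sort(
            np.concatenate(
                [
                    rng.choice(nav, size=k_nav, replace=False),
                    rng.choice(mel, size=k_mel, replace=False),
                ]
            )
        )
        test_idx = np.setdiff1d(np.arange(n), train_idx)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    model = train(data.subset(train_idx), config=config, seed=seed)
    out = _fold_metrics(model, data.subset(test_idx))
    out["scheme"] = scheme
    out["n_train"] = len(train_idx)
    return out


def kfold_balanced_accuracy(
    data: LabeledSet, k: int = 5, seed: int = 0, config: PipelineConfig | None = None
):
    """Stratified k-fold cross-validated balanced accuracy at the zero
    cutoff, plus the per-sample risk reports from each held-out fold."""
    config = config or PipelineConfig()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y = data.y
    sens, spec, reports = [], [], []
    for tr, te in skf.split(data.vectors, y):
        model = train(data.subset(tr), config=config, seed=seed)
        m = _fold_metrics(model, data.subset(te))
        sens.append(m["sensitivity"])
        spec.append(m["specificity"])
        for i in te:
            reports.append(predict_risk(model, data.vectors[i], id=data.ids[i]))
    balanced = float((np.mean(sens) + np.mean(spec)) / 2.0)
    return {
        "balanced_accuracy": balanced,
        "sensitivity": float(np.mean(sens)),
        "specificity": float(np.mean(spec)),
        "reports": reports,
    }


def model_to_json(model: TrainedModel) -> str:
    return json.dumps(
        {
            "mean": model.mean.tolist(),
            "scale": model.scale.tolist(),
            "support_vectors": model.support_vectors.tolist(),
            "dual_coef": model.dual_coef.tolist(),
            "intercept": model.intercept,
            "gamma": model.gamma,
            "coef0": model.coef0,
            "degree": model.degree,
            "threshold_high_sens": model.threshold_high_sens,
            "threshold_high_spec": model.threshold_high_spec,
            "config": model.config,
        }
    )


def model_from_json(s: str) -> TrainedModel:
    o = json.loads(s)
    return TrainedModel(
        mean=np.asarray(o["mean"]),
        scale=np.asarray(o["scale"]),
        support_vectors=np.asarray(o["support_vectors"]),
        dual_coef=np.asarray(o["dual_coef"]),
        intercept=float(o["intercept"]),
        gamma=float(o["gamma"]),
        coef0=float(o["coef0"]),
        degree=int(o["degree"]),
        threshold_high_sens=float(o["threshold_high_sens"]),
        threshold_high_spec=float(o["threshold_high_spec"]),
        config=o.get("config", {}),
    )
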
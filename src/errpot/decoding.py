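"""Leave-one-subject-out decoding of correct vs incorrect feedback.

Each fold holds out one subject as the target; the remaining subjects'
feature vectors are pooled into the source. With the optimal-transport
arm enabled, the source is coupled to the target by regularized OT,
relocated by barycentric mapping, and a classifier trained on the
transported source predicts the target's trials. The baseline arm trains
directly on the pooled raw source. Metrics treat 'incorrect' (the
error-related-potential class) as positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (AdaBoostClassifier, BaggingClassifier,
                              RandomForestClassifier)
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .erp_stats import wilcoxon_signed_rank
from .preprocessing import FeatureMatrix
from .transport import (CostMatrix, OTConfig, barycentric_map, cost_matrix,
                        empirical_measure, group_lasso_transport)

__all__ = [
    "ClassifierSpec",
    "MetricsReport",
    "train_classifier",
    "compute_metrics",
    "loso_evaluate",
    "run_ablation",
]

logger = logging.getLogger(__name__)

POSITIVE_CLASS = "incorrect"


@dataclass(frozen=True)
class ClassifierSpec:
    """Named classifier with the fixed hyperparameters used in this study.

    The random forest (100 trees, Gini, bootstrap) is the primary
    decoder; the others are comparison baselines with their published
    grid-search winners.
    """

    kind: str = "random_forest"
    seed: int = 0

    _KINDS = ("random_forest", "lda", "logistic", "linear_svm",
              "bagging_lda", "adaboost")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")

    def build(self):
        if self.kind == "random_forest":
            return RandomForestClassifier(n_estimators=100, criterion="gini",
                                          bootstrap=True, random_state=self.seed)
        if self.kind == "lda":
            return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        if self.kind == "logistic":
            return LogisticRegression(C=1000.0, tol=1e-4, solver="lbfgs",
                                      max_iter=100)
        if self.kind == "linear_svm":
            return LinearSVC(penalty="l2", loss="hinge", tol=1e-4, C=1.0,
                             max_iter=1000)
        if self.kind == "bagging_lda":
            return BaggingClassifier(
                estimator=LinearDiscriminantAnalysis(solver="lsqr",
                                                     shrinkage="auto"),
                n_estimators=100, bootstrap=True, random_state=self.seed)
        if self.kind == "adaboost":
            return AdaBoostClassifier(
                estimator=DecisionTreeClassifier(max_depth=1),
                n_estimators=100, learning_rate=1.0, random_state=self.seed)
        raise AssertionError


@dataclass
class MetricsReport:
    """Per-subject precision/recall/F1 (percent) for one pipeline variant."""

    pipeline: str
    classifier: str
    label_mode: str
    subjects: list[str] = field(default_factory=list)
    precision: list[float] = field(default_factory=list)
    recall: list[float] = field(default_factory=list)
    f1: list[float] = field(default_factory=list)
    weighted_f1: list[float] = field(default_factory=list)
    confusion: list[dict] = field(default_factory=list)

    def add(self, subject: str, y_true, y_pred) -> None:
        p, r, f = compute_metrics(y_true, y_pred)
        self.subjects.append(subject)
        self.precision.append(p)
        self.recall.append(r)
        self.f1.append(f)
        self.weighted_f1.append(weighted_f1_score(y_true, y_pred))
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos = POSITIVE_CLASS
        self.confusion.append({
            "tp": int(np.sum((y_true == pos) & (y_pred == pos))),
            "fp": int(np.sum((y_true != pos) & (y_pred == pos))),
            "fn": int(np.sum((y_true == pos) & (y_pred != pos))),
            "tn": int(np.sum((y_true != pos) & (y_pred != pos))),
        })

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.f1))

    def to_frame(self) -> pd.DataFrame:
        """Table shaped like the published per-subject result tables."""
        df = pd.DataFrame({"Precision": self.precision, "Recall": self.recall,
                           "F1-Score": self.f1}, index=self.subjects)
        df.loc["Mean"] = df.mean()
        df.loc["SD"] = df.iloc[:-1].std(ddof=1)
        return df


def train_classifier(features: FeatureMatrix | tuple, spec: ClassifierSpec):
    """Fit the configured classifier; deterministic for a fixed seed."""
    if isinstance(features, FeatureMatrix):
        X, y = features.X, features.y
    else:
        X, y = features
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    model = spec.build()
    model.fit(X, y.astype(str))
    return model


def compute_metrics(y_true, y_pred,
                    positive_class: str = POSITIVE_CLASS
                    ) -> tuple[float, float, float]:
    """Positive-class precision, recall and F1 = 2PR/(P+R), in percent.

    Zero denominators yield 0 with a logged warning (no error-class
    predictions, or no error trials in the fold).
    """
    y_true = np.asarray(y_true).astype(str)
    y_pred = np.asarray(y_pred).astype(str)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    tp = np.sum((y_true == positive_class) & (y_pred == positive_class))
    fp = np.sum((y_true != positive_class) & (y_pred == positive_class))
    fn = np.sum((y_true == positive_class) & (y_pred != positive_class))
    if tp + fp == 0:
        logger.warning("no positive predictions; precision set to 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        logger.warning("no positive instances; recall set to 0")
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return 100.0 * precision, 100.0 * recall, 100.0 * f1


def weighted_f1_score(y_true, y_pred) -> float:
    """Support-weighted two-class F1 (percent), the secondary report."""
    y_true = np.asarray(y_true).astype(str)
    total = len(y_true)
    score = 0.0
    for cls in np.unique(y_true):
        _, _, f = compute_metrics(y_true, y_pred, positive_class=cls)
        score += f * np.sum(y_true == cls) / total
    return float(score)


def _pool(features: list[FeatureMatrix]) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack([f.X for f in features])
    y = np.concatenate([f.y for f in features]).astype(str)
    return X, y


def _transport_source(Xs, ys, Xt, yt, ot_config):
    """Fit group-sparse OT and return the barycentrically mapped source."""
    mu_s = empirical_measure(Xs)
    mu_t = empirical_measure(Xt)
    J = cost_matrix(mu_s, mu_t)
    # lambda/eta are calibrated on a unit-median cost scale, so the fold's
    # cost is normalized by its median (pure rescaling of the objective)
    med = float(np.median(J.values))
    if med > 0:
        J = CostMatrix(values=J.values / med, metric=J.metric)
    tgt = yt if ot_config.label_mode == "semisupervised_target" else None
    plan = group_lasso_transport(J, mu_s.mass, mu_t.mass, ys, tgt, ot_config)
    return barycentric_map(plan, mu_t).points, plan


def loso_evaluate(features: list[FeatureMatrix], use_ot: bool,
                  ot_config: OTConfig = OTConfig(),
                  spec: ClassifierSpec = ClassifierSpec(),
                  standardize: bool = False,
                  pool: str = "concat") -> MetricsReport:
    """Leave-one-subject-out evaluation over a cohort.

    With ``use_ot``, each fold couples the pooled source to the held-out
    target (source labels always; target labels only in semisupervised
    mode), maps the source barycentrically, and trains on the transported
    source. Without, it trains on the raw pooled source. The held-out
    subject's trials never enter classifier training in either arm.

    ``standardize`` z-scores features with source statistics before the
    cost computation and classification (off by default).  ``pool``
    selects how the source is transported: 'concat' fits one coupling on
    the pooled source (default), 'per_subject' transports each training
    subject separately and pools the mapped features.
    """
    if len(features) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    if pool not in ("concat", "per_subject"):
        raise ValueError(f"unknown pooling mode {pool!r}")
    pipeline = "with_ot" if use_ot else "without_ot"
    report = MetricsReport(pipeline=pipeline, classifier=spec.kind,
                           label_mode=ot_config.label_mode if use_ot else "n/a")
    for k, held_out in enumerate(features):
        source = [f for i, f in enumerate(features) if i != k]
        Xs, ys = _pool(source)
        Xt = held_out.X
        yt = np.asarray(held_out.y).astype(str)
        if len(np.unique(ys)) < 2:
            raise ValueError(f"fold {held_out.subject_id}: single-class source")
        if standardize:
            mu, sd = Xs.mean(axis=0), Xs.std(axis=0)
            sd[sd == 0] = 1.0
            Xs = (Xs - mu) / sd
            Xt = (Xt - mu) / sd
        if use_ot:
            if pool == "concat":
                Xs, plan = _transport_source(Xs, ys, Xt, yt, ot_config)
            else:
                mapped = []
                for f in source:
                    Xi = f.X
                    if standardize:
                        Xi = (Xi - mu) / sd
                    Xm, plan = _transport_source(Xi, np.asarray(f.y, str),
                                                 Xt, yt, ot_config)
                    mapped.append(Xm)
                Xs = np.vstack(mapped)
            logger.info("fold %s: OT marginal error %.2e, %d outer objectives",
                        held_out.subject_id, plan.marginal_error,
                        len(plan.objective_trace))
        model = train_classifier((Xs, ys), spec)
        y_pred = model.predict(Xt)
        report.add(held_out.subject_id, yt, y_pred)
    return report


def run_ablation(features: list[FeatureMatrix],
                 classifiers: list[ClassifierSpec] | None = None,
                 label_modes: tuple[str, ...] = ("semisupervised_target",
                                                 "unsupervised_target"),
                 ot_config: OTConfig = OTConfig(),
                 standardize: bool = False) -> dict:
    """With/without-OT ablation plus optional classifier sweep.

    Returns {'reports': [MetricsReport...], 'comparisons': [...]}, where
    each comparison carries the exact two-tailed Wilcoxon signed-rank
    p-value over the paired per-subject F1 scores.
    """
    if classifiers is None:
        classifiers = [ClassifierSpec("random_forest")]
    if len(features) < 6:
        raise ValueError("need >= 6 subjects for a meaningful paired test")

    reports: list[MetricsReport] = []
    baseline = loso_evaluate(features, use_ot=False, ot_config=ot_config,
                             spec=classifiers[0], standardize=standardize)
    reports.append(baseline)
    comparisons = []
    for mode in label_modes:
        cfg = OTConfig(lambda_entropy=ot_config.lambda_entropy,
                       eta_group=ot_config.eta_group, label_mode=mode,
                       max_outer=ot_config.max_outer,
                       max_sinkhorn=ot_config.max_sinkhorn,
                       marginal_tol=ot_config.marginal_tol)
        for spec in classifiers:
            rep = loso_evaluate(features, use_ot=True, ot_config=cfg,
                                spec=spec, standardize=standardize)
            reports.append(rep)
            if rep.subjects != baseline.subjects:
                raise ValueError("mismatched subject sets across arms")
            p = wilcoxon_signed_rank(np.array(rep.f1), np.array(baseline.f1))
            comparisons.append({
                "arm_a": f"with_ot/{spec.kind}/{mode}",
                "arm_b": f"without_ot/{classifiers[0].kind}",
                "mean_f1_a": rep.mean_f1,
                "mean_f1_b": baseline.mean_f1,
                "wilcoxon_p": p,
            })
    return {"reports": reports, "comparisons": comparisons}
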
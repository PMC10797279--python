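"""Model evaluation: ROC/PR AUC, fold-wise t-tests, k-fold cross-validation
with patient-disjoint folds, and decision curve analysis.

ROC-AUC is the rank statistic (Mann-Whitney form, ties averaged); PR-AUC is
average precision, i.e. step-function integration of the precision-recall
curve.  Decision curve analysis reports, for each decision threshold t, the
net benefit  NB(t) = TP/n − (FP/n)·t/(1−t)  of treating patients whose
predicted risk is ≥ t, against the treat-all and treat-none references.

Baselines mirror common practice on tabular EHR data: logistic regression,
random forest and gradient-boosted trees on mean-imputed structured features
concatenated with a TF-IDF vectorization of the text-like fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score
from sklearn.model_selection import StratifiedGroupKFold

from .preprocessing import FeatureSchema
from .synthetic_ehr import DischargeRecord

__all__ = [
    "FoldMetrics",
    "NetBenefitCurve",
    "auc_roc",
    "auc_pr",
    "compare_folds",
    "net_benefit",
    "decision_curve",
    "kfold_evaluate",
    "baseline_features",
    "BASELINE_MODELS",
]

logger = logging.getLogger(__name__)


# -- scalar metrics -----------------------------------------------------
def _check_two_class(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute an AUC")
    return labels


def auc_roc(labels, scores) -> float:
    """ROC-AUC via the rank statistic; tied scores receive averaged ranks."""
    labels = _check_two_class(labels)
    scores = np.asarray(scores, dtype=float)
    r = stats.rankdata(scores)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    return float((r[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def auc_pr(labels, scores) -> float:
    """PR-AUC as average precision (step integration of the PR curve)."""
    labels = _check_two_class(labels)
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def compare_folds(metrics_a, metrics_b, paired: bool = False) -> float:
    """Two-sided t-test p-value on two fold-metric vectors.

    Unpaired mode uses the Welch correction.  When both vectors have zero
    variance the statistic is undefined; equal constants are reported as
    p = 1.0 and distinct constants as p = 0.0.
    """
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("fold metric vectors must have equal length >= 2")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        return 1.0 if np.allclose(a.mean(), b.mean()) else 0.0
    if paired:
        return float(stats.ttest_rel(a, b).pvalue)
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


# -- decision curve analysis --------------------------------------------
def net_benefit(labels, scores, threshold: float) -> float:
    """Net benefit of treating at predicted risk >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n = len(labels)
    pos = scores >= threshold
    tp = int((pos & (labels == 1)).sum())
    fp = int((pos & (labels == 0)).sum())
    return tp / n - (fp / n) * threshold / (1.0 - threshold)


@dataclass
class NetBenefitCurve:
    """Fold-averaged net benefit with treat-all / treat-none references."""

    thresholds: np.ndarray
    model_mean: np.ndarray
    model_sd: np.ndarray
    treat_all_mean: np.ndarray
    treat_all_sd: np.ndarray

    @property
    def treat_none(self) -> np.ndarray:
        return np.zeros_like(self.thresholds)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "model_mean": self.model_mean,
                "model_sd": self.model_sd,
                "treat_all_mean": self.treat_all_mean,
                "treat_all_sd": self.treat_all_sd,
                "treat_none": self.treat_none,
            }
        )


def decision_curve(
    fold_labels: list[np.ndarray],
    fold_scores: list[np.ndarray],
    thresholds: np.ndarray | None = None,
) -> NetBenefitCurve:
    """Per-threshold net benefit, fold-wise mean and standard deviation.

    `fold_labels`/`fold_scores` hold one array per fold; pass single-element
    lists for an unfolded curve.  Threshold 1.0 is invalid (the harm weight
    t/(1−t) diverges) and rejected by `net_benefit`.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.01, 1.0, 0.01), 2)
    thresholds = np.asarray(thresholds, dtype=float)
    model = np.empty((len(fold_labels), len(thresholds)))
    tall = np.empty_like(model)
    for i, (y, s) in enumerate(zip(fold_labels, fold_scores)):
        y = np.asarray(y, dtype=int)
        prev = y.mean()
        for j, t in enumerate(thresholds):
            model[i, j] = net_benefit(y, s, t)
            tall[i, j] = prev - (1.0 - prev) * t / (1.0 - t)
    return NetBenefitCurve(
        thresholds=thresholds,
        model_mean=model.mean(axis=0),
        model_sd=model.std(axis=0),
        treat_all_mean=tall.mean(axis=0),
        treat_all_sd=tall.std(axis=0),
    )


# -- baselines ----------------------------------------------------------
def _structured_matrix(records: list[DischargeRecord]) -> np.ndarray:
    """Age + one-hot sex/marital + raw lab values (NaN for missing)."""
    sexes = sorted({r.sex for r in records})
    maritals = sorted({r.marital_status for r in records})
    rows = []
    for r in records:
        row = [r.age]
        row += [1.0 if r.sex == s else 0.0 for s in sexes]
        row += [1.0 if r.marital_status == m else 0.0 for m in maritals]
        row += [np.nan if v is None else v for _, v in r.labs]
        rows.append(row)
    return np.asarray(rows, dtype=float)


def _text_of(r: DischargeRecord) -> str:
    return " ".join(list(r.history_tokens) + sorted(r.diagnosis_codes) + sorted(r.medication_codes))


def baseline_features(
    train: list[DischargeRecord], test: list[DischargeRecord]
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-imputed structured features ‖ TF-IDF text features.

    Imputation means and the TF-IDF vocabulary are fitted on the training
    split only.
    """
    X = _structured_matrix(train + test)
    Xtr, Xte = X[: len(train)], X[len(train):]
    mu = np.nanmean(Xtr, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    Xtr = np.where(np.isnan(Xtr), mu, Xtr)
    Xte = np.where(np.isnan(Xte), mu, Xte)
    vec = TfidfVectorizer(token_pattern=r"\S+")
    Ttr = vec.fit_transform([_text_of(r) for r in train]).toarray()
    Tte = vec.transform([_text_of(r) for r in test]).toarray()
    return np.hstack([Xtr, Ttr]), np.hstack([Xte, Tte])


def _make_baseline(name: str, seed: int):
    if name == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)
    if name == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=100, max_depth=4, random_state=seed, verbosity=0, n_jobs=1
        )
    raise ValueError(f"unknown baseline {name!r}")


BASELINE_MODELS = ("logistic", "random_forest", "xgboost")


# -- cross-validation ---------------------------------------------------
@dataclass
class FoldMetrics:
    """Per-fold ROC/PR AUC for every evaluated model."""

    k: int
    roc_auc: dict[str, np.ndarray]
    pr_auc: dict[str, np.ndarray]
    fold_labels: list[np.ndarray] = field(default_factory=list)
    fold_scores: dict[str, list[np.ndarray]] = field(default_factory=dict)

    def mean_roc(self, model: str) -> float:
        return float(self.roc_auc[model].mean())

    def mean_pr(self, model: str) -> float:
        return float(self.pr_auc[model].mean())

    def summary(self) -> dict:
        return {
            m: {
                "roc_auc_mean": float(self.roc_auc[m].mean()),
                "roc_auc_sd": float(self.roc_auc[m].std()),
                "pr_auc_mean": float(self.pr_auc[m].mean()),
                "pr_auc_sd": float(self.pr_auc[m].std()),
            }
            for m in self.roc_auc
        }


def kfold_evaluate(
    records: list[DischargeRecord],
    labels: np.ndarray,
    patient_ids: list[str],
    k: int,
    seed: int,
    baselines: tuple[str, ...] = BASELINE_MODELS,
    contrastive_trainer=None,
    encode_schema: FeatureSchema | None = None,
) -> FoldMetrics:
    """Stratified, patient-disjoint k-fold evaluation.

    `contrastive_trainer`, when given, is a callable
    ``(train_records, train_labels, test_records) -> test_scores`` wrapping
    pre-trained-encoder fine-tuning; its scores appear under model name
    "contrastive".  Folds are stratified on the label and grouped by patient
    so no patient contributes to both sides of a split.
    """
    labels = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    groups = np.asarray(patient_ids)

    model_names = list(baselines) + (["contrastive"] if contrastive_trainer else [])
    roc = {m: [] for m in model_names}
    pr = {m: [] for m in model_names}
    fold_scores = {m: [] for m in model_names}
    fold_labels = []

    for fold, (tr, te) in enumerate(splitter.split(np.zeros(len(labels)), labels, groups)):
        y_tr, y_te = labels[tr], labels[te]
        if len(np.unique(y_te)) < 2 or len(np.unique(y_tr)) < 2:
            raise ValueError(
                f"fold {fold} lost a class (train {np.bincount(y_tr)}, test {np.bincount(y_te)}); "
                "use more data or fewer folds"
            )
        assert not set(groups[tr]) & set(groups[te]), "patient leaked across folds"
        rec_tr = [records[i] for i in tr]
        rec_te = [records[i] for i in te]
        Xtr, Xte = baseline_features(rec_tr, rec_te)
        fold_labels.append(y_te)
        for name in baselines:
            clf = _make_baseline(name, seed)
            clf.fit(Xtr, y_tr)
            s = clf.predict_proba(Xte)[:, 1]
            roc[name].append(auc_roc(y_te, s))
            pr[name].append(auc_pr(y_te, s))
            fold_scores[name].append(s)
        if contrastive_trainer:
            s = contrastive_trainer(rec_tr, y_tr, rec_te)
            roc["contrastive"].append(auc_roc(y_te, s))
            pr["contrastive"].append(auc_pr(y_te, s))
            fold_scores["contrastive"].append(s)
        logger.info("fold %d done: %s", fold, {m: round(roc[m][-1], 3) for m in model_names})

    return FoldMetrics(
        k=k,
        roc_auc={m: np.array(v) for m, v in roc.items()},
        pr_auc={m: np.array(v) for m, v in pr.items()},
        fold_labels=fold_labels,
        fold_scores=fold_scores,
    )
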
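"""Classifier evaluation and univariate statistics.

A selected feature subset is validated by random permutations: the
cohort is repeatedly split into stratified 2/3 train / 1/3 test
partitions (default 10 iterations); on each split a random forest and a
linear SVM are trained on the subset and their test misclassification
recorded. The forest's test-split class probability serves as the
combined score turning the subset into a single feature: it is fed to
ROC analysis for AUC, and sensitivity/specificity are read at the
operating point maximizing Youden's J on that split. Results are
reported as mean +/- SD over iterations.

The univariate comparator tests each feature against the binary outcome
with a two-sided Mann-Whitney U test, adjusts the P-values by
Benjamini-Hochberg across the feature set, and reports per-feature ROC
performance at the optimal cutoff.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import ShuffleSplit, StratifiedShuffleSplit
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateOutcomeError, ParameterError
from .io import FeatureTable
from .selection import RFConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROCResult:
    auc: float
    sensitivity: float  # percent, at the Youden-optimal cutoff
    specificity: float  # percent
    cutoff: float


@dataclass(frozen=True)
class EvaluationReport:
    """Per-iteration and mean +/- SD performance of a feature subset."""

    rf_err: np.ndarray  # percent
    svm_err: np.ndarray  # percent
    auc: np.ndarray
    se: np.ndarray  # percent
    sp: np.ndarray  # percent
    split: float
    seed: int

    @property
    def iterations(self) -> int:
        return len(self.auc)

    def summary(self) -> dict[str, tuple[float, float]]:
        return {
            name: (float(np.mean(v)), float(np.std(v, ddof=0)))
            for name, v in [
                ("RF_err", self.rf_err),
                ("SVM_err", self.svm_err),
                ("AUC", self.auc),
                ("Se", self.se),
                ("Sp", self.sp),
            ]
        }


@dataclass(frozen=True)
class UnivariateResult:
    feature_names: list[str]
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    auc: np.ndarray  # oriented (>= 0.5) per-feature AUC
    se: np.ndarray
    sp: np.ndarray
    cutoff: np.ndarray
    alpha: float

    @property
    def m_prime(self) -> int:
        """Count of features significant after BH adjustment."""
        return int(np.sum(self.p_adjusted < self.alpha))

    def significant_features(self) -> list[str]:
        return [
            n for n, p in zip(self.feature_names, self.p_adjusted) if p < self.alpha
        ]


def roc_analysis(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """AUC plus the Youden-optimal operating point.

    AUC is the trapezoidal area under the ROC curve, equal to the
    Mann-Whitney U statistic scaled by n1*n0 (ties count 0.5). Among
    tied Youden values the highest cutoff (most specific point) wins.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if np.unique(labels).size < 2:
        raise DegenerateOutcomeError("ROC analysis needs both classes")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thresholds = roc_curve(labels, scores)
    j = tpr - fpr
    k = int(np.argmax(j))
    return ROCResult(
        auc=auc,
        sensitivity=float(100.0 * tpr[k]),
        specificity=float(100.0 * (1.0 - fpr[k])),
        cutoff=float(thresholds[k]),
    )


def permutation_evaluate(
    table: FeatureTable,
    labels: np.ndarray,
    subset: list[str],
    cfg: RFConfig = RFConfig(),
    iterations: int = 10,
    train_fraction: float = 2.0 / 3.0,
    stratified: bool = True,
) -> EvaluationReport:
    """Random-permutation validation of a feature subset.

    Each iteration draws a random train/test split (stratified by
    default, preserving the cohort's class mix in both partitions),
    trains an RF and a standardized linear SVM on the subset columns,
    and records test misclassification, AUC of the RF class probability,
    and Se/Sp at that iteration's own Youden-optimal cutoff.
    """
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise DegenerateOutcomeError("both classes must be present")
    X = table.subset(subset).values  # raises SchemaError on unknown feature
    splitter_cls = StratifiedShuffleSplit if stratified else ShuffleSplit
    splitter = splitter_cls(
        n_splits=iterations, train_size=train_fraction, random_state=cfg.seed
    )
    rf_err, svm_err, aucs, ses, sps = [], [], [], [], []
    for it, (tr, te) in enumerate(splitter.split(X, labels)):
        rf = RandomForestClassifier(
            n_estimators=cfg.trees,
            max_features=cfg.max_features,
            max_depth=cfg.max_depth,
            class_weight=cfg.class_weight,
            random_state=cfg.seed + it,
            n_jobs=1,
        )
        rf.fit(X[tr], labels[tr])
        rf_err.append(100.0 * np.mean(rf.predict(X[te]) != labels[te]))
        scores = rf.predict_proba(X[te])[:, 1]
        if np.unique(labels[te]).size < 2:  # unstratified splits may do this
            aucs.append(np.nan), ses.append(np.nan), sps.append(np.nan)
        else:
            roc = roc_analysis(scores, labels[te])
            aucs.append(roc.auc), ses.append(roc.sensitivity), sps.append(roc.specificity)
        svm = make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
        svm.fit(X[tr], labels[tr])
        svm_err.append(100.0 * np.mean(svm.predict(X[te]) != labels[te]))
    return EvaluationReport(
        rf_err=np.array(rf_err),
        svm_err=np.array(svm_err),
        auc=np.array(aucs),
        se=np.array(ses),
        sp=np.array(sps),
        split=train_fraction,
        seed=cfg.seed,
    )


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values (monotone, capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1) | np.isnan(pvals)):
        raise ParameterError("P-values must lie in [0, 1]")
    if pvals.size == 0:
        return pvals.copy()
    return multipletests(pvals, method="fdr_bh")[1]


def univariate_mann_whitney(
    table: FeatureTable, labels: np.ndarray, alpha: float = 0.05
) -> UnivariateResult:
    """Per-feature Mann-Whitney U tests with BH adjustment and ROC.

    Constant features get P = 1 with a warning rather than an error.
    Reported AUCs are oriented (max of AUC and 1-AUC) so a protective
    and a risk feature of equal strength score alike.
    """
    labels = np.asarray(labels).astype(int)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise DegenerateOutcomeError("need both classes with >= 2 patients")
    g1 = labels == classes.max()
    p_raw, aucs, ses, sps, cuts = [], [], [], [], []
    for name in table.feature_names:
        x = table.column(name)
        if np.all(x == x[0]):
            logger.warning("constant feature %r: P set to 1", name)
            p_raw.append(1.0)
            aucs.append(0.5), ses.append(np.nan), sps.append(np.nan), cuts.append(np.nan)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.mannwhitneyu(x[g1], x[~g1], alternative="two-sided",
                                     method="auto")
        p_raw.append(float(res.pvalue))
        roc = roc_analysis(x, labels)
        auc = roc.auc
        if auc < 0.5:
            roc = roc_analysis(-x, labels)
            auc = roc.auc
        aucs.append(auc), ses.append(roc.sensitivity), sps.append(roc.specificity)
        cuts.append(roc.cutoff)
    return UnivariateResult(
        feature_names=list(table.feature_names),
        p_raw=np.array(p_raw),
        p_adjusted=bh_adjust(np.array(p_raw)),
        auc=np.array(aucs),
        se=np.array(ses),
        sp=np.array(sps),
        cutoff=np.array(cuts),
        alpha=alpha,
    )


def wilcoxon_compare(errors_a: np.ndarray, errors_b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank P on paired per-iteration errors."""
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("paired error vectors must have equal length")
    if np.all(a == b):
        logger.warning("all paired differences are zero; P = 1")
        return 1.0
    res = stats.wilcoxon(a, b, alternative="two-sided")
    return float(res.pvalue)
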
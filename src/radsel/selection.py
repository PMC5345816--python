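"""Random-forest feature selection: importance ranking, the 10%-of-max
threshold rule, and an out-of-bag-error subset search.

The ranking stage fits one forest (default 500 trees) on the uncorrelated
features and orders them by importance coefficient (CI); mean decrease in
impurity by default, permutation importance by configuration. Features
with CI strictly above ``fraction`` times the best CI survive. The search
stage then evaluates candidate subsets by the OOB misclassification of a
forest restricted to each subset: exhaustively over all non-empty subsets
when the candidate count permits, by greedy backward elimination beyond
that. The reported winner minimizes OOB error, with ties broken toward
smaller subsets, then higher summed CI, then lexicographic order.

A greedy forward comparator (``hfs_select``) selects features by
cross-validated linear-SVM accuracy; it approximates the hierarchical
forward selection family of SVM wrappers and is tagged ``hfs_svm``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import DegenerateOutcomeError, ParameterError
from .io import FeatureTable


@dataclass(frozen=True)
class RFConfig:
    """Forest configuration for ranking and subset search.

    ``trees`` is the forest size for importance ranking and final
    evaluation; ``trees_search`` is the (smaller) forest size used for
    each OOB evaluation during the subset search, where hundreds of
    forests may be fitted — at 75 trees each sample is out-of-bag in
    roughly 27 trees, which stabilizes the error estimate at this cohort
    size while keeping exhaustive enumeration tractable. ``exhaustive_limit`` bounds the
    candidate count for exhaustive enumeration; above it the search
    switches to greedy backward elimination.
    """

    trees: int = 500
    trees_search: int = 75
    seed: int = 0
    max_features: str | int | float = "sqrt"
    max_depth: int | None = None
    class_weight: str | None = None
    importance: str = "gini"  # or "permutation"
    exhaustive_limit: int = 9

    def __post_init__(self) -> None:
        if self.trees < 1 or self.trees_search < 1:
            raise ParameterError("forest sizes must be >= 1")
        if self.importance not in ("gini", "permutation"):
            raise ParameterError("importance must be 'gini' or 'permutation'")


@dataclass(frozen=True)
class ImportanceRanking:
    """Features ordered by descending importance coefficient."""

    entries: list[tuple[str, float]]

    @property
    def features(self) -> list[str]:
        return [name for name, _ in self.entries]

    @property
    def coefficients(self) -> dict[str, float]:
        return dict(self.entries)


@dataclass(frozen=True)
class SubsetSearchResult:
    subset: list[str]
    oob_error: float  # OOB misclassification for rf_oob; CV error for hfs_svm
    method: str
    search_log: list[tuple[tuple[str, ...], float]] = field(repr=False, default_factory=list)


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise DegenerateOutcomeError("labels contain a single class")
    if counts.min() < 2:
        raise DegenerateOutcomeError("each class needs at least 2 patients")
    return labels


def _forest(cfg: RFConfig, n_trees: int, seed: int, oob: bool) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_features=cfg.max_features,
        max_depth=cfg.max_depth,
        class_weight=cfg.class_weight,
        oob_score=oob,
        random_state=seed,
        n_jobs=1,
    )


def rank_importance(
    table: FeatureTable, labels: np.ndarray, cfg: RFConfig = RFConfig()
) -> ImportanceRanking:
    """Rank features by the forest's importance coefficient (CI).

    Deterministic for a fixed seed. Ties are broken by input column
    order (stable sort).
    """
    labels = _check_labels(labels)
    rf = _forest(cfg, cfg.trees, cfg.seed, oob=False)
    rf.fit(table.values, labels)
    if cfg.importance == "gini":
        ci = rf.feature_importances_
    else:
        result = permutation_importance(
            rf, table.values, labels, n_repeats=10, random_state=cfg.seed
        )
        ci = np.maximum(result.importances_mean, 0.0)
    order = np.argsort(-ci, kind="stable")
    entries = [(table.feature_names[k], float(ci[k])) for k in order]
    return ImportanceRanking(entries=entries)


def threshold_select(
    ranking: ImportanceRanking, fraction: float = 0.1
) -> list[str]:
    """Retain features whose CI is strictly higher than fraction * max CI."""
    if not ranking.entries:
        raise ParameterError("empty importance ranking")
    top = ranking.entries[0][1]
    return [name for name, ci in ranking.entries if ci > fraction * top]


def _oob_error(
    table: FeatureTable, labels: np.ndarray, subset: tuple[str, ...], cfg: RFConfig
) -> float:
    X = table.subset(list(subset)).values
    rf = _forest(cfg, cfg.trees_search, cfg.seed, oob=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny forests may leave a sample in-bag
        rf.fit(X, labels)
    return float(1.0 - rf.oob_score_)


def _pick_best(
    log: list[tuple[tuple[str, ...], float]], ci: dict[str, float]
) -> tuple[tuple[str, ...], float]:
    def key(entry):
        subset, err = entry
        return (err, len(subset), -sum(ci.get(f, 0.0) for f in subset), subset)

    return min(log, key=key)


def subset_search(
    table: FeatureTable,
    labels: np.ndarray,
    candidates: list[str],
    cfg: RFConfig = RFConfig(),
    ci: dict[str, float] | None = None,
) -> SubsetSearchResult:
    """Find the candidate subset minimizing forest OOB misclassification.

    All non-empty subsets are enumerated when the candidate count is at
    most ``cfg.exhaustive_limit``. Beyond that, a recursive backward
    elimination is used: starting from the full candidate set, the
    lowest-CI feature is removed at each step (when ``ci`` is supplied;
    otherwise the removal minimizing OOB error is chosen greedily) and
    every subset along the chain is OOB-evaluated; the best subset seen
    anywhere wins. The complete search log (subset, OOB error) is part
    of the result.
    """
    if not candidates:
        raise ParameterError("candidate set is empty")
    labels = _check_labels(labels)
    ci = ci or {}
    log: list[tuple[tuple[str, ...], float]] = []

    if len(candidates) <= cfg.exhaustive_limit:
        for r in range(1, len(candidates) + 1):
            for subset in combinations(candidates, r):
                log.append((subset, _oob_error(table, labels, subset, cfg)))
    elif ci:
        # nested chain by ascending importance: k evaluations total
        ordered = sorted(candidates, key=lambda f: (-ci.get(f, 0.0), f))
        for r in range(len(ordered), 0, -1):
            subset = tuple(f for f in candidates if f in set(ordered[:r]))
            log.append((subset, _oob_error(table, labels, subset, cfg)))
    else:
        current = tuple(candidates)
        log.append((current, _oob_error(table, labels, current, cfg)))
        while len(current) > 1:
            step = [
                (sub, _oob_error(table, labels, sub, cfg))
                for sub in (
                    tuple(f for f in current if f != drop) for drop in current
                )
            ]
            log.extend(step)
            current = _pick_best(step, ci)[0]

    best, err = _pick_best(log, ci)
    return SubsetSearchResult(
        subset=list(best), oob_error=err, method="rf_oob", search_log=log
    )


def hfs_select(
    table: FeatureTable,
    labels: np.ndarray,
    candidates: list[str],
    cfg: RFConfig = RFConfig(),
    cv_folds: int = 5,
) -> SubsetSearchResult:
    """Greedy forward selection by cross-validated linear-SVM accuracy.

    Starts empty and repeatedly adds the feature whose addition maximizes
    stratified k-fold CV accuracy of a standardized linear-kernel SVM,
    stopping when no addition strictly improves it.
    """
    if not candidates:
        raise ParameterError("candidate set is empty")
    labels = _check_labels(labels)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=cfg.seed)

    def cv_accuracy(subset: tuple[str, ...]) -> float:
        model = make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
        X = table.subset(list(subset)).values
        return float(np.mean(cross_val_score(model, X, labels, cv=cv)))

    selected: tuple[str, ...] = ()
    best_acc = -np.inf
    log: list[tuple[tuple[str, ...], float]] = []
    while True:
        remaining = [f for f in candidates if f not in selected]
        if not remaining:
            break
        trials = []
        for f in remaining:
            subset = selected + (f,)
            acc = cv_accuracy(subset)
            log.append((subset, 1.0 - acc))
            trials.append((subset, acc))
        # best addition: highest accuracy, alphabetical tie-break
        top = max(acc for _, acc in trials)
        subset, acc = min(
            (t for t in trials if t[1] == top), key=lambda t: t[0][-1]
        )
        if acc > best_acc:
            selected, best_acc = subset, acc
        else:
            break
    return SubsetSearchResult(
        subset=list(selected),
        oob_error=float(1.0 - best_acc),
        method="hfs_svm",
        search_log=log,
    )
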
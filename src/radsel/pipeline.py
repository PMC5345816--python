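"""End-to-end predictive and prognostic runs with a reproducible manifest.

Both runs share the same spine: median imputation of undefined feature
values, removal of constant features, Spearman redundancy grouping with
one representative per group, random-forest importance ranking, the
10%-of-max threshold, the OOB subset search, and random-permutation
evaluation of the winning subset. The predictive run classifies the
binary treatment-response label and adds a univariate Mann-Whitney
comparator; the prognostic run classifies death-within-horizon (default
36 months; patients censored before the horizon are excluded from
classifier training with a logged count), adds a per-feature univariate
Kaplan-Meier comparator with optimal-cutoff dichotomization, Altman and
BH correction, and a KM/log-rank contrast of the cohort split by the
classifier's own out-of-bag predicted labels.

Every stochastic stage derives its seed from the run configuration, so
a manifest suffices to reproduce all artifacts bit-identically. Reruns
into a new output directory never mutate previous artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from . import __version__
from .errors import DegenerateOutcomeError, DegenerateRegionError, SchemaError
from .evaluation import (
    EvaluationReport,
    UnivariateResult,
    bh_adjust,
    permutation_evaluate,
    univariate_mann_whitney,
)
from .io import FeatureTable
from .names import DEFAULT_ROBUSTNESS_PRIORITY
from .preselection import CorrelationGroups, drop_constant_features, preselect
from .selection import (
    ImportanceRanking,
    RFConfig,
    SubsetSearchResult,
    rank_importance,
    subset_search,
    threshold_select,
)
from .survival import (
    SurvivalData,
    SurvivalResult,
    feature_survival_analysis,
    km_logrank,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Defaults mirror the study protocol: |rho| threshold 0.8 at P < 0.05,
    500-tree forests, 10%-of-max importance threshold, 10 random
    permutations with stratified 2/3 train splits, 36-month prognostic
    horizon, 5%-95% minimal-P selection interval."""

    theta: float = 0.8
    alpha: float = 0.05
    rf: RFConfig = field(default_factory=RFConfig)
    threshold_fraction: float = 0.1
    iterations: int = 10
    train_fraction: float = 2.0 / 3.0
    stratified: bool = True
    priority: tuple[str, ...] | None = None
    prognostic_horizon_months: float = 36.0
    altman_eps: float = 0.05
    min_group_fraction: float = 0.10


@dataclass
class RunManifest:
    """Machine-readable record of one pipeline run."""

    mode: str
    config: dict
    seed: int
    dropped_constant: list[str]
    groups: CorrelationGroups
    ranking: ImportanceRanking
    retained: list[str]
    subset: SubsetSearchResult
    report: EvaluationReport
    univariate: UnivariateResult | None = None
    univariate_km: list[tuple[str, SurvivalResult]] | None = None
    classifier_km: SurvivalResult | None = None
    excluded_censored: int = 0
    started: float = 0.0
    finished: float = 0.0

    def to_dict(self) -> dict:
        out = {
            "mode": self.mode,
            "version": __version__,
            "config": self.config,
            "seed": self.seed,
            "dropped_constant": self.dropped_constant,
            "groups": self.groups.groups,
            "representatives": self.groups.representatives,
            "f_u": self.groups.f_u,
            "ranking": self.ranking.entries,
            "retained": self.retained,
            "subset": self.subset.subset,
            "subset_error": self.subset.oob_error,
            "search_log_size": len(self.subset.search_log),
            "evaluation": self.report.summary(),
            "excluded_censored": self.excluded_censored,
            "started": self.started,
            "finished": self.finished,
        }
        if self.univariate is not None:
            out["univariate"] = {
                "features": self.univariate.feature_names,
                "p_raw": self.univariate.p_raw.tolist(),
                "p_adjusted": self.univariate.p_adjusted.tolist(),
                "auc": self.univariate.auc.tolist(),
                "m_prime": self.univariate.m_prime,
            }
        if self.univariate_km is not None:
            out["univariate_km"] = [
                {
                    "feature": name,
                    "cutoff": r.cutoff,
                    "p_raw": r.p_logrank_raw,
                    "p_altman": r.p_altman,
                    "p_bh": r.p_bh,
                    "hazard_ratio": r.hazard_ratio,
                }
                for name, r in self.univariate_km
            ]
        if self.classifier_km is not None:
            r = self.classifier_km
            out["classifier_km"] = {
                "p_raw": r.p_logrank_raw,
                "hazard_ratio": r.hazard_ratio,
                "median_survival": list(r.median_survival),
            }
        return out

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=_json_default)
        return path


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def impute_median(table: FeatureTable) -> FeatureTable:
    """Replace NaN cells by the per-column cohort median."""
    values = table.values.copy()
    for j in range(values.shape[1]):
        col = values[:, j]
        bad = np.isnan(col)
        if bad.any():
            col[bad] = np.nanmedian(col)
    return dataclasses.replace(table, values=values)


def _priority_for(table: FeatureTable, config: PipelineConfig) -> list[str]:
    if config.priority is not None:
        return list(config.priority)
    if set(table.feature_names) <= set(DEFAULT_ROBUSTNESS_PRIORITY):
        return DEFAULT_ROBUSTNESS_PRIORITY
    return list(table.feature_names)  # table order for non-canonical names


def _select_and_evaluate(
    table: FeatureTable,
    labels: np.ndarray,
    eval_table: FeatureTable,
    eval_labels: np.ndarray,
    config: PipelineConfig,
):
    """Shared spine from preselection through permutation evaluation.

    ``table``/``labels`` drive the selection stages (possibly excluding
    patients without a determinate label); ``eval_table``/``eval_labels``
    are used for the final permutation evaluation.
    """
    table = impute_median(table)
    table, dropped = drop_constant_features(table)
    groups = preselect(
        table, theta=config.theta, alpha=config.alpha,
        priority=_priority_for(table, config),
    )
    reduced = table.subset(groups.retained_features())
    ranking = rank_importance(reduced, labels, config.rf)
    retained = threshold_select(ranking, config.threshold_fraction)
    subset = subset_search(
        reduced, labels, retained, config.rf, ci=ranking.coefficients
    )
    report = permutation_evaluate(
        impute_median(eval_table),
        eval_labels,
        subset.subset,
        config.rf,
        iterations=config.iterations,
        train_fraction=config.train_fraction,
        stratified=config.stratified,
    )
    return table, dropped, groups, reduced, ranking, retained, subset, report


def run_predictive(
    table: FeatureTable,
    config: PipelineConfig = PipelineConfig(),
    outdir: str | Path | None = None,
) -> RunManifest:
    """Response-prediction arm: selection, evaluation, univariate comparator."""
    if table.response is None:
        raise SchemaError("predictive run requires response labels")
    started = _time.time()
    labels = table.response.astype(int)
    (imp_table, dropped, groups, reduced, ranking, retained,
     subset, report) = _select_and_evaluate(table, labels, table, labels, config)
    univariate = univariate_mann_whitney(
        imp_table.subset(groups.retained_features()), labels, alpha=config.alpha
    )
    manifest = RunManifest(
        mode="predictive",
        config=dataclasses.asdict(config),
        seed=config.rf.seed,
        dropped_constant=dropped,
        groups=groups,
        ranking=ranking,
        retained=retained,
        subset=subset,
        report=report,
        univariate=univariate,
        started=started,
        finished=_time.time(),
    )
    if outdir is not None:
        manifest.write(outdir)
    return manifest


def run_prognostic(
    table: FeatureTable,
    config: PipelineConfig = PipelineConfig(),
    outdir: str | Path | None = None,
) -> RunManifest:
    """Survival arm: classification of death-within-horizon plus KM analyses."""
    if table.time is None or table.event is None:
        raise SchemaError("prognostic run requires time and event columns")
    started = _time.time()
    horizon = config.prognostic_horizon_months
    dead_by_h = (table.event == 1) & (table.time <= horizon)
    determinate = (table.event == 1) | (table.time >= horizon)
    excluded = int(np.sum(~determinate))
    if excluded:
        logger.info(
            "excluding %d patient(s) censored before %.0f months from "
            "classifier training", excluded, horizon,
        )
    ids = [pid for pid, keep in zip(table.patient_ids, determinate) if keep]
    train_table = dataclasses.replace(
        table,
        patient_ids=ids,
        values=table.values[determinate],
        response=None,
        time=table.time[determinate],
        event=table.event[determinate],
    )
    labels = dead_by_h[determinate].astype(int)
    if np.unique(labels).size < 2:
        raise DegenerateOutcomeError("horizon label has a single class")

    (imp_train, dropped, groups, reduced, ranking, retained,
     subset, report) = _select_and_evaluate(
        train_table, labels, train_table, labels, config)

    # univariate KM comparator on the full cohort, per retained feature
    surv_all = SurvivalData(table.time, table.event)
    imp_full = impute_median(table)
    univariate_km: list[tuple[str, SurvivalResult]] = []
    raw_ps = []
    for name in groups.retained_features():
        try:
            res = feature_survival_analysis(
                imp_full.column(name), surv_all,
                min_group_fraction=config.min_group_fraction,
                eps=config.altman_eps,
            )
        except (DegenerateOutcomeError, DegenerateRegionError) as exc:
            logger.warning("univariate KM skipped for %s: %s", name, exc)
            continue
        univariate_km.append((name, res))
        raw_ps.append(res.p_altman)
    p_bh = bh_adjust(np.array(raw_ps)) if raw_ps else np.array([])
    univariate_km = [
        (name, dataclasses.replace(res, p_bh=float(adj)))
        for (name, res), adj in zip(univariate_km, p_bh)
    ]

    # KM contrast of classifier-estimated groups (out-of-bag labels)
    rf = RandomForestClassifier(
        n_estimators=config.rf.trees,
        max_features=config.rf.max_features,
        oob_score=True,
        random_state=config.rf.seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rf.fit(imp_train.subset(subset.subset).values, labels)
    oob_prob = rf.oob_decision_function_[:, 1]
    oob_labels = np.where(np.isnan(oob_prob), 0.5, oob_prob) > 0.5
    classifier_km = None
    if oob_labels.any() and not oob_labels.all():
        classifier_km = km_logrank(
            SurvivalData(
                train_table.time, train_table.event, group=oob_labels.astype(int)
            )
        )

    manifest = RunManifest(
        mode="prognostic",
        config=dataclasses.asdict(config),
        seed=config.rf.seed,
        dropped_constant=dropped,
        groups=groups,
        ranking=ranking,
        retained=retained,
        subset=subset,
        report=report,
        univariate_km=univariate_km,
        classifier_km=classifier_km,
        excluded_censored=excluded,
        started=started,
        finished=_time.time(),
    )
    if outdir is not None:
        manifest.write(outdir)
    return manifest
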
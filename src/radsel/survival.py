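"""Prognostic analysis: optimal-cutoff dichotomization, Kaplan-Meier /
log-rank testing, O/E hazard ratio, and the minimal-P (Altman) correction.

A continuous feature is dichotomized at the cutoff that best separates
patients by vital status: candidate cutoffs are midpoints between sorted
unique values (restricted so each side keeps a minimum fraction of the
cohort) and the winner maximizes |Youden's J| of the high-group
indicator against the event indicator, matching cutoff selection by ROC.
Because scanning cutoffs inflates the log-rank P of the chosen split,
the corrected P is computed from the Miller-Siegmund approximation for
the minimal P over an inner selection interval — the inflation
adjustment Altman introduced for "optimal" cutpoints::

    p_cor = phi(z) * [ (z - 1/z) * ln((1-eps)^2 / eps^2) + 4/z ],
    z = Phi^-1(1 - p_min / 2)

with ``eps`` the selection fraction at each tail (default 0.05, i.e. the
5%-95% interval). The approximation is valid for small p_min; above the
validity bound (0.1) the corrected value saturates at 1.

The hazard ratio is the log-rank O/E estimator (O1/E1)/(O0/E0) — no
proportional-hazards regression is fitted — reported for the high group
(values above the cutoff) versus the low group.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateOutcomeError, DegenerateRegionError, ParameterError

logger = logging.getLogger(__name__)

ALTMAN_VALIDITY_BOUND = 0.1


@dataclass(frozen=True)
class SurvivalData:
    """Right-censored survival: months to death (event=1) or censoring."""

    time: np.ndarray
    event: np.ndarray
    group: np.ndarray | None = None

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event).astype(int)
        if time.shape != event.shape or time.ndim != 1:
            raise ParameterError("time and event must be matching 1D vectors")
        if np.any(time < 0):
            raise ParameterError("survival times must be non-negative")
        if not np.all(np.isin(event, (0, 1))):
            raise ParameterError("event flags must be 0 or 1")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)
        if self.group is not None:
            group = np.asarray(self.group).astype(int)
            if group.shape != time.shape:
                raise ParameterError("group must match time in length")
            object.__setattr__(self, "group", group)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate as a step function."""

    times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray

    def median(self) -> float:
        below = self.survival <= 0.5
        return float(self.times[below][0]) if below.any() else math.nan


@dataclass(frozen=True)
class SurvivalResult:
    cutoff: float
    p_logrank_raw: float
    p_altman: float
    hazard_ratio: float  # high vs low; NaN when a group has no events
    median_survival: tuple[float, float]  # (low group, high group), months
    km_curves: tuple[KMCurve, KMCurve]
    chi_square: float
    observed: tuple[float, float]
    expected: tuple[float, float]
    p_bh: float = math.nan  # BH-adjusted across a feature set, set by callers


def km_curve(time: np.ndarray, event: np.ndarray) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    With no censoring this equals the empirical survival function.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    event_times = np.unique(time[event == 1])
    surv = 1.0
    times, at_risk, survival = [], [], []
    for t in event_times:
        n_t = int(np.sum(time >= t))
        d_t = int(np.sum((time == t) & (event == 1)))
        surv *= 1.0 - d_t / n_t
        times.append(t), at_risk.append(n_t), survival.append(surv)
    return KMCurve(np.array(times), np.array(at_risk), np.array(survival))


def logrank_oe(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> tuple[float, float, float, float, float]:
    """Log-rank observed/expected table for two groups.

    Returns (O0, O1, E1, V, chi_square); E0 = O0 + O1 - E1.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    group = np.asarray(group).astype(int)
    event_times = np.unique(time[event == 1])
    e1 = v = 0.0
    for t in event_times:
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & (group == 1)).sum())
        d = int(((time == t) & (event == 1)).sum())
        e1 += d * n1 / n
        if n > 1:
            v += d * (n - d) / (n - 1) * n1 * (n - n1) / n**2
    o1 = float(((group == 1) & (event == 1)).sum())
    o0 = float(((group == 0) & (event == 1)).sum())
    chi2 = (o1 - e1) ** 2 / v if v > 0 else 0.0
    return o0, o1, e1, v, chi2


def km_logrank(surv: SurvivalData, cutoff: float = math.nan) -> SurvivalResult:
    """KM curves, two-sided log-rank P, O/E hazard ratio and medians.

    ``surv.group`` must be a binary stratum (1 = high). The hazard
    ratio (O1/E1)/(O0/E0) is NaN — flagged undefined — when either
    group has zero events; the log-rank P is still computed.
    """
    if surv.group is None:
        raise ParameterError("km_logrank needs a group stratum")
    g = surv.group
    if not ((g == 0).any() and (g == 1).any()):
        raise DegenerateOutcomeError("both groups must be non-empty")
    o0, o1, e1, v, chi2 = logrank_oe(surv.time, surv.event, g)
    p_raw = float(stats.chi2.sf(chi2, df=1)) if v > 0 else 1.0
    e0 = o0 + o1 - e1
    if o0 > 0 and o1 > 0 and e0 > 0 and e1 > 0:
        hr = (o1 / e1) / (o0 / e0)
    else:
        hr = math.nan
    curves = (
        km_curve(surv.time[g == 0], surv.event[g == 0]),
        km_curve(surv.time[g == 1], surv.event[g == 1]),
    )
    return SurvivalResult(
        cutoff=cutoff,
        p_logrank_raw=p_raw,
        p_altman=altman_correct(p_raw) if p_raw < ALTMAN_VALIDITY_BOUND else 1.0,
        hazard_ratio=float(hr),
        median_survival=(curves[0].median(), curves[1].median()),
        km_curves=curves,
        chi_square=float(chi2),
        observed=(o0, o1),
        expected=(float(e0), float(e1)),
    )


def optimal_cutoff(
    values: np.ndarray, surv: SurvivalData, min_group_fraction: float = 0.10
) -> float:
    """Most discriminating cutoff for the event indicator (ROC / Youden).

    Candidates are midpoints between sorted unique values, restricted so
    each side keeps at least ``min_group_fraction`` of the patients (the
    inner selection interval the minimal-P correction assumes). The
    winner maximizes |Youden's J| of (value > cutoff) against the event
    flag; ties go to the lower cutoff.
    """
    values = np.asarray(values, dtype=float)
    uniq = np.unique(values)
    if uniq.size < 2:
        raise DegenerateRegionError("constant feature admits no cutoff")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    n = values.size
    lo = max(1, math.ceil(min_group_fraction * n))
    keep = np.array([lo <= np.sum(values > c) <= n - lo for c in mids])
    if not keep.any():
        raise DegenerateRegionError("no cutoff satisfies the group-size floor")
    mids = mids[keep]
    pos = surv.event == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateOutcomeError("event indicator has a single class")
    best_c, best_j = math.nan, -1.0
    for c in mids:
        high = values > c
        j = abs(
            np.sum(high & pos) / n_pos - np.sum(high & ~pos) / n_neg
        )
        if j > best_j + 1e-12:  # strict improvement; ties keep lower cutoff
            best_c, best_j = float(c), float(j)
    return best_c


def altman_correct(p_min: float, eps: float = 0.05) -> float:
    """Correct a minimal P-value from optimal-cutpoint selection.

    Valid for 0 < p_min < 0.1; at or above the bound the corrected value
    is 1 (with a warning). The corrected value never falls below p_min.
    """
    if not 0.0 < p_min:
        raise ParameterError("p_min must be positive")
    if not 0.0 < eps < 0.5:
        raise ParameterError("selection fraction must be in (0, 0.5)")
    if p_min >= ALTMAN_VALIDITY_BOUND:
        logger.warning(
            "p_min=%.4g is outside the correction's validity range; returning 1",
            p_min,
        )
        return 1.0
    z = stats.norm.isf(p_min / 2.0)
    phi = stats.norm.pdf(z)
    corrected = phi * ((z - 1.0 / z) * math.log((1.0 - eps) ** 2 / eps**2) + 4.0 / z)
    return float(min(max(corrected, p_min), 1.0))


def feature_survival_analysis(
    values: np.ndarray,
    surv: SurvivalData,
    min_group_fraction: float = 0.10,
    eps: float = 0.05,
) -> SurvivalResult:
    """Dichotomize at the optimal cutoff, then KM/log-rank with correction."""
    cutoff = optimal_cutoff(values, surv, min_group_fraction)
    group = (np.asarray(values, dtype=float) > cutoff).astype(int)
    result = km_logrank(
        SurvivalData(surv.time, surv.event, group=group), cutoff=cutoff
    )
    p_altman = (
        altman_correct(result.p_logrank_raw, eps=eps)
        if result.p_logrank_raw < ALTMAN_VALIDITY_BOUND
        else 1.0
    )
    return SurvivalResult(
        cutoff=cutoff,
        p_logrank_raw=result.p_logrank_raw,
        p_altman=p_altman,
        hazard_ratio=result.hazard_ratio,
        median_survival=result.median_survival,
        km_curves=result.km_curves,
        chi_square=result.chi_square,
        observed=result.observed,
        expected=result.expected,
    )
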
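"""Redundancy pre-selection by Spearman rank correlation.

Features whose pairwise |rho| reaches the threshold (default 0.8) with a
raw two-sided P below alpha (default 0.05) are linked; groups are the
connected components of this graph, so correlation is propagated
transitively (a chain A~B~C lands in one group even when A and C are not
directly correlated). Each group contributes a single representative —
its most robust member according to an ordered priority list — and every
unlinked feature survives as its own singleton, giving the F_u
uncorrelated features passed to the selection stage.

P-values are used raw here; multiple-testing correction belongs to the
univariate outcome tests, not to this redundancy screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .errors import ConfigurationError, DegenerateRegionError, ParameterError
from .io import FeatureTable
from .names import DEFAULT_ROBUSTNESS_PRIORITY

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationMatrix:
    feature_names: list[str]
    rho: np.ndarray
    pval: np.ndarray


@dataclass(frozen=True)
class CorrelationGroups:
    """A partition of the features with one representative per group."""

    groups: list[list[str]]
    representatives: list[str]

    @property
    def f_u(self) -> int:
        """Number of retained features (groups, singletons included)."""
        return len(self.groups)

    def retained_features(self) -> list[str]:
        return list(self.representatives)


def drop_constant_features(table: FeatureTable) -> tuple[FeatureTable, list[str]]:
    """Remove zero-variance features, logging a warning for each."""
    variances = np.nanvar(table.values, axis=0)
    constant = [n for n, v in zip(table.feature_names, variances) if v == 0]
    if constant:
        logger.warning("dropping constant feature(s): %s", ", ".join(constant))
        keep = [n for n in table.feature_names if n not in set(constant)]
        return table.subset(keep), constant
    return table, []


def spearman_matrix(table: FeatureTable) -> CorrelationMatrix:
    """Tie-corrected Spearman rho and two-sided P for every feature pair."""
    if table.n_patients < 3:
        raise ParameterError("Spearman analysis needs at least 3 patients")
    variances = np.var(table.values, axis=0)
    flat = [n for n, v in zip(table.feature_names, variances) if v == 0]
    if flat:
        raise DegenerateRegionError(
            f"constant feature(s) reached correlation analysis: {', '.join(flat)}"
        )
    rho, pval = stats.spearmanr(table.values)
    if np.ndim(rho) == 0:  # scipy collapses the two-feature case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        pval = np.array([[0.0, float(pval)], [float(pval), 0.0]])
    np.fill_diagonal(pval, 0.0)
    return CorrelationMatrix(list(table.feature_names), rho, pval)


def build_groups(
    c: CorrelationMatrix, theta: float = 0.8, alpha: float = 0.05
) -> list[list[str]]:
    """Partition features into connected components of the correlation graph.

    An edge joins two features iff |rho| >= theta and P < alpha.
    """
    if not 0 < theta <= 1:
        raise ParameterError("theta must be in (0, 1]")
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    adj = (np.abs(c.rho) >= theta) & (c.pval < alpha)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(sparse.csr_matrix(adj), directed=False)
    groups: list[list[str]] = [[] for _ in range(n_comp)]
    for name, lab in zip(c.feature_names, labels):
        groups[lab].append(name)
    # deterministic order: by first member's position in the input table
    order = {n: k for k, n in enumerate(c.feature_names)}
    groups.sort(key=lambda g: min(order[n] for n in g))
    return groups


def pick_representatives(
    groups: list[list[str]], priority: list[str] | None = None
) -> CorrelationGroups:
    """Choose each group's highest-priority member (ties alphabetical)."""
    if priority is None:
        priority = DEFAULT_ROBUSTNESS_PRIORITY
    rank = {name: k for k, name in enumerate(priority)}
    missing = sorted({n for g in groups for n in g} - rank.keys())
    if missing:
        raise ConfigurationError(
            f"feature(s) missing from priority list: {', '.join(missing)}"
        )
    reps = [min(g, key=lambda n: (rank[n], n)) for g in groups]
    return CorrelationGroups(groups=[list(g) for g in groups], representatives=reps)


def preselect(
    table: FeatureTable,
    theta: float = 0.8,
    alpha: float = 0.05,
    priority: list[str] | None = None,
) -> CorrelationGroups:
    """Full pre-selection: correlation matrix -> groups -> representatives."""
    corr = spearman_matrix(table)
    groups = build_groups(corr, theta=theta, alpha=alpha)
    return pick_representatives(groups, priority)
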
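"""Group inference: covariate adjustment, permutation tests, FDR, correlations.

Group differences in network measures are tested nonparametrically.  The
dependent values are first residualized on the covariates (ordinary least
squares with an intercept; the study covariates are age, sex and six
rigid-body motion summaries), then group labels are permuted to build the
null distribution of the mean group difference (a simplified Freedman-Lane
scheme).  Two-tailed p-values use the add-one rule

    p = (1 + #{ |null| >= |observed| }) / (n_perm + 1),

which keeps p > 0 and makes the test exact at the permutation resolution.
Per-density global comparisons report the 2.5/97.5 percentile null envelope;
nodal comparisons are run on per-region AUC values and corrected across
regions with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GroupComparison",
    "GroupPermutationTest",
    "residualize",
    "permutation_test_global",
    "permutation_test_nodal_auc",
    "fdr_bh",
    "clinical_correlation",
]


def _design(covariates) -> np.ndarray:
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    return np.column_stack([np.ones(len(c)), c])


def residualize(values, covariates=None) -> np.ndarray:
    """OLS residuals of ``values`` on covariates plus an intercept.

    ``values`` may be a vector (one value per subject) or a matrix
    (subjects x features).  With no covariates the values are demeaned.
    Raises on a rank-deficient covariate matrix, naming the offending
    columns.
    """
    v = np.asarray(values, dtype=float)
    if covariates is None:
        return v - v.mean(axis=0)
    x = _design(covariates)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify columns not adding rank, scanning left to right
        bad = []
        r = 1
        for j in range(1, x.shape[1]):
            rj = np.linalg.matrix_rank(x[:, : j + 1])
            if rj == r:
                bad.append(j - 1)
            r = rj
        raise ValueError(f"covariate matrix is rank deficient (collinear columns: {bad})")
    beta, *_ = np.linalg.lstsq(x, v, rcond=None)
    return v - x @ beta


@dataclass
class GroupComparison:
    """Result of a permutation group comparison.

    ``observed`` is the group2 - group1 mean difference of residualized
    values, one entry per feature (density or region).  ``ci_low``/``ci_high``
    are the 2.5/97.5 percentiles of the permutation null.
    """

    measure: str
    scope: str  # 'global-per-density' | 'nodal-auc'
    feature_names: list
    observed: np.ndarray
    p_values: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_perm: int
    seed: int
    group_labels: tuple = ("group1", "group2")
    fdr_q: float | None = None
    rejected: np.ndarray | None = None
    p_adjusted: np.ndarray | None = None

    def apply_fdr(self, q: float = 0.05) -> "GroupComparison":
        self.rejected, self.p_adjusted = fdr_bh(self.p_values, q)
        self.fdr_q = q
        return self


class GroupPermutationTest(BaseEstimator):
    """Permutation test of group mean differences with covariate adjustment.

    Parameters
    ----------
    n_perm : int
        Number of label permutations (10 000 for the full analysis).
    seed : int
        Seed for the permutation stream; results are reproducible and
        invariant to subject ordering.
    """

    def __init__(self, n_perm: int = 10_000, seed: int = 0):
        self.n_perm = n_perm
        self.seed = seed

    def fit(self, X, y, covariates=None):
        """X: (n_subjects, n_features) values; y: binary group labels."""
        v = np.atleast_2d(np.asarray(X, dtype=float))
        if v.shape[0] == 1 and np.asarray(y).size != 1:
            v = v.T
        y = np.asarray(y)
        groups = np.unique(y)
        if len(groups) != 2:
            raise ValueError(f"expected exactly 2 groups, found {len(groups)}")
        g2 = y == groups[1]
        n1, n2 = int((~g2).sum()), int(g2.sum())
        if min(n1, n2) < 2:
            raise ValueError("each group needs at least 2 subjects")
        if self.n_perm < 100:
            logger.warning("n_perm=%d is very low; p-values will be coarse", self.n_perm)
        r = residualize(v, covariates)
        obs = r[g2].mean(axis=0) - r[~g2].mean(axis=0)
        rng = np.random.default_rng(self.seed)
        null = np.empty((self.n_perm, v.shape[1]))
        for i in range(self.n_perm):
            perm = rng.permutation(g2)
            null[i] = r[perm].mean(axis=0) - r[~perm].mean(axis=0)
        self.groups_ = tuple(groups)
        self.observed_ = obs
        self.null_ = null
        self.p_values_ = (1.0 + (np.abs(null) >= np.abs(obs)).sum(axis=0)) / (self.n_perm + 1.0)
        self.ci_low_, self.ci_high_ = np.percentile(null, [2.5, 97.5], axis=0)
        return self

    def to_comparison(self, measure: str, scope: str, feature_names) -> GroupComparison:
        return GroupComparison(
            measure=measure,
            scope=scope,
            feature_names=list(feature_names),
            observed=self.observed_,
            p_values=self.p_values_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            n_perm=self.n_perm,
            seed=self.seed,
            group_labels=tuple(str(g) for g in self.groups_),
        )


def permutation_test_global(
    values_by_density,
    groups,
    covariates=None,
    n_perm: int = 10_000,
    seed: int = 0,
    measure: str = "measure",
    densities=None,
) -> GroupComparison:
    """Per-density group comparison of a global measure.

    ``values_by_density``: (n_subjects, n_densities) array of a global measure
    evaluated on each subject's network across the density grid.
    """
    v = np.asarray(values_by_density, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    if densities is None:
        densities = list(range(v.shape[1]))
    test = GroupPermutationTest(n_perm=n_perm, seed=seed).fit(v, groups, covariates)
    return test.to_comparison(measure, "global-per-density", densities)


def permutation_test_nodal_auc(
    auc_by_region,
    groups,
    covariates=None,
    n_perm: int = 10_000,
    seed: int = 0,
    measure: str = "measure",
    region_labels=None,
    q: float | None = 0.05,
) -> GroupComparison:
    """Per-region group comparison of AUC values, BH-FDR corrected across
    regions when ``q`` is given."""
    v = np.asarray(auc_by_region, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    if region_labels is None:
        region_labels = [f"R{i:03d}" for i in range(v.shape[1])]
    test = GroupPermutationTest(n_perm=n_perm, seed=seed).fit(v, groups, covariates)
    comp = test.to_comparison(measure, "nodal-auc", region_labels)
    if q is not None:
        comp.apply_fdr(q)
    return comp


def fdr_bh(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control at level ``q``.

    Returns ``(rejected, p_adjusted)``; empty input yields empty output.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    rejected, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return rejected, p_adj


def clinical_correlation(
    network_values,
    scores,
    covariates=None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Pearson correlation between residualized network values and a clinical
    score, with a two-tailed permutation p-value.

    Used only for regions that survive the group comparison, associating their
    connectivity with symptom severity or cognitive performance.
    """
    v = np.asarray(network_values, dtype=float).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    if v.size != s.size:
        raise ValueError("values and scores must be the same length")
    if v.size < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.ptp(s) == 0:
        raise ValueError("score is constant; correlation undefined")
    rv = residualize(v, covariates)
    rs = residualize(s, covariates)
    sd_v, sd_s = rv.std(), rs.std()
    if sd_v == 0:
        raise ValueError("network values are constant after adjustment")
    r = float(np.dot(rv, rs) / (len(rv) * sd_v * sd_s))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = np.dot(rv, rng.permutation(rs)) / (len(rv) * sd_v * sd_s)
    p = float((1.0 + (np.abs(null) >= abs(r)).sum()) / (n_perm + 1.0))
    return r, p
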
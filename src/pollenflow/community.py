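"""Multivariate and rank statistics for pollinator and seed-predator data.

Covers correlation-matrix PCA of the population-year x taxon abundance
matrix, sequential (Type-I) PERMANOVA on Bray-Curtis dissimilarities,
Mann-Whitney U comparisons of camera-derived visitation, and two-sample
chi-square tests for germination and chlorosis proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from pollenflow.datamodel import CommunityMatrix

__all__ = ["PCAResult", "PermanovaResult", "UTestResult", "ChiSquareResult",
           "pca_correlation", "permanova", "bray_curtis", "mann_whitney_u",
           "chisq_two_proportions"]


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    proportion_variance: np.ndarray
    scores: pd.DataFrame
    variable_axis_correlations: pd.DataFrame  # signed Pearson r, variables x axes

    @property
    def abs_correlations(self) -> pd.DataFrame:
        return self.variable_axis_correlations.abs()


def pca_correlation(m: CommunityMatrix) -> PCAResult:
    """PCA on the correlation matrix of the abundance columns.

    Columns are standardized to zero mean and unit variance; scores are
    the standardized data projected on the eigenvectors. The sign of
    each axis is normalized so its largest-|loading| variable loads
    positively. Variable-axis association is the Pearson correlation
    between each raw column and the axis scores.
    """
    X = m.counts.to_numpy(dtype=float)
    if len(X) < 3:
        raise ValueError("need at least 3 rows for PCA")
    sd = X.std(axis=0, ddof=1)
    zero_var = np.flatnonzero(sd == 0)
    if zero_var.size:
        names = [m.taxa[i] for i in zero_var]
        raise ValueError(f"zero-variance column(s): {names}")
    Z = (X - X.mean(axis=0)) / sd
    C = np.corrcoef(X, rowvar=False)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    # sign convention: largest-|loading| variable positive on each axis
    for j in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    scores = Z @ evecs
    axes = [f"PC{j + 1}" for j in range(len(evals))]
    corr = np.array([[float(np.corrcoef(X[:, v], scores[:, j])[0, 1])
                      for j in range(len(axes))] for v in range(X.shape[1])])
    return PCAResult(
        eigenvalues=evals,
        proportion_variance=evals / evals.sum(),
        scores=pd.DataFrame(scores, index=m.row_labels, columns=axes),
        variable_axis_correlations=pd.DataFrame(corr, index=m.taxa, columns=axes))


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity sum|a-b| / sum(a+b) for count vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("Bray-Curtis requires non-negative vectors")
    tot = float(np.sum(a + b))
    if tot == 0:
        raise ValueError("Bray-Curtis undefined: both vectors all-zero")
    return float(np.sum(np.abs(a - b)) / tot)


@dataclass
class PermanovaResult:
    table: pd.DataFrame  # term, df, sum_of_squares, pseudo_F, p_perm
    residual_df: int
    residual_ss: float
    total_ss: float
    n_perm: int
    distance_metric: str

    def pseudo_f(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "pseudo_F"])

    def p_value(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "p_perm"])


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = len(d2)
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ d2 @ J


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X.T @ X) @ X.T


def permanova(m: CommunityMatrix, factors=("ecotype", "year"),
              distance: str = "bray_curtis", n_perm: int = 999,
              seed: int = 0) -> PermanovaResult:
    """Sequential (Type-I) PERMANOVA on the abundance matrix.

    Partitions the distance-based sums of squares term by term in the
    order given (each term adjusted for those before it); pseudo-F per
    term uses the residual of the full model. Significance by permuting
    rows of the distance matrix.
    """
    X = m.counts.to_numpy(dtype=float)
    n = len(X)
    if distance == "bray_curtis":
        if np.any(X.sum(axis=1) == 0):
            raise ValueError("all-zero row: Bray-Curtis distances undefined")
        d = squareform(pdist(X, metric="braycurtis"))
    elif distance == "euclidean":
        d = squareform(pdist(X, metric="euclidean"))
    else:
        raise ValueError(f"unknown distance {distance!r}")

    meta = {"ecotype": m.ecotype, "year": m.year}
    designs = []
    dfs = []
    Xcur = np.ones((n, 1))
    for f in factors:
        levels = pd.unique(meta[f])
        if len(levels) < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")
        dummies = np.column_stack([(meta[f] == lv).astype(float) for lv in levels[1:]])
        Xcur = np.column_stack([Xcur, dummies])
        designs.append(Xcur.copy())
        dfs.append(len(levels) - 1)

    hats = [_hat(Xd) for Xd in designs]
    h_full = hats[-1]
    n_terms = len(factors)
    df_res = n - 1 - sum(dfs)

    def partition(dmat):
        G = _gower_center(dmat ** 2)
        total = float(np.trace(G))
        ss_terms = []
        prev = _hat(np.ones((n, 1)))
        for H in hats:
            ss_terms.append(float(np.trace((H - prev) @ G)))
            prev = H
        ss_res = float(np.trace((np.eye(n) - h_full) @ G))
        return ss_terms, ss_res, total

    ss_terms, ss_res, total = partition(d)
    f_obs = [(ss_terms[i] / dfs[i]) / (ss_res / df_res) for i in range(n_terms)]

    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_terms)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ss_p, ss_res_p, _ = partition(d[np.ix_(perm, perm)])
        for i in range(n_terms):
            if (ss_p[i] / dfs[i]) / (ss_res_p / df_res) >= f_obs[i]:
                exceed[i] += 1
    p = (1.0 + exceed) / (n_perm + 1.0)

    table = pd.DataFrame({
        "term": list(factors), "df": dfs, "sum_of_squares": ss_terms,
        "pseudo_F": f_obs, "p_perm": p})
    return PermanovaResult(table=table, residual_df=df_res, residual_ss=ss_res,
                           total_ss=total, n_perm=n_perm, distance_metric=distance)


@dataclass
class UTestResult:
    U_first: float
    U_other: float
    p_two_sided: float


def mann_whitney_u(first, second) -> UTestResult:
    """Mann-Whitney U with midranks and tie-corrected normal approximation.

    ``U_first`` is the statistic for the sample given first;
    ``U_other = n1*n2 - U_first``.
    """
    first = np.asarray(first, dtype=float)
    second = np.asarray(second, dtype=float)
    if len(first) < 1 or len(second) < 1:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(first, second, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    u1 = float(res.statistic)
    return UTestResult(U_first=u1, U_other=len(first) * len(second) - u1,
                       p_two_sided=float(res.pvalue))


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p: float


def chisq_two_proportions(successes1: int, total1: int, successes2: int,
                          total2: int, correction: bool = False) -> ChiSquareResult:
    """Pearson chi-square on the 2x2 table of successes/failures.

    No continuity correction by default; pass ``correction=True`` for
    the Yates-corrected variant.
    """
    if total1 <= 0 or total2 <= 0:
        raise ValueError("group totals must be positive")
    table = np.array([[successes1, total1 - successes1],
                      [successes2, total2 - successes2]], dtype=float)
    if np.any(table < 0):
        raise ValueError("successes exceed totals")
    expected = stats.contingency.expected_freq(table)
    if np.any(expected == 0):
        raise ValueError("expected cell count of zero: test undefined")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=correction)
    return ChiSquareResult(statistic=float(chi2), df=int(dof), p=float(p))
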
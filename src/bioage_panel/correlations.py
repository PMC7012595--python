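"""Repeated-measures correlation and correlation-distance clustering.

``rmcorr`` estimates the common within-subject association between two
repeatedly measured variables: subject means are removed from both series
and the Pearson correlation of the centered values is computed, which is
algebraically identical to the ANCOVA decomposition (a common slope with
subject-specific intercepts).  Degrees of freedom are N - k - 1 for N used
observations from k subjects; the p-value comes from the t reference
t = r * sqrt(df / (1 - r^2)) and the confidence interval from a Fisher
z-transform with standard error 1/sqrt(df - 1).

``cluster_bas`` turns a correlation matrix into squared Euclidean distances
between standardized variables, d^2(a, b) = 2 (1 - r_ab), and agglomerates
with Ward's method.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "RmcorrResult",
    "rmcorr",
    "correlation_matrix",
    "complete_measurements",
    "cluster_bas",
    "ClusterResult",
]


class DegenerateWithinSubjectError(ValueError):
    """No within-subject variation left after centering."""


@dataclass
class RmcorrResult:
    r: float
    df: int
    p_value: float
    ci95: tuple[float, float]
    n_obs: int
    n_subjects: int


def rmcorr(x, y, subjects) -> RmcorrResult:
    """Repeated-measures correlation of two variables over subjects.

    Subjects contribute only their complete (x, y) visits; subjects with
    fewer than two complete visits are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    subjects = np.asarray(subjects)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y, subjects = x[ok], y[ok], subjects[ok]

    codes, counts = np.unique(subjects, return_counts=True)
    keep_ids = codes[counts >= 2]
    m = np.isin(subjects, keep_ids)
    x, y, subjects = x[m], y[m], subjects[m]
    n, k = x.size, keep_ids.size
    if k < 2:
        raise ValueError("need at least 2 subjects with >= 2 complete visits")

    _, inv = np.unique(subjects, return_inverse=True)
    xm = np.bincount(inv, x) / np.bincount(inv)
    ym = np.bincount(inv, y) / np.bincount(inv)
    xc = x - xm[inv]
    yc = y - ym[inv]
    ssx, ssy = float(xc @ xc), float(yc @ yc)
    if ssx <= 0 or ssy <= 0:
        raise DegenerateWithinSubjectError(
            "degenerate within-subject variance: a variable is constant "
            "within every subject"
        )
    r = float((xc @ yc) / np.sqrt(ssx * ssy))
    r = float(np.clip(r, -1.0, 1.0))
    dof = n - k - 1
    if dof < 1:
        raise ValueError(f"non-positive error degrees of freedom (N={n}, k={k})")
    if abs(r) < 1.0:
        t = r * np.sqrt(dof / (1.0 - r ** 2))
        p = float(2.0 * stats.t.sf(abs(t), dof))
    else:
        p = 0.0
    if dof > 1 and abs(r) < 1.0:
        z = np.arctanh(r)
        hw = stats.norm.ppf(0.975) / np.sqrt(dof - 1)
        ci = (float(np.tanh(z - hw)), float(np.tanh(z + hw)))
    else:
        ci = (r, r)
    return RmcorrResult(r=r, df=int(dof), p_value=p, ci95=ci,
                        n_obs=int(n), n_subjects=int(k))


def complete_measurements(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    """Visits at which every listed variable is observed."""
    return df.loc[df[cols].notna().all(axis=1)]


def correlation_matrix(df: pd.DataFrame, cols: list[str],
                       subject_col: str = "individual_id"
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs rmcorr matrix (and its df matrix) on complete rows.

    Rows are first restricted to visits with every variable present, so
    each cell uses the same observations.  Pairs failing the rmcorr
    preconditions give NaN cells with a warning.
    """
    rows = complete_measurements(df, cols)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    dof = pd.DataFrame(0, index=cols, columns=cols, dtype=int)
    for a, b in combinations(cols, 2):
        try:
            res = rmcorr(rows[a], rows[b], rows[subject_col])
        except ValueError as e:   # degenerate cell: leave missing
            import warnings
            warnings.warn(f"rmcorr({a}, {b}) failed: {e}", stacklevel=2)
            r.loc[a, b] = r.loc[b, a] = np.nan
            continue
        r.loc[a, b] = r.loc[b, a] = res.r
        dof.loc[a, b] = dof.loc[b, a] = res.df
    return r, dof


@dataclass
class ClusterResult:
    labels: list[str]
    linkage: np.ndarray           # scipy linkage matrix
    distances: pd.DataFrame       # the d^2 = 2(1-r) matrix
    newick: str

    def flat_clusters(self, k: int) -> dict[str, int]:
        assign = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assign)))


def cluster_bas(corr: pd.DataFrame, transform: str = "2(1-r)") -> ClusterResult:
    """Ward hierarchical clustering of variables from their correlations.

    ``transform="2(1-r)"`` (default) reads d^2 = 2 (1 - r): the squared
    Euclidean distance between standardized variables.  The alternative
    ``"1-r"`` uses d^2 = 1 - r.  Ward linkage operates on the Euclidean
    distances d (the square roots).
    """
    if corr.isna().any().any():
        raise ValueError(
            "correlation matrix has missing cells; recompute with a "
            "pairwise-complete configuration before clustering"
        )
    labels = list(corr.columns)
    r = corr.to_numpy(dtype=float)
    if transform == "2(1-r)":
        d2 = 2.0 * (1.0 - r)
    elif transform == "1-r":
        d2 = 1.0 - r
    else:
        raise ValueError("transform must be '2(1-r)' or '1-r'")
    d2 = np.clip(d2, 0.0, None)
    np.fill_diagonal(d2, 0.0)
    condensed = np.sqrt(d2[np.triu_indices_from(d2, k=1)])
    Z = hierarchy.linkage(condensed, method="ward")
    tree = hierarchy.to_tree(Z)

    def _newick(node):
        if node.is_leaf():
            return labels[node.id]
        return (f"({_newick(node.left)}:{node.dist - node.left.dist:.6g},"
                f"{_newick(node.right)}:{node.dist - node.right.dist:.6g})")

    return ClusterResult(
        labels=labels,
        linkage=Z,
        distances=pd.DataFrame(d2, index=labels, columns=labels),
        newick=_newick(tree) + ";",
    )
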
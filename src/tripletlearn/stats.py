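"""Group-level statistics: pooled-variance t-tests, cluster-based
permutation comparison of TLI time courses, z-standardization, and
brain-behavior correlations.

The cluster test controls the family-wise error across time points:
pointwise independent-samples t-tests are thresholded at an
uncorrected alpha, runs of at least ``min_len`` adjacent suprathreshold
points of the same sign form clusters scored by their summed t-values,
and each observed cluster is compared with the permutation null of the
maximum absolute cluster sum obtained by shuffling group labels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst


@dataclass
class GroupTest:
    t: float
    df: int
    p: float
    d: float
    alternative: str = "two-sided"


def group_ttest(x, y, alternative: str = "two-sided") -> GroupTest:
    """Pooled-variance independent-samples t-test with Cohen's d.

    ``alternative='greater'`` tests mean(x) > mean(y).  df = n1+n2-2.
    Cohen's d uses the pooled sample SD.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 observations per group")
    n1, n2 = x.size, y.size
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    if alternative == "two-sided":
        p = 2 * sst.t.sf(abs(t), df)
    elif alternative == "greater":
        p = sst.t.sf(t, df)
    elif alternative == "less":
        p = sst.t.cdf(t, df)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    d = (x.mean() - y.mean()) / np.sqrt(sp2)
    return GroupTest(t=float(t), df=df, p=float(p), d=float(d),
                     alternative=alternative)


def zstandardize(scores) -> np.ndarray:
    """(x - mean) / sample SD; mean 0 and SD 1 across the sample."""
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 values to z-standardize")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation; cannot z-standardize")
    return (x - x.mean()) / sd


@dataclass
class CorrResult:
    r: float
    p: float
    n: int
    alternative: str = "greater"


def brain_behavior_correlation(tli, scores,
                               alternative: str = "greater") -> CorrResult:
    """Pearson correlation of per-subject TLI with a behavioral score.

    One-sided (r > 0) by default, matching the directional hypothesis
    that stronger triplet tracking goes with better literacy scores.
    """
    x = np.asarray(tli, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.size != y.size:
        raise ValueError("tli and scores must be paired")
    if x.size < 4:
        raise ValueError("need >= 4 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the variables")
    res = sst.pearsonr(x, y, alternative=alternative)
    return CorrResult(r=float(res.statistic), p=float(res.pvalue),
                      n=x.size, alternative=alternative)


# ---------------------------------------------------------------------------
# cluster-based permutation test
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    start: int          # first time point index (inclusive)
    end: int            # last time point index (inclusive)
    sum_t: float
    p: float = np.nan


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    t_series: np.ndarray
    p_pointwise: np.ndarray
    null_distribution: np.ndarray
    n_permutations: int
    alpha_pointwise: float
    min_cluster_len: int
    exact: bool = False

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p < 0.05]


def _pointwise_t(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Pooled t per time point for group1 = mask rows; vectorized over
    permutations if ``mask`` is 2-D (n_perm, n_subjects)."""
    mask = np.atleast_2d(mask).astype(float)
    n1 = mask.sum(axis=1, keepdims=True)
    n2 = mask.shape[1] - n1
    s1 = mask @ X
    s2 = X.sum(axis=0, keepdims=True) - s1
    q1 = mask @ (X ** 2)
    q2 = (X ** 2).sum(axis=0, keepdims=True) - q1
    m1, m2 = s1 / n1, s2 / n2
    df = mask.shape[1] - 2
    sp2 = (q1 - n1 * m1 ** 2 + q2 - n2 * m2 ** 2) / df
    denom = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
    return t


def _clusters_from_t(t: np.ndarray, thresh: float, min_len: int
                     ) -> list[tuple[int, int, float]]:
    """Maximal same-sign runs of |t| > thresh with length >= min_len."""
    above = np.abs(t) > thresh
    sign = np.sign(t)
    out = []
    i, T = 0, len(t)
    while i < T:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < T and above[j + 1] and sign[j + 1] == sign[i]:
            j += 1
        if j - i + 1 >= min_len:
            out.append((i, j, float(t[i:j + 1].sum())))
        i = j + 1
    return out


def _max_cluster_stats(tmat: np.ndarray, thresh: float,
                       min_len: int) -> np.ndarray:
    out = np.zeros(tmat.shape[0])
    for k in range(tmat.shape[0]):
        cl = _clusters_from_t(tmat[k], thresh, min_len)
        if cl:
            out[k] = max(abs(c[2]) for c in cl)
    return out


def cluster_permutation(timecourses: np.ndarray, groups,
                        n_perm: int = 1000, alpha: float = 0.05,
                        min_len: int = 2, seed: int | None = None,
                        exact: bool = False) -> ClusterTestResult:
    """Cluster-based permutation comparison of two groups of time courses.

    ``timecourses``: (n_subjects, n_timepoints); ``groups``: per-subject
    labels with exactly two levels (the first level encountered is
    "group 1"; the statistic's sign convention follows it, and cluster
    p-values are invariant to which group comes first).

    Cluster p = (1 + #{null >= |sum t|}) / (n_perm + 1) with the random
    null; with ``exact=True`` all distinct relabelings of group-1
    membership are enumerated and p is the exact proportion.
    """
    X = np.asarray(timecourses, dtype=float)
    if X.ndim != 2:
        raise ValueError("timecourses must be (n_subjects, n_timepoints)")
    labels = np.asarray(groups)
    levels = list(dict.fromkeys(labels.tolist()))
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    g1 = labels == levels[0]
    if g1.sum() < 2 or (~g1).sum() < 2:
        raise ValueError("need >= 2 subjects per group")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("constant time courses; t-statistics undefined")
    n, T = X.shape
    df = n - 2
    thresh = sst.t.ppf(1 - alpha / 2, df)

    t_obs = _pointwise_t(X, g1)[0]
    p_pointwise = 2 * sst.t.sf(np.abs(t_obs), df)
    observed = _clusters_from_t(t_obs, thresh, min_len)

    n1 = int(g1.sum())
    if exact:
        combos = list(itertools.combinations(range(n), n1))
        masks = np.zeros((len(combos), n), dtype=bool)
        for k, c in enumerate(combos):
            masks[k, list(c)] = True
        null = _max_cluster_stats(_pointwise_t(X, masks), thresh, min_len)
        n_eff = len(combos)
        pvals = [(null >= abs(c[2]) - 1e-12).mean() for c in observed]
    else:
        rng = np.random.default_rng(seed)
        masks = np.zeros((n_perm, n), dtype=bool)
        for k in range(n_perm):
            masks[k, rng.permutation(n)[:n1]] = True
        null = _max_cluster_stats(_pointwise_t(X, masks), thresh, min_len)
        n_eff = n_perm
        pvals = [(1 + (null >= abs(c[2]) - 1e-12).sum()) / (n_perm + 1)
                 for c in observed]

    clusters = [Cluster(start=c[0], end=c[1], sum_t=c[2], p=float(p))
                for c, p in zip(observed, pvals)]
    return ClusterTestResult(clusters=clusters, t_series=t_obs,
                             p_pointwise=p_pointwise,
                             null_distribution=null,
                             n_permutations=n_eff,
                             alpha_pointwise=alpha,
                             min_cluster_len=min_len, exact=exact)


def behavior_table(behavior: pd.DataFrame,
                   raw_columns: tuple[str, ...] = ()) -> pd.DataFrame:
    """Attach z-standardized versions of raw behavioral score columns."""
    out = behavior.copy()
    for c in raw_columns:
        out[c + "_z"] = zstandardize(out[c].to_numpy())
    return out
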
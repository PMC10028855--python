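"""Cross-signature comparison: correlation clustering, survival, group tests.

The clustering mirrors the case-study recipe: Euclidean distances between
the rows of the score correlation matrix, complete-linkage agglomeration,
and silhouette-guided choice of the number of clusters.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import scipy.stats
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from statsmodels.stats.multitest import multipletests

from sigcompass.errors import SigcompassError


def score_correlation_matrix(
    score_table: pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Pairwise-complete correlation matrix of signature score columns.

    Zero-variance signatures are dropped with a warning; the diagonal is
    exactly 1.
    """
    if method not in ("pearson", "spearman"):
        raise SigcompassError(f"unknown correlation method {method!r}")
    numeric = score_table.select_dtypes(include=[np.number])
    if numeric.shape[1] < 2:
        raise SigcompassError("need at least 2 numeric signature columns")
    if numeric.shape[0] < 3:
        raise SigcompassError("need at least 3 observations")
    sd = numeric.std(ddof=1)
    flat = sd.index[(sd == 0) | sd.isna()]
    if len(flat):
        warnings.warn(
            f"zero-variance signature(s) dropped from correlation: {list(flat)}",
            stacklevel=2,
        )
        numeric = numeric.drop(columns=list(flat))
        if numeric.shape[1] < 2:
            raise SigcompassError("fewer than 2 signatures left after dropping zero variance")
    corr = numeric.corr(method=method)
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass
class ClusterResult:
    """Complete-linkage tree over correlation-matrix rows."""

    names: list[str]
    linkage: np.ndarray  # scipy linkage matrix
    distances: pd.DataFrame  # Euclidean distances between corr rows

    def labels(self, k: int) -> pd.Series:
        lab = sch.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(lab, index=self.names, name="cluster")

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()


def cluster_scores(corr: pd.DataFrame) -> ClusterResult:
    """Hierarchical clustering of signatures from their correlation profiles.

    Distance is Euclidean between rows of the correlation matrix;
    agglomeration is complete linkage.  Missing entries are an error (drop
    zero-variance signatures before calling).
    """
    if corr.isna().any().any():
        raise SigcompassError(
            "correlation matrix contains missing entries; drop incomplete rows first"
        )
    dvec = ssd.pdist(corr.to_numpy(), metric="euclidean")
    link = sch.linkage(dvec, method="complete")
    dmat = pd.DataFrame(
        ssd.squareform(dvec), index=corr.index, columns=corr.index
    )
    return ClusterResult(names=list(corr.index), linkage=link, distances=dmat)


def mean_silhouette(dist: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width from a precomputed distance matrix.

    Singleton clusters contribute 0 for their point (standard convention).
    """
    n = len(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise SigcompassError("silhouette needs >=2 clusters")
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        a = dist[i, own].sum() / (n_own - 1)
        b = min(dist[i, labels == c].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def select_k_silhouette(
    corr: pd.DataFrame,
    clustering: ClusterResult | None = None,
    k_range: range | None = None,
) -> tuple[int, pd.Series]:
    """Choose the cluster count maximising mean silhouette over the tree.

    Uses the same Euclidean distances as the clustering; ties go to the
    smallest k.  Returns (k_best, profile of mean silhouette by k).
    """
    n = corr.shape[0]
    if n < 3:
        raise SigcompassError("silhouette-based selection needs >=3 signatures")
    clustering = clustering or cluster_scores(corr)
    dist = clustering.distances.to_numpy()
    if np.allclose(dist, 0):
        raise SigcompassError(
            "all signatures are identical (zero distances); silhouette undefined"
        )
    k_range = k_range or range(2, min(10, n - 1) + 1)
    profile = {}
    for k in k_range:
        labels = clustering.labels(k).to_numpy()
        if len(np.unique(labels)) < 2:
            continue
        profile[k] = mean_silhouette(dist, labels)
    if not profile:
        raise SigcompassError("no valid k in range produced >=2 clusters")
    prof = pd.Series(profile, name="mean_silhouette").sort_index()
    k_best = int(prof.idxmax())  # idxmax returns first (smallest) k on ties
    return k_best, prof


@dataclass
class SurvivalResult:
    """Median-split survival association for one signature score."""

    signature: str
    split_value: float
    logrank_stat: float
    p_value: float
    n_low: int
    n_high: int
    curves: dict = field(default_factory=dict)  # arm -> KaplanMeierFitter

    def as_row(self) -> dict:
        return {
            "signature": self.signature,
            "split_value": self.split_value,
            "logrank_stat": self.logrank_stat,
            "p": self.p_value,
            "n_low": self.n_low,
            "n_high": self.n_high,
        }


def survival_association(
    scores: pd.Series,
    time: pd.Series,
    event: pd.Series,
    split: str | float = "median",
) -> SurvivalResult:
    """Dichotomize a score and test the two arms with a two-sample log-rank.

    Default split is the score median; tied values go to the low arm.
    Kaplan-Meier fitters for both arms are returned alongside the statistic.
    An all-censored arm yields a warning and a missing p-value.
    """
    df = pd.DataFrame({"score": scores, "time": time, "event": event}).dropna()
    split_value = float(df["score"].median()) if split == "median" else float(split)
    low = df["score"] <= split_value
    n_low, n_high = int(low.sum()), int((~low).sum())
    if n_low == 0 or n_high == 0:
        raise SigcompassError("median split produced an empty arm")

    curves = {}
    all_censored = False
    for arm, mask in (("low", low), ("high", ~low)):
        km = KaplanMeierFitter(label=f"{scores.name or 'score'}_{arm}")
        km.fit(df.loc[mask, "time"], df.loc[mask, "event"])
        curves[arm] = km
        if df.loc[mask, "event"].sum() == 0:
            all_censored = True
    if all_censored:
        warnings.warn("an arm has no events; log-rank p-value set missing", stacklevel=2)
        stat, p = np.nan, np.nan
    else:
        res = logrank_test(
            df.loc[low, "time"], df.loc[~low, "time"],
            event_observed_A=df.loc[low, "event"], event_observed_B=df.loc[~low, "event"],
        )
        stat, p = float(res.test_statistic), float(res.p_value)
    return SurvivalResult(
        signature=str(scores.name or "score"),
        split_value=split_value,
        logrank_stat=stat,
        p_value=p,
        n_low=n_low,
        n_high=n_high,
        curves=curves,
    )


def group_compare(
    scores: pd.DataFrame,
    group_labels: pd.Series,
    min_group_size: int = 20,
    adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """Welch t-tests of every signature between every eligible group pair.

    Groups below ``min_group_size`` are excluded with a warning.  P-values
    are Benjamini-Hochberg adjusted across the whole returned table.
    """
    numeric = scores.select_dtypes(include=[np.number])
    labels = group_labels.reindex(numeric.index)
    sizes = labels.value_counts()
    eligible = sorted(sizes.index[sizes >= min_group_size])
    small = sorted(set(sizes.index) - set(eligible))
    if small:
        warnings.warn(
            f"group(s) below min size {min_group_size} excluded: {small}", stacklevel=2
        )
    if len(eligible) < 2:
        raise SigcompassError("need at least 2 groups meeting the minimum size")

    rows = []
    for sig in numeric.columns:
        for ga, gb in itertools.combinations(eligible, 2):
            a = numeric.loc[labels == ga, sig].dropna()
            b = numeric.loc[labels == gb, sig].dropna()
            res = scipy.stats.ttest_ind(a, b, equal_var=False)
            rows.append(
                {
                    "signature": sig,
                    "groupA": ga,
                    "groupB": gb,
                    "n_A": len(a),
                    "n_B": len(b),
                    "t_stat": float(res.statistic),
                    "p": float(res.pvalue),
                }
            )
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p"], method=adjust)[1]
    return table
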
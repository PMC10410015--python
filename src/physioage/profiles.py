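"""Explanation-space clustering and cluster signatures.

Individuals are clustered on their contextualized contribution rows
(Ward linkage, Euclidean distance; chronological age is not a feature),
grouping people whose physiological-age deviation is *explained the
same way*. For every variable and cluster pair a Mann-Whitney test with
a rank-biserial-style effect size r = |Z| / sqrt(n1 + n2) is run; only
variables with at least a medium effect (r >= 0.3) and a
Benjamini-Hochberg-adjusted significant p-value are retained in a
cluster's signature. Decision profiles accumulate the cluster's mean
contributions in importance order down to its mean PPA deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import mannwhitneyu, norm, rankdata, tiecorrect
from statsmodels.stats.multitest import multipletests

from .cohort import CohortError
from .explain import ExplanationMatrix, ImportanceRanking


@dataclass
class ClusterAssignment:
    labels: pd.Series  # id -> cluster label in 1..k
    k: int
    linkage_record: np.ndarray  # scipy linkage matrix (merge heights)


@dataclass
class ClusterSignature:
    cluster: int
    mean_phi: pd.Series  # variable -> mean contextualized contribution (years)
    retained_variables: list[str]
    decision_path: pd.DataFrame  # variable, mean_phi, cumulative


def cluster_explanations(expl: ExplanationMatrix, k: int, seed: int = 0) -> ClusterAssignment:
    """Agglomerative Ward clustering of contribution rows, cut at ``k``.

    Deterministic given the matrix (the seed only disambiguates exact
    distance ties, which do not arise on continuous contributions).
    """
    n = len(expl.phi)
    if k < 2 or k > n:
        raise CohortError("need n >= k >= 2 clusters")
    X = expl.phi.to_numpy(dtype=float)
    Z = linkage(X, method="ward", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterAssignment(
        labels=pd.Series(labels, index=expl.phi.index, name="cluster"),
        k=k,
        linkage_record=Z,
    )


def silhouette_report(expl: ExplanationMatrix, k_values=range(2, 13), seed: int = 0,
                      sample: int = 2000) -> pd.DataFrame:
    """Mean silhouette width of the Ward partition for each candidate k.

    No automatic k-selection is imposed; this report lets the analyst
    judge the cluster-count trade-off. Computed on a subsample for large
    cohorts.
    """
    from sklearn.metrics import silhouette_score

    X = expl.phi.to_numpy(dtype=float)
    if len(X) > sample:
        idx = np.random.default_rng(seed).choice(len(X), size=sample, replace=False)
        X = X[idx]
    Z = linkage(X, method="ward", metric="euclidean")
    rows = []
    for k in k_values:
        labels = fcluster(Z, t=k, criterion="maxclust")
        rows.append((k, float(silhouette_score(X, labels))))
    return pd.DataFrame(rows, columns=["k", "silhouette"])


def mann_whitney_effect(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """(U, Z, r, p) for a two-sided Mann-Whitney comparison.

    ``U`` counts pairs where an ``x`` observation exceeds a ``y`` one
    (ties half-weighted). ``Z`` is the tie-corrected normal deviate
    without continuity correction — the deviate the effect size
    r = |Z|/sqrt(n1+n2) is defined from. The p-value uses the exact null
    distribution when n1+n2 <= 12 and the sample is tie-free, otherwise
    the tie- and continuity-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:  # degenerate: constant variable
        return float(n1 * n2 / 2.0), 0.0, 0.0, 1.0
    ranks = rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    tie = tiecorrect(ranks)
    sigma = np.sqrt(tie * n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = 0.0 if sigma == 0 else (u1 - mu) / sigma
    r = abs(z) / np.sqrt(n1 + n2)
    tie_free = len(np.unique(pooled)) == n1 + n2
    if n1 + n2 <= 12 and tie_free:
        p = float(mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
    else:
        if sigma == 0:
            p = 1.0
        else:
            z_cc = (abs(u1 - mu) - 0.5) / sigma
            p = float(2.0 * norm.sf(max(z_cc, 0.0)))
    return float(u1), float(z), float(r), min(p, 1.0)


def signature_tests(
    expl: ExplanationMatrix,
    assignment: ClusterAssignment,
    r_min: float = 0.3,
    alpha: float = 0.05,
    family: str = "per_pair",
) -> pd.DataFrame:
    """Mann-Whitney + effect-size + FDR screen for every (variable,
    cluster-pair).

    Benjamini-Hochberg adjustment is applied across the variables of one
    cluster pair (``family="per_pair"``) or across all pairs pooled
    (``family="pooled"``). A variable is retained for a pair when
    ``r >= r_min`` and ``q < alpha``.
    """
    if family not in ("per_pair", "pooled"):
        raise CohortError("family must be 'per_pair' or 'pooled'")
    labels = assignment.labels
    counts = labels.value_counts()
    if (counts < 2).any():
        raise CohortError("every cluster needs at least 2 members")
    clusters = sorted(counts.index)
    rows = []
    for ia, ca in enumerate(clusters):
        in_a = expl.phi.loc[labels[labels == ca].index]
        for cb in clusters[ia + 1:]:
            in_b = expl.phi.loc[labels[labels == cb].index]
            for var in expl.phi.columns:
                u, z, r, p = mann_whitney_effect(in_a[var].to_numpy(), in_b[var].to_numpy())
                rows.append((var, ca, cb, u, z, r, p))
    out = pd.DataFrame(rows, columns=["variable", "cluster_a", "cluster_b", "U", "Z", "r", "p"])
    out["q"] = np.nan
    if family == "pooled":
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    else:
        for _, idx in out.groupby(["cluster_a", "cluster_b"]).groups.items():
            out.loc[idx, "q"] = multipletests(out.loc[idx, "p"].to_numpy(), method="fdr_bh")[1]
    out["q"] = np.maximum(out["q"], out["p"])  # step-up never decreases p
    out["retained"] = (out["r"] >= r_min) & (out["q"] < alpha)
    return out


def cluster_decision_profile(
    expl: ExplanationMatrix,
    assignment: ClusterAssignment,
    ordering: ImportanceRanking,
    tests: pd.DataFrame | None = None,
) -> list[ClusterSignature]:
    """Mean contribution profile and cumulative decision path per cluster.

    The path accumulates mean contributions in the supplied importance
    order; its terminal value is the cluster's mean PPA deviation. When
    ``tests`` is given, a cluster's retained variables are those passing
    the signature screen against at least one other cluster.
    """
    labels = assignment.labels
    order = [v for v in ordering.variables if v in expl.phi.columns]
    order += [v for v in expl.phi.columns if v not in order]  # keep the path exhaustive
    signatures = []
    for cluster in sorted(labels.unique()):
        members = labels[labels == cluster].index
        if len(members) == 0:
            raise CohortError(f"cluster {cluster} is empty")
        mean_phi = expl.phi.loc[members].mean(axis=0)
        retained: list[str] = []
        if tests is not None:
            hit = tests[
                tests["retained"]
                & ((tests["cluster_a"] == cluster) | (tests["cluster_b"] == cluster))
            ]
            retained = sorted(hit["variable"].unique())
        path = pd.DataFrame({"variable": order, "mean_phi": mean_phi.loc[order].to_numpy()})
        path["cumulative"] = path["mean_phi"].cumsum()
        signatures.append(
            ClusterSignature(
                cluster=int(cluster),
                mean_phi=mean_phi,
                retained_variables=retained,
                decision_path=path,
            )
        )
    return signatures
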
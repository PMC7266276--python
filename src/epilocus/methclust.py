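"""Hierarchical clustering of a samples x CpG beta-value matrix.

Emulates the heatmap analysis run on patient RRBS data: unsupervised
agglomerative clustering of samples (pairwise-complete Euclidean distance,
average linkage by default), a two-cluster cut scored for purity against
known group labels, and per-group means over the two promoter methylation
domains (a TSS-adjacent hypomethylated proximal zone and a more methylated
distal zone) compared by two-tailed t-tests.

Missing beta values ("NA" in the TSV serialisation) are allowed throughout:
distances are computed over the CpGs observed in both samples and rescaled
to the full column count, and columns observed in fewer than two samples are
dropped with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BetaMatrix:
    """Samples x CpG methylation fractions with group and domain annotations."""

    values: pd.DataFrame          # samples x CpG, NaN = unavailable
    sample_groups: pd.Series      # per sample
    domains: pd.Series            # per CpG column: "proximal" | "distal"

    def __post_init__(self) -> None:
        finite = self.values.to_numpy(dtype=float)
        finite = finite[np.isfinite(finite)]
        if len(finite) and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")


@dataclass(frozen=True)
class ClusterResult:
    linkage: np.ndarray
    leaf_order: tuple[str, ...]
    two_cluster_labels: pd.Series
    purity: float | None


def _pairwise_complete_distance(values: pd.DataFrame, metric: str) -> np.ndarray:
    """Condensed distance matrix over shared observed CpGs, rescaled by the
    fraction observed so sparsity does not shrink distances."""
    x = values.to_numpy(dtype=float)
    n, p = x.shape
    obs = np.isfinite(x)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = obs[i] & obs[j]
            k = int(shared.sum())
            if k == 0:
                raise ValueError(
                    f"samples {values.index[i]!r} and {values.index[j]!r} share no observed CpGs"
                )
            diff = x[i, shared] - x[j, shared]
            if metric == "euclidean":
                d[i, j] = d[j, i] = np.sqrt(np.sum(diff**2) * p / k)
            elif metric == "manhattan":
                d[i, j] = d[j, i] = np.sum(np.abs(diff)) * p / k
            else:
                raise ValueError(f"unsupported distance {metric!r}")
    return squareform(d, checks=False)


def cluster_purity(truth: pd.Series, labels: pd.Series) -> float:
    """Fraction of samples in the majority truth group of their cluster."""
    correct = 0
    for _, idx in labels.groupby(labels).groups.items():
        correct += truth.loc[idx].value_counts().iloc[0]
    return correct / len(labels)


def cluster_samples(
    matrix: BetaMatrix,
    distance: str = "euclidean",
    linkage: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of samples with a scored two-cluster cut.

    Columns observed in fewer than two samples are dropped first.  The tree
    is deterministic given the input (scipy's tie-breaking by merge order);
    purity of the two-cluster cut is computed against ``sample_groups``.
    """
    values = matrix.values
    if len(values) < 3:
        raise ValueError("need at least 3 samples to cluster")
    observed = values.notna().sum(axis=0)
    keep = observed >= 2
    if (~keep).any():
        logger.info("dropping %d CpG columns observed in < 2 samples", int((~keep).sum()))
    values = values.loc[:, keep]
    if values.shape[1] == 0:
        raise ValueError("no CpG columns with >= 2 observations")
    condensed = _pairwise_complete_distance(values, distance)
    Z = hierarchy.linkage(condensed, method=linkage)
    order = hierarchy.leaves_list(Z)
    cut = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    labels = pd.Series(cut, index=values.index, name="cluster")
    purity = cluster_purity(matrix.sample_groups, labels)
    return ClusterResult(
        linkage=Z,
        leaf_order=tuple(values.index[order]),
        two_cluster_labels=labels,
        purity=purity,
    )


def domain_means(matrix: BetaMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group x domain mean beta plus two-tailed t-tests between group pairs.

    Per sample, the domain value is the mean over that domain's observed
    CpGs; tests compare those per-sample values between each pair of groups
    within each domain.
    """
    domains = matrix.domains
    if domains.isna().all():
        raise ValueError("domain labels required")
    per_sample = {}
    for dom in ("distal", "proximal"):
        cols = domains[domains == dom].index
        if len(cols) == 0:
            raise ValueError(f"empty domain {dom!r}")
        per_sample[dom] = matrix.values[cols].mean(axis=1, skipna=True)
    means_rows, test_rows = [], []
    groups = matrix.sample_groups
    for g, idx in groups.groupby(groups).groups.items():
        row = {"group": g, "n": len(idx)}
        for dom in per_sample:
            row[f"{dom}_mean"] = float(per_sample[dom].loc[idx].mean())
        means_rows.append(row)
    names = list(dict.fromkeys(groups))
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            for dom in per_sample:
                xa = per_sample[dom].loc[groups[groups == a].index].dropna()
                xb = per_sample[dom].loc[groups[groups == b].index].dropna()
                t, p = stats.ttest_ind(xa, xb)
                test_rows.append({"group_a": a, "group_b": b, "domain": dom,
                                  "t": float(t), "p_value": float(p),
                                  "significant": bool(p < 0.05)})
    return pd.DataFrame(means_rows), pd.DataFrame(test_rows)


def export_heatmap(matrix: BetaMatrix, result: ClusterResult, path) -> pd.DataFrame:
    """Write heatmap data: rows in dendrogram leaf order, NA cells preserved,
    group and cluster side annotations. Returns the written frame."""
    if matrix.values.size == 0:
        raise ValueError("empty matrix")
    out = matrix.values.loc[list(result.leaf_order)].copy()
    out.insert(0, "group", matrix.sample_groups.loc[out.index])
    out.insert(1, "cluster", result.two_cluster_labels.loc[out.index])
    out.to_csv(path, sep="\t", na_rep="NA", index_label="sample")
    return out


def read_heatmap(path) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Read a heatmap export back into (values, groups, cluster labels)."""
    df = pd.read_csv(path, sep="\t", index_col="sample")
    groups = df.pop("group")
    clusters = df.pop("cluster")
    return df, groups, clusters


def linkage_to_newick(Z: np.ndarray, labels) -> str:
    """Serialise a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(Z)

    def rec(node) -> str:
        if node.is_leaf():
            return str(labels[node.id])
        left, right = rec(node.left), rec(node.right)
        ld = node.dist - node.left.dist
        rd = node.dist - node.right.dist
        return f"({left}:{ld:g},{right}:{rd:g})"

    return rec(tree) + ";"
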
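"""Clustering and functional profiling of the differential secretome.

Differentially secreted proteins are z-score-transformed per protein,
clustered by complete-linkage hierarchical agglomeration on Euclidean
distance, and the dendrogram is cut into k clusters (default 4).  Proteins
are separately ranked by mean iBAQ (a molar-abundance proxy), and each
cluster's gene list is profiled against a background with a one-sided
hypergeometric overrepresentation test with Benjamini-Hochberg adjustment —
an explicit offline test standing in for web-based annotation services.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .msio import IntensityMatrix


@dataclass
class ClusterAssignment:
    """Flat cluster labels (1..k) plus the merge history for audit."""

    labels: pd.Series  # protein -> cluster label in {1..k}
    k: int
    linkage_matrix: np.ndarray
    method: str = "complete"
    metric: str = "euclidean"
    metadata: dict = field(default_factory=dict)

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each protein row to mean 0, SD 1 (population SD).

    Raises on any zero-variance row, naming the offending protein.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples to z-score")
    vals = matrix.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        raise ValueError(f"zero-variance row(s): {list(matrix.index[flat[:5]])}")
    return pd.DataFrame((vals - mu) / sd, index=matrix.index, columns=matrix.columns)


def hierarchical_cluster(
    z: pd.DataFrame,
    k: int = 4,
    order_by: list[str] | None = None,
) -> ClusterAssignment:
    """Complete-linkage agglomeration on Euclidean distance, cut at k.

    Labels are relabelled deterministically: by descending cluster mean over
    the ``order_by`` sample columns when given (e.g. the visceral CM columns,
    so cluster 1 is the most visceral-enriched), otherwise by first
    appearance in input row order.
    """
    if k > z.shape[0]:
        raise ValueError(f"k={k} exceeds {z.shape[0]} proteins")
    lm = linkage(z.to_numpy(dtype=float), method="complete", metric="euclidean")
    raw = fcluster(lm, t=k, criterion="maxclust")
    if order_by is not None:
        means = {
            c: z.loc[raw == c, order_by].to_numpy().mean() for c in np.unique(raw)
        }
        ordered = sorted(means, key=lambda c: -means[c])
    else:
        seen: list[int] = []
        for c in raw:
            if c not in seen:
                seen.append(c)
        ordered = seen
    remap = {old: new + 1 for new, old in enumerate(ordered)}
    labels = pd.Series([remap[c] for c in raw], index=z.index, name="cluster")
    return ClusterAssignment(
        labels=labels, k=int(labels.max()), linkage_matrix=lm,
        metadata={"order_by": list(order_by) if order_by else "input order"},
    )


def rank_by_abundance(m: IntensityMatrix, assignment: ClusterAssignment | None = None) -> pd.DataFrame:
    """Proteins in decreasing order of mean iBAQ, carrying cluster labels.

    The sort is stable: equal mean iBAQ keeps input order.
    """
    mean_ibaq = m.ibaq.mean(axis=1)
    out = pd.DataFrame({"mean_ibaq": mean_ibaq, "gene": m.gene_symbols})
    if assignment is not None:
        out["cluster"] = assignment.labels.reindex(out.index)
    out = out.sort_values("mean_ibaq", ascending=False, kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def overrepresentation(
    cluster_genes,
    background_genes,
    term_map: dict[str, set[str]],
    top_n: int | None = None,
) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation of terms in a cluster.

    For a term with ``n`` background genes and overlap ``x`` with the
    ``N``-gene cluster drawn from an ``M``-gene background, the p-value is
    P(X >= x) under Hypergeometric(M, n, N).  BH adjustment is applied
    across all terms; rows are sorted by p (ties by term name).
    """
    cluster = set(cluster_genes)
    background = set(background_genes)
    stray = cluster - background
    if stray:
        raise ValueError(f"cluster genes absent from background: {sorted(stray)[:5]}")
    M, N = len(background), len(cluster)
    rows = []
    for term, genes in term_map.items():
        term_bg = set(genes) & background
        n = len(term_bg)
        x = len(term_bg & cluster)
        p = float(hypergeom.sf(x - 1, M, n, N)) if n else 1.0
        rows.append((term, x, n, p))
    out = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p"])
    out = out.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    if len(out):
        out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    else:
        out["p_adj"] = []
    return out.head(top_n) if top_n else out


def cluster_table(
    m: IntensityMatrix, assignment: ClusterAssignment
) -> pd.DataFrame:
    """Tidy per-protein export: cluster, mean iBAQ, abundance rank."""
    ranked = rank_by_abundance(m, assignment)
    return ranked.loc[:, ["gene", "cluster", "mean_ibaq", "rank"]]
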
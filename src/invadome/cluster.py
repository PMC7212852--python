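"""Hierarchical clustering with bootstrap branch support.

Sample dendrograms and protein clustermaps use Euclidean distance with the
Ward-D2 criterion (scipy's ``ward``, equivalent to R hclust's ``ward.D2``
on Euclidean distances).  Branch confidence is estimated by resampling
features with replacement: the bootstrap probability (BP) of an internal
node is the percentage of resampled dendrograms that reproduce exactly the
same member set.  An approximately-unbiased (AU) estimate via multiscale
bootstrap (resample sizes from 0.5x to 1.4x the feature count, followed by
a normal-quantile regression) is available but experimental and off by
default — BP is the load-bearing statistic here.

Matrices must be complete; impute first.  Merge ties are broken by scipy's
deterministic lowest-index rule, so results are reproducible under a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy


@dataclass
class Dendrogram:
    """Agglomerative merge tree over labelled items.

    Attributes
    ----------
    linkage:
        scipy linkage matrix (n-1 x 4).
    labels:
        Item labels in input order.
    bp_support, au_support:
        Optional per-internal-node support, keyed by the node's member
        set (frozenset of labels); percentages in [0, 100].
    """

    linkage: np.ndarray
    labels: list[str]
    bp_support: dict[frozenset, float] = field(default_factory=dict)
    au_support: dict[frozenset, float] = field(default_factory=dict)

    def member_sets(self) -> list[frozenset]:
        """Member set of every internal node, in merge order."""
        n = len(self.labels)
        members: dict[int, frozenset] = {
            i: frozenset([self.labels[i]]) for i in range(n)
        }
        out = []
        for k, (left, right, _h, _c) in enumerate(self.linkage):
            merged = members[int(left)] | members[int(right)]
            members[n + k] = merged
            out.append(merged)
        return out

    def heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def cut(self, k: int) -> pd.Series:
        """Flat clustering into k groups."""
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(flat, index=self.labels, name="cluster")

    def to_newick(self, support: str | None = "bp") -> str:
        """Newick serialization; internal node labels carry support values."""
        n = len(self.labels)
        members: dict[int, frozenset] = {
            i: frozenset([self.labels[i]]) for i in range(n)
        }
        for k, (left, right, _h, _c) in enumerate(self.linkage):
            members[n + k] = members[int(left)] | members[int(right)]
        heights = {i: 0.0 for i in range(n)}
        for k, row in enumerate(self.linkage):
            heights[n + k] = float(row[2])

        def render(node: int) -> str:
            if node < n:
                return self.labels[node]
            row = self.linkage[node - n]
            left, right = int(row[0]), int(row[1])
            bl = heights[node] - heights[left]
            br = heights[node] - heights[right]
            label = ""
            if support == "bp" and members[node] in self.bp_support:
                label = f"{self.bp_support[members[node]]:.0f}"
            elif support == "au" and members[node] in self.au_support:
                label = f"{self.au_support[members[node]]:.0f}"
            return f"({render(left)}:{bl:.6g},{render(right)}:{br:.6g}){label}"

        return render(2 * n - 2) + ";"


def hierarchical_cluster(
    matrix: pd.DataFrame | np.ndarray, labels: list[str] | None = None
) -> Dendrogram:
    """Ward-D2 / Euclidean agglomerative clustering of the rows.

    Raises if the matrix contains missing values (impute first) or has
    fewer than two rows.
    """
    if isinstance(matrix, pd.DataFrame):
        if labels is None:
            labels = [str(i) for i in matrix.index]
        matrix = matrix.to_numpy(dtype=float)
    else:
        matrix = np.asarray(matrix, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(matrix.shape[0])]
    if matrix.shape[0] < 2:
        raise ValueError("need at least two items to cluster")
    if np.isnan(matrix).any():
        raise ValueError("matrix contains missing values; run impute_missing first")
    Z = hierarchy.linkage(matrix, method="ward", metric="euclidean")
    return Dendrogram(Z, list(labels))


def bootstrap_support(
    matrix: pd.DataFrame | np.ndarray,
    n_boot: int = 200,
    seed: int = 0,
    labels: list[str] | None = None,
    with_au: bool = False,
    au_scales: np.ndarray | None = None,
) -> Dendrogram:
    """Attach bootstrap probabilities to the Ward dendrogram of the rows.

    Features (columns) are resampled with replacement ``n_boot`` times;
    each original internal node's BP is the percentage of resampled trees
    containing exactly the same member set.  With ``with_au=True`` the
    multiscale bootstrap adds AU estimates.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if isinstance(matrix, pd.DataFrame):
        if labels is None:
            labels = [str(i) for i in matrix.index]
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
    dend = hierarchical_cluster(X, labels)
    nodes = dend.member_sets()
    m = X.shape[1]
    if m < 2:
        raise ValueError("need at least two features to bootstrap")
    rng = np.random.default_rng(seed)

    def bp_at_scale(n_features: int, n_rep: int) -> dict[frozenset, int]:
        counts = {node: 0 for node in nodes}
        for _ in range(n_rep):
            idx = rng.integers(0, m, size=n_features)
            boot = hierarchical_cluster(X[:, idx], dend.labels)
            seen = set(boot.member_sets())
            for node in nodes:
                if node in seen:
                    counts[node] += 1
        return counts

    counts = bp_at_scale(m, n_boot)
    dend.bp_support = {node: 100.0 * c / n_boot for node, c in counts.items()}

    if with_au:
        scales = (
            np.linspace(0.5, 1.4, 10) if au_scales is None else np.asarray(au_scales)
        )
        # multiscale bootstrap: fit qnorm(1 - bp_s) = v*sqrt(s) + c/sqrt(s),
        # AU = 1 - Phi(v - c)
        per_scale: list[dict[frozenset, int]] = []
        sizes = [max(2, int(round(r * m))) for r in scales]
        for size in sizes:
            per_scale.append(bp_at_scale(size, n_boot))
        eff = np.array([s / m for s in sizes])
        design = np.column_stack([np.sqrt(eff), 1.0 / np.sqrt(eff)])
        au = {}
        for node in nodes:
            counts_node = np.array([c[node] for c in per_scale])
            # saturated BP leaves the regression degenerate: report the limit
            if (counts_node == n_boot).all():
                au[node] = 100.0
                continue
            if (counts_node == 0).all():
                au[node] = 0.0
                continue
            bp = np.clip(counts_node / n_boot, 0.5 / n_boot, 1 - 0.5 / n_boot)
            z = stats.norm.ppf(1 - bp)
            coef, *_ = np.linalg.lstsq(design, z, rcond=None)
            v, c = coef
            au[node] = float(100.0 * (1 - stats.norm.cdf(v - c)))
        dend.au_support = au
    return dend


def clustermap_export(
    flagged_de: pd.DataFrame,
    table,
    log_transform: bool = True,
    z_score_rows: bool = True,
) -> dict:
    """Numeric clustermap of the clustermap-tier hit proteins.

    Selects ``clustermap_hit`` proteins from the (imputed, complete)
    quantification table, log2-transforms, z-scores each protein row, and
    clusters both rows and columns with Ward-D2/Euclidean.  Returns a dict
    with the standardized matrix and both dendrograms; empty (with a
    ``warning`` key) when there are no hits.
    """
    hit_ids = flagged_de.loc[flagged_de["clustermap_hit"], "protein_id"]
    hit_ids = [pid for pid in hit_ids if pid in table.meta.index]
    if not hit_ids:
        return {"matrix": pd.DataFrame(), "warning": "no clustermap hits"}
    vals = table.values.loc[hit_ids]
    if vals.isna().to_numpy().any():
        raise ValueError("clustermap input contains missing values; impute first")
    mat = np.log2(vals.to_numpy()) if log_transform else vals.to_numpy().copy()
    if z_score_rows:
        mu = mat.mean(axis=1, keepdims=True)
        sd = mat.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        mat = (mat - mu) / sd
    frame = pd.DataFrame(mat, index=hit_ids, columns=vals.columns)
    row_dend = hierarchical_cluster(frame)
    col_dend = hierarchical_cluster(frame.T)
    return {"matrix": frame, "row_dendrogram": row_dend, "col_dendrogram": col_dend}
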
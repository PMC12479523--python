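"""Hierarchical clustering of similarity matrices and report artifacts.

Drugs (and optionally features) are grouped by agglomerative
complete-linkage clustering on Euclidean distances between their
``-log10(Q)`` profiles — the values as plotted in the similarity heatmap,
so the dendrogram reflects exactly what the figure shows. The linkage is
implemented here with an explicit deterministic tie-break (ties merge the
pair with the lexicographically smallest pair of leaf indices); merge
heights are identical to standard complete linkage.

Also provides the per-drug up-vs-down scatter data and the ranked mimic
tables that accompany the heatmaps, plus thin matplotlib rendering. All
plotted numbers are serialized to TSV first so every figure is regenerable
and testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .core import PharmacobiomeError

logger = logging.getLogger("pharmacobiome")


@dataclass
class DendrogramSpec:
    """A complete-linkage dendrogram over named items.

    ``merge_list`` follows the scipy linkage convention: row ``t`` merges
    clusters ``merge_list[t, 0]`` and ``merge_list[t, 1]`` (leaves are
    ``0..n-1``, the cluster formed at step ``t`` is ``n + t``) at height
    ``merge_list[t, 2]`` into a cluster of size ``merge_list[t, 3]``.
    """

    item_ids: list[str]
    merge_list: np.ndarray
    leaf_order: list[int]
    linkage_method: str = "complete"
    metric: str = "euclidean"

    @property
    def heights(self) -> np.ndarray:
        return self.merge_list[:, 2]

    def cut(self, k: int) -> np.ndarray:
        """Labels of the k-cluster partition (scipy maxclust criterion)."""
        return hierarchy.fcluster(self.merge_list, t=k, criterion="maxclust")

    def to_newick(self) -> str:
        """Newick serialization with branch lengths from merge heights."""
        n = len(self.item_ids)

        def node(idx: int, parent_h: float) -> str:
            if idx < n:
                return f"{self.item_ids[idx]}:{parent_h:.6g}"
            row = self.merge_list[idx - n]
            h = row[2]
            left = node(int(row[0]), h)
            right = node(int(row[1]), h)
            return f"({left},{right}):{max(parent_h - h, 0.0):.6g}"

        if n == 1:
            return f"{self.item_ids[0]};"
        root_h = float(self.merge_list[-1, 2])
        return node(n + len(self.merge_list) - 1, root_h) + ";"


def cluster_items(matrix: pd.DataFrame, axis: str = "columns") -> DendrogramSpec:
    """Complete-linkage Euclidean clustering of a similarity matrix's axis.

    ``axis="columns"`` clusters drugs by their per-feature -log10(Q)
    profiles (the grouping reported for compounds); ``axis="rows"`` clusters
    features. A single item yields a trivial dendrogram with a warning.
    """
    if axis == "columns":
        X = matrix.to_numpy(dtype=float).T
        ids = [str(c) for c in matrix.columns]
    elif axis == "rows":
        X = matrix.to_numpy(dtype=float)
        ids = [str(r) for r in matrix.index]
    else:
        raise ValueError("axis must be 'rows' or 'columns'")
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix entries must be finite")
    n = len(ids)
    if n < 2:
        logger.warning("cluster_items: single item on axis %s; trivial dendrogram", axis)
        return DendrogramSpec(ids, np.empty((0, 4)), [0])
    Z = complete_linkage(squareform(pdist(X, metric="euclidean")))
    leaf_order = hierarchy.leaves_list(Z).tolist()
    return DendrogramSpec(ids, Z, leaf_order)


def complete_linkage(D: np.ndarray) -> np.ndarray:
    """Agglomerative complete linkage from a square distance matrix.

    Returns a scipy-format linkage matrix. Among tied minimum-distance
    cluster pairs, the pair whose (smallest-leaf-index, smallest-leaf-index)
    tuple is lexicographically lowest merges first, making the merge order
    fully deterministic.
    """
    D = np.asarray(D, dtype=float).copy()
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("D must be square")
    # active cluster id -> (representative = min leaf index, size)
    active: dict[int, tuple[int, int]] = {i: (i, 1) for i in range(n)}
    # distances kept in a dict keyed by frozenset of cluster ids
    dist: dict[frozenset, float] = {
        frozenset((i, j)): D[i, j] for i in range(n) for j in range(i + 1, n)
    }
    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best_key = None
        best = (np.inf, np.inf, np.inf)
        for key, d in dist.items():
            a, b = sorted(key, key=lambda c: active[c][0])
            cand = (d, active[a][0], active[b][0])
            if cand < best:
                best = cand
                best_key = key
        assert best_key is not None
        a, b = sorted(best_key)
        d_ab = dist.pop(best_key)
        size = active[a][1] + active[b][1]
        rep = min(active[a][0], active[b][0])
        Z[step] = [a, b, d_ab, size]
        others = [c for c in active if c not in (a, b)]
        for c in others:
            d_new = max(dist.pop(frozenset((a, c))), dist.pop(frozenset((b, c))))
            dist[frozenset((next_id, c))] = d_new
        del active[a], active[b]
        active[next_id] = (rep, size)
        next_id += 1
    return Z


# ---------------------------------------------------------------------------
# Scatter and ranking artifacts
# ---------------------------------------------------------------------------

def drug_scatter_data(
    results: pd.DataFrame, drug_id: str, alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature (up, down) -log10(Q) coordinates for one drug.

    One point per feature: x is the up-direction -log10(Q), y the
    down-direction one. Features significant (q <= alpha) in either
    direction are flagged for labeling.
    """
    sub = results[results["drug_id"] == drug_id]
    if sub.empty:
        raise KeyError(f"drug {drug_id!r} not present in results")
    up = sub[sub["direction"] == "up"].set_index("feature_id")
    down = sub[sub["direction"] == "down"].set_index("feature_id")
    feats = list(dict.fromkeys(sub["feature_id"]))
    out = pd.DataFrame(
        {
            "feature_id": feats,
            "x_up": [float(up["neg_log10_q"].get(f, 0.0)) for f in feats],
            "y_down": [float(down["neg_log10_q"].get(f, 0.0)) for f in feats],
            "significant": [
                bool(
                    (f in up.index and up.loc[f, "q_adj"] <= alpha)
                    or (f in down.index and down.loc[f, "q_adj"] <= alpha)
                )
                for f in feats
            ],
        }
    )
    return out


def rank_mimics(
    results: pd.DataFrame, mode: str = "by_drug", alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank mimicry comparisons by strength of evidence.

    Within each group (each drug for ``by_drug``, each feature for
    ``by_feature``, everything at once for ``global``), rows sort by
    ascending adjusted q, then descending odds ratio (an undefined 0/0 odds
    ratio sorts last), then lexicographic identifiers. Rows at q <= alpha
    are flagged significant.
    """
    group_col = {"by_drug": "drug_id", "by_feature": "feature_id", "global": None}
    if mode not in group_col:
        raise ValueError(f"unknown mode {mode!r}")
    tbl = results.copy()
    tbl["_or_key"] = -tbl["odds_ratio"].fillna(-np.inf)
    sort_cols = ["q_adj", "_or_key", "feature_id", "drug_id", "direction"]
    gc = group_col[mode]
    if gc is None:
        tbl = tbl.sort_values(sort_cols, kind="stable")
        tbl["rank"] = np.arange(1, len(tbl) + 1)
    else:
        tbl = tbl.sort_values([gc, *sort_cols], kind="stable")
        tbl["rank"] = tbl.groupby(gc, sort=False).cumcount() + 1
    tbl["significant"] = tbl["q_adj"] <= alpha
    return tbl.drop(columns="_or_key").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Rendering (thin, replaceable)
# ---------------------------------------------------------------------------

def render_heatmap(
    matrix: pd.DataFrame,
    out_path: str,
    row_spec: DendrogramSpec | None = None,
    col_spec: DendrogramSpec | None = None,
    title: str = "",
) -> None:
    """Render a (optionally dendrogram-ordered) -log10(Q) heatmap to file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    mat = matrix
    if row_spec is not None:
        mat = mat.iloc[row_spec.leaf_order, :]
    if col_spec is not None:
        mat = mat.iloc[:, col_spec.leaf_order]
    h = max(3.0, 0.18 * mat.shape[0] + 1.5)
    w = max(4.0, 0.25 * mat.shape[1] + 2.0)
    fig, ax = plt.subplots(figsize=(w, h))
    sns.heatmap(mat, cmap="viridis", ax=ax,
                cbar_kws={"label": "-log10(Q)"})
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def render_scatter(points: pd.DataFrame, out_path: str, alpha: float = 0.05,
                   title: str = "") -> None:
    """Render a per-drug up-vs-down -log10(Q) scatter to file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref = -np.log10(alpha)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(points["x_up"], points["y_down"],
               c=np.where(points["significant"], "tab:red", "tab:gray"), s=18)
    ax.axvline(ref, ls="--", lw=0.8, c="k")
    ax.axhline(ref, ls="--", lw=0.8, c="k")
    for _, row in points[points["significant"]].iterrows():
        ax.annotate(row["feature_id"], (row["x_up"], row["y_down"]), fontsize=7)
    ax.set_xlabel("up-signature similarity, -log10(Q)")
    ax.set_ylabel("down-signature similarity, -log10(Q)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
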
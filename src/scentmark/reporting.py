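"""UPGMA-clustered heatmaps, dendrogram sorting, and the tag-adjacency count.

The figures of a nest-mark analysis arrange compounds in rows and odor
samples in columns of a heatmap of normalized, clr-transformed peak areas,
with unweighted-pair-group (UPGMA) clustering of both axes and deterministic
dendrogram sorting (smallest subtree first).  The tag-adjacency count — how
many nests have their two sequential mark sleeves on adjacent leaves of the
sample dendrogram — summarizes how faithfully tags map to individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform


class ReportingError(ValueError):
    pass


@dataclass
class ClusterResult:
    """UPGMA clustering of one axis.

    ``linkage`` is a SciPy linkage matrix; ``leaf_order`` indexes into
    ``labels``; ``merge_heights`` are non-decreasing (UPGMA ultrametric).
    """

    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[int]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]


def upgma_cluster(distance: pd.DataFrame) -> ClusterResult:
    """Average-linkage (UPGMA) agglomeration of a distance matrix.

    The input must be symmetric with a zero diagonal.  Merge heights are
    the average pairwise distance between the merged clusters and are
    non-decreasing; SciPy's deterministic merge order makes the result
    reproducible for identical input.
    """
    D = distance.to_numpy(dtype=float) if isinstance(distance, pd.DataFrame) \
        else np.asarray(distance, dtype=float)
    labels = (list(map(str, distance.index))
              if isinstance(distance, pd.DataFrame)
              else [str(i) for i in range(D.shape[0])])
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ReportingError(f"distance matrix must be square, got {D.shape}")
    if not np.allclose(D, D.T, rtol=1e-10, atol=1e-12):
        raise ReportingError("distance matrix is not symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ReportingError("distance matrix diagonal is not zero")
    if (D < 0).any():
        raise ReportingError("distance matrix has negative entries")
    if D.shape[0] < 2:
        raise ReportingError("need at least 2 items to cluster")
    Z = linkage(squareform(D, checks=False), method="average")
    order = leaves_list(Z).tolist()
    return ClusterResult(linkage=Z, labels=labels, leaf_order=order)


def _subtree_stats(Z: np.ndarray, n: int):
    """For every node id, the minimum merge height and smallest leaf index
    of its subtree (leaves have height 0)."""
    total = n + len(Z)
    min_height = np.zeros(total)
    min_leaf = np.arange(total)
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        node = n + k
        child_heights = [h]
        for c in (a, b):
            if c >= n:
                child_heights.append(min_height[c])
        min_height[node] = min(child_heights)
        min_leaf[node] = min(min_leaf[a], min_leaf[b])
    return min_height, min_leaf


def sort_dendrogram(cluster: ClusterResult) -> ClusterResult:
    """Reorder leaves so the subtree with the smaller minimum merge height
    comes first at every internal node (dendsort smallest-first convention;
    ties broken by smallest leaf index).  Topology and heights are
    untouched — only ``leaf_order`` changes."""
    Z = cluster.linkage
    n = len(cluster.labels)
    min_height, min_leaf = _subtree_stats(Z, n)

    def key(node: int):
        h = 0.0 if node < n else min_height[node]
        return (h, int(min_leaf[node]))

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
        first, second = sorted((a, b), key=key)
        return leaves(first) + leaves(second)

    import sys
    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 4 * (n + len(Z)) + 100))
    try:
        order = leaves(n + len(Z) - 1) if len(Z) else [0]
    finally:
        sys.setrecursionlimit(old_limit)
    return replace(cluster, leaf_order=order)


def tag_adjacency(cluster: ClusterResult, meta: pd.DataFrame) -> int:
    """Count nests whose mark sleeves occupy adjacent leaves.

    ``cluster`` must be a clustering of mark samples; ``meta`` maps each
    sample to its nest.  A nest counts when all of its tags form one
    contiguous block in the leaf order (for the standard design: its two
    sleeves side by side).
    """
    ordered = cluster.ordered_labels
    position = {s: i for i, s in enumerate(ordered)}
    count = 0
    for nest, group in meta.loc[meta.index.isin(ordered)].groupby("nest_id"):
        pos = sorted(position[s] for s in group.index)
        if len(pos) >= 1 and pos[-1] - pos[0] == len(pos) - 1:
            count += 1
    return count


def write_leaf_orders(path, row_cluster: ClusterResult | None,
                      col_cluster: ClusterResult | None) -> Path:
    """Write leaf orders as a two-column TSV (axis, label)."""
    path = Path(path)
    lines = ["axis\tlabel"]
    if row_cluster is not None:
        lines += [f"row\t{lab}" for lab in row_cluster.ordered_labels]
    if col_cluster is not None:
        lines += [f"col\t{lab}" for lab in col_cluster.ordered_labels]
    path.write_text("\n".join(lines) + "\n")
    return path


def render_heatmap(matrix: pd.DataFrame, row_cluster: ClusterResult,
                   col_cluster: ClusterResult, class_colors: dict | None,
                   path, row_classes: pd.Series | None = None,
                   col_classes: pd.Series | None = None,
                   leaf_order_path=None) -> Path:
    """Render the clustered heatmap to ``path`` (PNG/SVG by extension).

    Rows and columns are reordered by the cluster leaf orders; optional
    ``row_classes`` / ``col_classes`` (label → class) are shown as colored
    side bars using ``class_colors``.  Leaf orders are additionally written
    as TSV (``leaf_order_path`` or ``<path>.leaforder.tsv``) so the figure
    content is testable without pixel comparison.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    row_labels = row_cluster.ordered_labels
    col_labels = col_cluster.ordered_labels
    data = matrix.loc[row_labels, col_labels]

    fig_w = max(4.0, 0.22 * len(col_labels) + 2.5)
    fig_h = max(3.0, 0.18 * len(row_labels) + 2.0)
    fig, ax = plt.subplots(figsize=(fig_w, fig_h))
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="RdYlBu_r",
                   interpolation="nearest")
    ax.set_xticks(range(len(col_labels)))
    ax.set_xticklabels(col_labels, rotation=90, fontsize=5)
    ax.set_yticks(range(len(row_labels)))
    ax.set_yticklabels(row_labels, fontsize=5)
    fig.colorbar(im, ax=ax, shrink=0.6, label="clr(normalized area)")

    class_colors = class_colors or {}

    def _tick_colors(labels, classes, axis_ticks):
        if classes is None:
            return
        for tick, lab in zip(axis_ticks, labels):
            color = class_colors.get(classes.get(lab))
            if color:
                tick.set_color(color)

    _tick_colors(row_labels,
                 None if row_classes is None else row_classes.to_dict(),
                 ax.get_yticklabels())
    _tick_colors(col_labels,
                 None if col_classes is None else col_classes.to_dict(),
                 ax.get_xticklabels())

    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150, metadata=_stable_metadata(path.suffix))
    plt.close(fig)

    tsv = Path(leaf_order_path) if leaf_order_path else \
        path.with_suffix(path.suffix + ".leaforder.tsv")
    write_leaf_orders(tsv, row_cluster, col_cluster)
    return path


def _stable_metadata(suffix: str) -> dict | None:
    # keep output bytes independent of wall-clock time
    if suffix == ".png":
        return {"Software": "scentmark"}
    if suffix == ".svg":
        return {"Date": None}
    return None
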
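"""Hierarchical clustering of immune profiles and group-segregation scoring.

Default preprocessing follows common heatmap practice for positive-valued
fluorescence panels: log-transform, z-score per analyte, Euclidean distance,
average linkage.  Every result embeds the preprocessing descriptor so a
figure can be reproduced from the result alone.  The segregation score
quantifies the "one group clusters away from the rest" statement: the sample
dendrogram is cut into two clusters and the score is the fraction of samples
on the correct side of that cut for a target group.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .preprocess import NormalizedMatrix

__all__ = ["ClusterResult", "hier_cluster", "segregation_score"]

logger = logging.getLogger(__name__)


@dataclass
class ClusterResult:
    """Linkage tree with leaf labels and the preprocessing descriptor."""

    linkage: np.ndarray
    labels: list[str]
    axis: str  # "samples" or "analytes"
    descriptor: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.linkage.shape != (len(self.labels) - 1, 4):
            raise ValueError("linkage must have (n_leaves - 1) merges")

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, k: int = 2) -> pd.Series:
        """Flat cluster assignment for a k-cluster cut, indexed by label."""
        assign = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(assign, index=self.labels, name="cluster")

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage, columns=["child_a", "child_b", "height", "size"]
        )

    def to_newick(self) -> str:
        """Newick rendering of the dendrogram with merge heights as lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def render(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return render(tree, tree.dist) + ";"

    def plot(self, ax=None, **kwargs):
        """Dendrogram rendering (matplotlib); cosmetic only."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        hierarchy.dendrogram(self.linkage, labels=self.labels, ax=ax, **kwargs)
        ax.set_ylabel("merge height")
        return ax


def _preprocess(
    values: pd.DataFrame, log_transform: bool, zscore: bool
) -> pd.DataFrame:
    X = values.astype(float)
    if log_transform:
        X = np.log(X)
    if zscore:
        sd = X.std(axis=0, ddof=0)
        constant = sd[sd == 0].index.tolist()
        if constant:
            msg = f"dropping constant analytes under z-scoring: {constant}"
            logger.warning("hier_cluster: %s", msg)
            warnings.warn(msg, RuntimeWarning, stacklevel=3)
            X = X.drop(columns=constant)
            sd = sd.drop(index=constant)
        X = (X - X.mean(axis=0)) / sd
    return X


def hier_cluster(
    matrix: NormalizedMatrix | pd.DataFrame,
    axis: str = "samples",
    log_transform: bool = True,
    zscore: bool = True,
    metric: str = "euclidean",
    method: str = "average",
) -> ClusterResult:
    """Hierarchical clustering of samples or analytes.

    The matrix is log-transformed and z-scored per analyte (defaults), then
    the requested axis is clustered with the given distance metric and
    linkage.  Constant analytes cannot be z-scored and are dropped with a
    warning.  The result is deterministic given matrix and settings, and
    invariant to the input row order up to tree isomorphism.
    """
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    if axis not in ("samples", "analytes"):
        raise ValueError("axis must be 'samples' or 'analytes'")
    X = _preprocess(values, log_transform, zscore)
    if axis == "analytes":
        X = X.T
    if len(X) < 2:
        raise ValueError(f"need at least 2 items on the {axis} axis")

    Z = hierarchy.linkage(X.to_numpy(), method=method, metric=metric)
    descriptor = {
        "axis": axis,
        "log_transform": log_transform,
        "zscore": zscore,
        "metric": metric,
        "method": method,
        "n_items": len(X),
        "n_features": X.shape[1],
    }
    return ClusterResult(
        linkage=Z, labels=[str(i) for i in X.index], axis=axis,
        descriptor=descriptor,
    )


def segregation_score(
    result: ClusterResult,
    labels: Mapping[str, str] | pd.Series,
    target: str,
) -> float:
    """Two-cluster segregation of a target group, in [0, 1].

    The tree is cut into two clusters; the score is the number of
    target-group samples in the cluster holding the majority of them, plus
    the number of non-target samples in the other cluster, divided by the
    total.  1.0 means the cut separates the target group perfectly.  If all
    samples belong to the target group the score is 1.0 by convention; a tie
    in the majority is resolved in favour of the higher score.
    """
    if result.axis != "samples":
        raise ValueError("segregation_score requires a sample-axis clustering")
    if len(result.labels) < 2:
        raise ValueError("need at least 2 samples")
    lab = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
    missing = [s for s in result.labels if s not in lab.index]
    if missing:
        raise ValueError(f"labels missing for samples {missing}")
    is_target = np.array([lab[s] == target for s in result.labels])
    if is_target.all():
        return 1.0

    assign = result.cut(2).to_numpy()
    n = len(assign)
    t1 = int(np.sum(is_target & (assign == 1)))
    t2 = int(np.sum(is_target & (assign == 2)))

    def score_for(side: int) -> float:
        in_side = assign == side
        return float((np.sum(is_target & in_side) + np.sum(~is_target & ~in_side)) / n)

    if t1 > t2:
        return score_for(1)
    if t2 > t1:
        return score_for(2)
    return max(score_for(1), score_for(2))
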
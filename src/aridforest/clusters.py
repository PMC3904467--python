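"""Ward clustering of communes by forest area and absolute forest change.

Each commune (territorial-administrative unit) carries two indicators:
total forest area (ha) and the signed absolute change of forest area
(ha) over the study interval. Communes are grouped by agglomerative
Ward clustering on the Euclidean distance — at every step the pair of
clusters whose merge least increases total within-cluster variance is
joined — and the tree is cut at k groups (k = 5 by default, matching
the five-class typology the indicators support: stable small/large
forests, expanding, and small/large declining forests).

Both indicators are in hectares but on very different scales, so they
are z-score standardized before distances by default; pass
``standardize=False`` to cluster on raw hectares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = ["ClusterAssignment", "ward_cluster", "cluster_profile"]

INDICATORS = ["forest_total", "forest_change"]


@dataclass
class ClusterAssignment:
    labels: pd.Series            # commune id → 1..k
    linkage: np.ndarray          # scipy linkage matrix (merge heights in col 2)
    k: int
    standardized: bool

    def __post_init__(self) -> None:
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("Ward merge heights must be non-decreasing")


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ["commune", *INDICATORS] if c not in table.columns]
    if missing:
        raise ValueError(f"commune table lacks columns: {missing}")
    if table["commune"].duplicated().any():
        raise ValueError("duplicate commune ids")
    if table[INDICATORS].isna().any(axis=None):
        raise ValueError("both indicators must be present for every commune")
    if (table["forest_total"] < 0).any():
        raise ValueError("negative forest area")
    return table


def ward_cluster(table: pd.DataFrame, k: int = 5, standardize: bool = True) -> ClusterAssignment:
    """Cut a Ward/Euclidean dendrogram of the communes at k clusters.

    Clusters are relabelled 1..k in order of appearance down the sorted
    commune list, so the labelling is deterministic and invariant to
    input row order.
    """
    table = _validate(table).sort_values("commune").reset_index(drop=True)
    n = len(table)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}")
    x = table[INDICATORS].to_numpy(dtype=float)
    if standardize:
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    link = hierarchy.linkage(pdist(x, metric="euclidean"), method="ward")
    raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
    # relabel in first-appearance order for determinism
    remap: dict[int, int] = {}
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    labels = pd.Series([remap[lab] for lab in raw], index=table["commune"], name="cluster")
    return ClusterAssignment(labels=labels, linkage=link, k=k, standardized=standardize)


def cluster_profile(assignment: ClusterAssignment, table: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster summary: size, indicator stats, share of total forest."""
    table = _validate(table)
    joined = table.set_index("commune").join(assignment.labels, how="inner")
    if len(joined) != len(table):
        raise ValueError("assignment does not cover the table's communes")
    grand_forest = joined["forest_total"].sum()
    rows = []
    for cluster, sub in joined.groupby("cluster", sort=True):
        row = {"cluster": cluster, "n": len(sub)}
        for ind in INDICATORS:
            row[f"{ind}_mean"] = sub[ind].mean()
            row[f"{ind}_min"] = sub[ind].min()
            row[f"{ind}_max"] = sub[ind].max()
        row["forest_share_pct"] = (
            100.0 * sub["forest_total"].sum() / grand_forest if grand_forest > 0 else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)
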
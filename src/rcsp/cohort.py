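"""Patient stratification on RCS scores and preranked exports.

Patients are clustered on their per-sample Phi rows with Ward's method on
Euclidean distances; the within-cluster sum of squares (WSS) curve over a
range of k supports elbow-style selection of the number of clusters.
Per-cluster D-RCS tables and two-column .rnk files (gene, score) feed
preranked gene-set enrichment tools downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .rcs import deviation

__all__ = ["ClusterResult", "ward_cluster", "elbow_suggest", "cluster_deviation", "export_rank", "read_rank"]


@dataclass
class ClusterResult:
    assignments: np.ndarray  # per-sample cluster id in [0, k_selected)
    linkage: np.ndarray  # scipy linkage matrix
    wss_curve: pd.Series  # WSS per k
    k_selected: int


def _wss(phi: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for c in np.unique(labels):
        rows = phi[labels == c]
        total += float(np.sum((rows - rows.mean(axis=0)) ** 2))
    return total


def ward_cluster(
    phi: np.ndarray, k_range: range | list[int] = range(1, 11), k: int | None = None
) -> ClusterResult:
    """Agglomerative Ward clustering of per-sample Phi rows.

    ``k`` fixes the number of clusters; when omitted it is suggested from
    the WSS curve by :func:`elbow_suggest`.
    """
    phi = np.asarray(phi, dtype=float)
    if np.isnan(phi).any():
        raise ValueError("phi contains NaN")
    n = phi.shape[0]
    k_range = [int(v) for v in k_range]
    if max(k_range) > n:
        raise ValueError(f"k={max(k_range)} exceeds {n} samples")
    z = linkage(phi, method="ward")
    wss = pd.Series(
        {kk: _wss(phi, fcluster(z, kk, criterion="maxclust")) for kk in k_range},
        name="wss",
    )
    k_sel = int(k) if k is not None else elbow_suggest(wss)
    labels = fcluster(z, k_sel, criterion="maxclust") - 1
    return ClusterResult(assignments=labels, linkage=z, wss_curve=wss, k_selected=k_sel)


def elbow_suggest(wss_curve: pd.Series) -> int:
    """k at the maximum discrete second difference (curvature) of the WSS
    curve; advisory only.  A flat curve returns 1 with a warning."""
    curve = wss_curve.sort_index()
    if len(curve) < 3:
        raise ValueError("need a WSS curve over at least three k values")
    if np.allclose(curve.values, curve.values[0]):
        warnings.warn("flat WSS curve: no elbow, returning k=1")
        return 1
    ks = curve.index.to_numpy()
    vals = curve.to_numpy(dtype=float)
    second = vals[:-2] - 2 * vals[1:-1] + vals[2:]  # curvature at ks[1:-1]
    if np.all(second <= 1e-12 * max(vals[0], 1.0)):
        warnings.warn("monotone linear WSS decay: no elbow, returning k=1")
        return 1
    return int(ks[1:-1][int(np.argmax(second))])


def cluster_deviation(
    phi: np.ndarray, assignments: np.ndarray, gene_names: list[str] | None = None
) -> pd.DataFrame:
    """Per-cluster, per-gene D-RCS: the RMS of Phi within each cluster."""
    phi = np.asarray(phi, dtype=float)
    assignments = np.asarray(assignments)
    if len(assignments) != phi.shape[0]:
        raise ValueError("assignments must align with phi rows")
    if gene_names is None:
        gene_names = [f"G{i}" for i in range(phi.shape[1])]
    rows = {}
    for c in np.unique(assignments):
        sub = phi[assignments == c]
        rows[c] = [deviation(sub[:, i]) for i in range(sub.shape[1])]
    return pd.DataFrame(rows, index=gene_names).T.rename_axis("cluster")


def export_rank(scores: pd.Series | dict, path: str | Path) -> None:
    """Write a two-column preranked .rnk file (gene, score), descending by
    score with ties broken by gene identifier."""
    s = pd.Series(scores, dtype=float)
    if not np.all(np.isfinite(s.to_numpy())):
        raise ValueError("rank scores must be finite")
    frame = s.rename("score").rename_axis("gene").reset_index()
    frame = frame.sort_values(["score", "gene"], ascending=[False, True])
    with open(path, "w") as fh:
        for _, row in frame.iterrows():
            fh.write(f"{row['gene']}\t{float(row['score'])!r}\n")


def read_rank(path: str | Path) -> pd.Series:
    """Read a .rnk file back into a gene -> score series."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"], comment="#")
    return pd.Series(frame["score"].to_numpy(), index=frame["gene"], name="score")
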
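"""Cluster-based Monte-Carlo significance on binarized statistic maps.

The procedure: binarize cell-level tests (1 = significant at the cell-level
alpha), find connected clusters of 1s among the valid cells, then build a
null distribution of the *maximum* cluster size by uniformly re-placing the
observed number of 1s over the valid cells many times. A cluster is declared
significant when its size exceeds the (1 - alpha) quantile of that null —
e.g. larger than 99.9% of the permuted maxima at alpha = 0.001.

Note this permutes the binarized map itself (fixed count of 1s, uniform
placement), not subject-level labels; it is a spatial-chance correction for
the multiplicity of cells, conditional on the number of suprathreshold
cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["BinaryMap", "ClusterResult", "find_clusters", "max_cluster_null",
           "mcs_significance", "run_mcs", "cluster_table"]


@dataclass
class BinaryMap:
    """An n-dimensional {0,1} array restricted to a validity mask.

    ``valid`` marks cells that exist (layout cells holding a channel, voxels
    inside the head); 1s may only occur on valid cells. ``direction`` tags
    which contrast direction the map encodes (e.g. "A>B").
    """

    data: np.ndarray
    valid: np.ndarray | None = None
    direction: str = "A>B"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(np.uint8)
        if self.valid is None:
            self.valid = np.ones(self.data.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.data.shape:
            raise ValueError("validity mask must match map shape")
        if np.any(self.data.astype(bool) & ~self.valid):
            raise ValueError("map has 1s on invalid cells")

    @property
    def n_ones(self) -> int:
        return int(self.data.sum())

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class ClusterResult:
    """One connected cluster of significant cells."""

    members: tuple[tuple[int, ...], ...]     # cell coordinates
    size: int
    n_spatial: int                           # distinct channels/voxels
    time_span: tuple[int, int] | None       # sample indices (space-time maps)
    direction: str = "A>B"
    p_value: float | None = None
    significant: bool | None = None

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("cluster size must be >= 1")


def _structure(ndim: int) -> np.ndarray:
    # orthogonal-neighbor adjacency: 4-connectivity in 2D, 6 in 3D
    return ndimage.generate_binary_structure(ndim, 1)


def find_clusters(bmap: BinaryMap, time_axis: int | None = None) -> list[ClusterResult]:
    """Connected components of 1-cells under orthogonal-neighbor adjacency.

    For space-time maps, pass the axis indexing time: time then counts as one
    more orthogonal axis, and each cluster reports its distinct-spatial-cell
    count and time span. Clusters are ordered by decreasing size, ties broken
    by the lexicographically smallest member cell.
    """
    labels, n = ndimage.label(bmap.data.astype(bool) & bmap.valid,
                              structure=_structure(bmap.data.ndim))
    clusters = []
    for lab in range(1, n + 1):
        cells = np.argwhere(labels == lab)
        members = tuple(sorted(map(tuple, cells)))
        if time_axis is not None:
            spatial = {tuple(np.delete(c, time_axis)) for c in cells}
            tspan = (int(cells[:, time_axis].min()), int(cells[:, time_axis].max()))
        else:
            spatial = set(members)
            tspan = None
        clusters.append(ClusterResult(members, len(members), len(spatial),
                                      tspan, bmap.direction))
    clusters.sort(key=lambda c: (-c.size, c.members[0]))
    return clusters


def max_cluster_null(bmap: BinaryMap, n_perm: int = 1000,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """Permutation null of the maximum cluster size.

    Each permutation uniformly re-places the observed number of 1s among the
    valid cells (without replacement) and records the size of the largest
    connected cluster (0 when the map holds no 1s).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    k = bmap.n_ones
    valid_idx = np.argwhere(bmap.valid)
    if k > len(valid_idx):
        raise ValueError("more 1s than valid cells")
    if k == 0:
        return np.zeros(n_perm, dtype=int)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    struct = _structure(bmap.data.ndim)
    out = np.empty(n_perm, dtype=int)
    scratch = np.zeros(bmap.data.shape, dtype=bool)
    for i in range(n_perm):
        pick = rng.choice(len(valid_idx), size=k, replace=False)
        scratch[:] = False
        scratch[tuple(valid_idx[pick].T)] = True
        labels, n = ndimage.label(scratch, structure=struct)
        out[i] = np.bincount(labels.ravel())[1:].max() if n else 0
    return out


def mcs_significance(observed: Sequence[ClusterResult], null: np.ndarray,
                     alpha: float = 0.001) -> list[ClusterResult]:
    """Annotate observed clusters with Monte-Carlo p-values and significance.

    ``p = (1 + #{null >= k}) / (1 + n_perm)`` (the +1 correction avoids
    zero p-values); a cluster is significant iff its size strictly exceeds
    the empirical (1 - alpha) quantile of the null maxima — the
    "larger than 99.9% of the permuted maxima" rule at alpha = 0.001.
    """
    null = np.asarray(null)
    if null.size == 0:
        raise ValueError("null distribution must be non-empty")
    thresh = np.quantile(null, 1.0 - alpha)
    out = []
    for c in observed:
        p = (1.0 + (null >= c.size).sum()) / (1.0 + null.size)
        out.append(ClusterResult(c.members, c.size, c.n_spatial, c.time_span,
                                 c.direction, float(p), bool(c.size > thresh)))
    return out


def run_mcs(bmap: BinaryMap, n_perm: int = 1000, alpha: float = 0.001,
            seed: int | np.random.Generator = 0,
            time_axis: int | None = None) -> list[ClusterResult]:
    """Full pipeline on one map: cluster, permute, annotate."""
    clusters = find_clusters(bmap, time_axis=time_axis)
    if not clusters:
        return []
    null = max_cluster_null(bmap, n_perm=n_perm, seed=seed)
    return mcs_significance(clusters, null, alpha=alpha)


def cluster_table(clusters: Sequence[ClusterResult], sfreq: float | None = None,
                  tmin: float = 0.0, path: str | Path | None = None) -> pd.DataFrame:
    """Cluster summary table (size, distinct cells, time interval, p, direction).

    Time spans are converted from sample indices to seconds when ``sfreq``
    is given. Optionally written as TSV.
    """
    rows = []
    for i, c in enumerate(clusters, start=1):
        if c.time_span is not None and sfreq is not None:
            t0, t1 = (tmin + c.time_span[0] / sfreq, tmin + c.time_span[1] / sfreq)
            interval = f"{t0:.3f}-{t1:.3f}"
        elif c.time_span is not None:
            interval = f"{c.time_span[0]}-{c.time_span[1]}"
        else:
            interval = ""
        rows.append({"cluster_number": i, "size": c.size,
                     "n_channels_or_voxels": c.n_spatial,
                     "time_interval_s": interval,
                     "p_value": c.p_value, "significant": c.significant,
                     "direction": c.direction})
    df = pd.DataFrame(rows, columns=["cluster_number", "size", "n_channels_or_voxels",
                                     "time_interval_s", "p_value", "significant",
                                     "direction"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
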
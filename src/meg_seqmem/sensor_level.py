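"""Sensor-space statistics on combined planar gradiometers.

Per-channel, per-timepoint paired t-tests across subjects contrast the
memorized and novel condition averages; significant cells (p < 0.01,
two-sided, split by the sign of t) are embedded into the 2D sensor layout
per timepoint, and the resulting space-time binary maps are corrected with
the cluster-based Monte-Carlo procedure (alpha = 0.001, 1000 permutations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cluster_stats import BinaryMap, cluster_table, run_mcs
from .megsim import SensorArray
from .preprocess import Evoked

__all__ = ["SensorStatMap", "pointwise_paired_t", "embed_layout", "run_sensor_mcs"]

log = logging.getLogger(__name__)


@dataclass
class SensorStatMap:
    """Paired-t results per combined channel and sample."""

    t: np.ndarray                    # (n_channels, n_samples)
    p: np.ndarray
    sfreq: float
    tmin: float
    window: tuple[float, float]      # analysis window actually used, seconds
    alpha: float


def pointwise_paired_t(
    evoked_a: list[Evoked],
    evoked_b: list[Evoked],
    alpha: float = 0.01,
    window: tuple[float, float] = (0.0, 2.5),
) -> tuple[SensorStatMap, BinaryMap, BinaryMap]:
    """Paired t-test at every (channel, sample) across subjects.

    ``evoked_a`` and ``evoked_b`` are per-subject condition averages in the
    same subject order. Cells with p < alpha are binarized into two maps
    split by the sign of t (A>B and B>A). The analysis window is clipped to
    the available epoch with a logged warning if it extends beyond it.
    """
    if len(evoked_a) != len(evoked_b) or not evoked_a:
        raise ValueError("need the same subjects in both condition lists")
    n = len(evoked_a)
    if n < 2:
        raise ValueError("need at least two subjects for a paired t-test")
    if n == 2:
        log.warning("only two subjects: df = 1, very low power")
    A = np.stack([e.data for e in evoked_a])   # (n_subj, n_ch, n_samp)
    B = np.stack([e.data for e in evoked_b])
    if A.shape != B.shape:
        raise ValueError("subject evoked arrays are inconsistent")
    sfreq, tmin = evoked_a[0].sfreq, evoked_a[0].tmin
    times = tmin + np.arange(A.shape[2]) / sfreq
    lo, hi = window
    if hi > times[-1] + 0.5 / sfreq:
        log.warning("analysis window end %.3f s exceeds epoch end %.3f s; clipping",
                    hi, times[-1])
        hi = times[-1]
    sel = (times >= lo) & (times <= hi + 1e-9)
    A, B = A[:, :, sel], B[:, :, sel]

    res = stats.ttest_rel(A, B, axis=0)
    t = np.nan_to_num(np.asarray(res.statistic), nan=0.0)
    p = np.nan_to_num(np.asarray(res.pvalue), nan=1.0)
    sig = p < alpha
    stat = SensorStatMap(t, p, sfreq, float(times[sel][0]),
                         (float(times[sel][0]), float(times[sel][-1])), alpha)
    return (stat,
            BinaryMap((sig & (t > 0)).astype(np.uint8), direction="A>B"),
            BinaryMap((sig & (t < 0)).astype(np.uint8), direction="B>A"))


def embed_layout(bmap: BinaryMap, sensors: SensorArray) -> BinaryMap:
    """Lift a (channels x samples) binary map into (rows x cols x samples).

    Channel c of the combined-gradiometer data occupies layout cell
    ``sensors.layout[c]`` at every timepoint; the validity mask marks the
    occupied cells. The embedding is a bijection between channels and valid
    spatial cells, so it is lossless.
    """
    n_ch, n_samp = bmap.data.shape
    if n_ch != sensors.n_positions:
        raise ValueError("map channels must match combined sensor positions")
    rows, cols = sensors.layout[:, 0], sensors.layout[:, 1]
    if len(np.unique(rows * sensors.layout_shape[1] + cols)) != n_ch:
        raise ValueError("layout collision: two channels share a cell")
    shape = (*sensors.layout_shape, n_samp)
    data = np.zeros(shape, dtype=np.uint8)
    valid = np.zeros(shape, dtype=bool)
    data[rows, cols, :] = bmap.data
    valid[rows, cols, :] = True
    return BinaryMap(data, valid, bmap.direction)


def run_sensor_mcs(
    spacetime: BinaryMap,
    sfreq: float,
    tmin: float = 0.0,
    n_perm: int = 1000,
    alpha: float = 0.001,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Cluster-based Monte-Carlo correction on a space-time sensor map.

    Returns the cluster table (size, distinct channels, time interval in
    seconds, Monte-Carlo p, direction), ordered by decreasing size.
    """
    clusters = run_mcs(spacetime, n_perm=n_perm, alpha=alpha, seed=seed, time_axis=2)
    return cluster_table(clusters, sfreq=sfreq, tmin=tmin)
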
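"""Source-space analysis: LCMV beamformer and two-level group statistics.

The inverse model is a scalar LCMV (linearly-constrained minimum-variance)
beamformer: per dipole, the orientation maximizing output source power is
the generalized eigenvector of the 2x2 projected-precision matrix, and the
unit-gain minimum-variance spatial filter is
``w = C^-1 l / (l^T C^-1 l)`` for the oriented lead-field column ``l``.

Group inference follows a two-level mass-univariate scheme: per-subject
condition contrasts (first level), one-sample or paired t-maps across
subjects (group level), binarization at the voxel alpha, and spatial
cluster-based Monte-Carlo correction per 250-ms tone window — ten tests per
piece (five tones x two bands), hence the adjusted alpha 0.01/10 = 0.001.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .cluster_stats import BinaryMap, cluster_table, run_mcs
from .megsim import LeadField, SourceGrid
from .preprocess import EpochSet, Evoked

__all__ = [
    "TONE_WINDOWS", "BeamformerWeights", "SourceEstimate", "GroupStatMap",
    "data_covariance", "lcmv_weights", "reconstruct", "window_means",
    "first_level", "group_level", "tone_window_mcs",
    "memorized_piece_contrast", "band_contrast", "familiarity_correlation",
]

log = logging.getLogger(__name__)

#: The five tone windows (seconds): 0-250, 251-500, 501-750, 751-1000,
#: 1001-1250 ms — contiguous, non-overlapping, covering the 1250-ms excerpt.
TONE_WINDOWS: tuple[tuple[float, float], ...] = tuple(
    (k * 0.250, (k + 1) * 0.250) for k in range(5)
)


@dataclass
class BeamformerWeights:
    """Unit-gain scalar LCMV spatial filters."""

    weights: np.ndarray              # (n_dipoles, n_channels)
    orientations: np.ndarray         # (n_dipoles, 2) tangential coefficients
    lam: float                       # regularization actually added to C
    active: np.ndarray               # (n_dipoles,) False where lead field ~ 0


@dataclass
class SourceEstimate:
    """Reconstructed dipole time courses (dipoles x samples)."""

    data: np.ndarray
    sfreq: float
    tmin: float
    subject: int | None = None
    condition: str | None = None
    band: str | None = None

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[1]) / self.sfreq


@dataclass
class GroupStatMap:
    """Group t-values per dipole and timepoint (or window)."""

    t: np.ndarray                    # (n_dipoles, n_cols)
    p: np.ndarray
    contrast: str
    band: str | None
    alpha: float


def data_covariance(ep: EpochSet | np.ndarray, lam_fraction: float = 0.05) -> np.ndarray:
    """Regularized sensor covariance from concatenated epoch samples.

    ``C = sample covariance + lam * I`` with ``lam = lam_fraction x mean
    diagonal``; with lam_fraction > 0 the result is symmetric positive
    definite. With lam_fraction = 0 a PD violation on rank-deficient data is
    detected and raised.
    """
    data = ep.data if isinstance(ep, EpochSet) else np.asarray(ep)
    if data.ndim == 3:
        if data.shape[0] < 2:
            raise ValueError("need at least 2 epochs")
        X = np.concatenate(list(data), axis=1)   # channels x (trials*samples)
    else:
        X = data
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in the data")
    C = np.cov(X)
    lam = lam_fraction * float(np.trace(C)) / C.shape[0]
    C = C + lam * np.eye(C.shape[0])
    try:
        linalg.cholesky(C, lower=True)
    except linalg.LinAlgError as err:
        raise linalg.LinAlgError(
            "covariance is not positive definite (rank-deficient data with "
            "lam_fraction = 0?)") from err
    return C


def lcmv_weights(lead: LeadField, C: np.ndarray, lam: float = 0.0) -> BeamformerWeights:
    """Scalar LCMV filters with power-maximizing orientation per dipole.

    For each dipole with tangential lead-field columns L (channels x 2), the
    scalar orientation u minimizes ``u^T (L^T C^-1 L) u`` over unit u
    (equivalently maximizes minimum-variance output power); the filter is
    the unit-gain solution for l = L u, so ``w . l = 1`` exactly. Dipoles
    whose lead field vanishes (e.g. at the sphere center) are flagged
    inactive with zero weights.
    """
    Cinv = linalg.inv(C)
    n_dip = lead.n_dipoles
    W = np.zeros((n_dip, lead.n_channels))
    orient = np.zeros((n_dip, 2))
    active = np.ones(n_dip, dtype=bool)
    scale = float(np.abs(lead.matrix).max())
    for d in range(n_dip):
        L = lead.matrix[:, d, :]                 # (n_ch, 2)
        if np.abs(L).max() < 1e-12 * scale:
            active[d] = False
            continue
        CiL = Cinv @ L
        M = L.T @ CiL                            # 2x2, SPD for nonzero L
        evals, evecs = linalg.eigh(M)
        u = evecs[:, 0]                          # smallest eigenvalue -> max power
        l = L @ u
        w = (Cinv @ l) / (l @ Cinv @ l)
        W[d] = w
        orient[d] = u
    n_skip = int((~active).sum())
    if n_skip:
        log.info("skipped %d dipoles with (near-)zero lead field", n_skip)
    return BeamformerWeights(W, orient, lam, active)


def reconstruct(bf: BeamformerWeights, ev: Evoked | EpochSet | np.ndarray,
                **meta) -> SourceEstimate:
    """Apply the spatial filters to sensor data (linear per timepoint)."""
    if isinstance(ev, (Evoked,)):
        data, sfreq, tmin = ev.data, ev.sfreq, ev.tmin
        meta.setdefault("condition", ev.condition)
        meta.setdefault("band", ev.band)
    elif isinstance(ev, EpochSet):
        raise TypeError("reconstruct expects an Evoked or a 2D array; "
                        "apply per epoch explicitly if needed")
    else:
        data = np.asarray(ev)
        sfreq = meta.pop("sfreq", 1.0)
        tmin = meta.pop("tmin", 0.0)
    if data.shape[0] != bf.weights.shape[1]:
        raise ValueError("channel count mismatch between weights and data")
    return SourceEstimate(bf.weights @ data, sfreq, tmin, **meta)


def window_means(est: SourceEstimate | np.ndarray, sfreq: float | None = None,
                 tmin: float | None = None,
                 windows: tuple[tuple[float, float], ...] = TONE_WINDOWS) -> np.ndarray:
    """Mean source activity within each tone window: (dipoles, n_windows)."""
    if isinstance(est, SourceEstimate):
        data, sfreq, tmin = est.data, est.sfreq, est.tmin
    else:
        data = np.asarray(est)
        if sfreq is None or tmin is None:
            raise ValueError("sfreq and tmin required for raw arrays")
    times = tmin + np.arange(data.shape[-1]) / sfreq
    cols = []
    for k, (lo, hi) in enumerate(windows):
        last = k == len(windows) - 1
        sel = (times >= lo - 1e-9) & ((times <= hi + 1e-9) if last else (times < hi - 1e-9))
        if not sel.any():
            raise ValueError(f"no samples in window {lo}-{hi} s")
        cols.append(data[..., sel].mean(axis=-1))
    return np.stack(cols, axis=-1)


def _align_signs(mem: np.ndarray, nov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resolve the beamformer's per-dipole sign ambiguity.

    Both conditions of a subject are flipped together so that the sample of
    largest magnitude of their summed time course is positive; |contrast| is
    then invariant to arbitrary orientation sign flips.
    """
    ref = mem + nov
    peak = np.take_along_axis(ref, np.abs(ref).argmax(axis=1, keepdims=True), axis=1)
    sign = np.where(peak >= 0, 1.0, -1.0)
    return mem * sign, nov * sign


def first_level(memorized: SourceEstimate, novel: SourceEstimate) -> SourceEstimate:
    """Per-subject memorized - novel contrast of condition-mean source
    activity, after sign alignment."""
    if memorized.data.shape != novel.data.shape:
        raise ValueError("condition estimates must share shape")
    m, n = _align_signs(memorized.data, novel.data)
    return SourceEstimate(m - n, memorized.sfreq, memorized.tmin,
                          memorized.subject, "memorized-novel", memorized.band)


def group_level(contrasts: np.ndarray, voxel_alpha: float = 0.05,
                contrast: str = "memorized-novel", band: str | None = None,
                ) -> tuple[GroupStatMap, BinaryMap, BinaryMap]:
    """One-sample t across subjects per dipole/timepoint, binarized by sign.

    ``contrasts`` is (n_subjects, n_dipoles, n_cols). Zero-variance cells are
    degenerate and marked non-significant (t = 0, p = 1).
    """
    contrasts = np.asarray(contrasts)
    if contrasts.shape[0] < 2:
        raise ValueError("need at least two subjects")
    import warnings as _warnings
    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)   # constant cells -> nan
        res = stats.ttest_1samp(contrasts, 0.0, axis=0)
    t = np.nan_to_num(np.asarray(res.statistic), nan=0.0)
    p = np.nan_to_num(np.asarray(res.pvalue), nan=1.0)
    sig = p < voxel_alpha
    smap = GroupStatMap(t, p, contrast, band, voxel_alpha)
    return (smap,
            BinaryMap((sig & (t > 0)).astype(np.uint8), direction="A>B"),
            BinaryMap((sig & (t < 0)).astype(np.uint8), direction="B>A"))


def _roi_votes(members, grid: SourceGrid) -> str:
    """Majority atlas label over a cluster's member voxels."""
    lookup = {}
    for d, cell in enumerate(map(tuple, grid.ijk)):
        lookup[cell] = d
    atlas = grid.atlas if grid.atlas is not None else grid.labels
    labels = [atlas[lookup[c]] for c in members if c in lookup]
    if not labels:
        return "none"
    vals, counts = np.unique(labels, return_counts=True)
    return str(vals[counts.argmax()])


def _windowed_spatial_mcs(
    subject_windows: np.ndarray,       # (n_subj, n_dip, n_win)
    grid: SourceGrid,
    voxel_alpha: float,
    mcs_alpha: float,
    n_perm: int,
    seed: int,
    band: str | None = None,
    directions: tuple[str, str] = ("A>B", "B>A"),
) -> pd.DataFrame:
    """Group t on per-window values, 3D spatial cluster MCS per window and
    direction; returns one long cluster table with ROI majority votes."""
    rng = np.random.default_rng(seed)
    _, pos, neg = group_level(subject_windows, voxel_alpha=voxel_alpha, band=band)
    valid = grid.validity_mask()
    rows = []
    for w in range(subject_windows.shape[2]):
        for bmap_flat, direction in ((pos, directions[0]), (neg, directions[1])):
            vol = grid.embed(bmap_flat.data[:, w]).astype(np.uint8)
            bmap = BinaryMap(vol, valid, direction)
            clusters = run_mcs(bmap, n_perm=n_perm, alpha=mcs_alpha, seed=rng)
            if not clusters:
                continue
            tab = cluster_table(clusters)
            tab.insert(0, "window", w + 1)
            tab["band"] = band if band is not None else ""
            tab["mcs_alpha"] = mcs_alpha
            tab["roi_majority"] = [_roi_votes(c.members, grid) for c in clusters]
            rows.append(tab)
    cols = ["window", "cluster_number", "size", "n_channels_or_voxels",
            "time_interval_s", "p_value", "significant", "direction", "band",
            "mcs_alpha", "roi_majority"]
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=cols)


def tone_window_mcs(
    contrasts: np.ndarray,             # (n_subj, n_dip, n_samples) first-level maps
    grid: SourceGrid,
    sfreq: float,
    tmin: float = 0.0,
    band: str | None = None,
    band_count: int = 2,
    voxel_alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-tone-window spatial cluster MCS on group-level contrast t-maps.

    The first-level maps are sub-averaged within each 250-ms tone window, a
    one-sample group t is computed per dipole, binarized at the voxel alpha,
    and each window x direction map is corrected by 3D spatial cluster MCS
    at alpha = 0.01 / (5 x band_count) — the family of five tones times the
    number of bands tested.
    """
    mcs_alpha = 0.01 / (5 * band_count)
    wm = window_means(np.asarray(contrasts), sfreq=sfreq, tmin=tmin)
    return _windowed_spatial_mcs(wm, grid, voxel_alpha, mcs_alpha, n_perm, seed,
                                 band=band,
                                 directions=("memorized>novel", "novel>memorized"))


def memorized_piece_contrast(
    tonal: np.ndarray,                 # (n_subj, n_dip, n_samples) memorized-tonal sources
    atonal: np.ndarray,                # same for memorized-atonal
    grid: SourceGrid,
    sfreq: float,
    tmin: float = 0.0,
    band: str | None = None,
    band_count: int = 2,
    voxel_alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Tonal-vs-atonal contrast of memorized-condition activity.

    Paired per-subject differences of window-averaged activity are tested at
    the group level (voxel alpha 0.01), then corrected by the same ten-MCS
    family (five windows x two bands) at 0.01/10 = 0.001.
    """
    tonal, atonal = np.asarray(tonal), np.asarray(atonal)
    if tonal.shape != atonal.shape:
        raise ValueError("piece arrays must share shape")
    diff = (window_means(np.abs(tonal), sfreq=sfreq, tmin=tmin)
            - window_means(np.abs(atonal), sfreq=sfreq, tmin=tmin))
    mcs_alpha = 0.01 / (5 * band_count)
    return _windowed_spatial_mcs(diff, grid, voxel_alpha, mcs_alpha, n_perm, seed,
                                 band=band, directions=("tonal>atonal", "atonal>tonal"))


def band_contrast(
    slow: np.ndarray,                  # (n_subj, n_dip, n_samples)
    fast: np.ndarray,
    grid: SourceGrid,
    sfreq: float,
    tmin: float = 0.0,
    voxel_alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Slow-vs-fast band contrast on per-band z-scored window means.

    Window means of each band are z-scored within subject (across dipoles
    and windows) before differencing, removing trivial global amplitude
    differences between the 0.1-1 Hz and 2-8 Hz signals; the result is
    invariant to a global gain applied to either band.
    """
    slow, fast = np.asarray(slow), np.asarray(fast)
    if slow.shape != fast.shape:
        raise ValueError("band arrays must share shape")

    def _z(w):
        mu = w.mean(axis=(1, 2), keepdims=True)
        sd = w.std(axis=(1, 2), keepdims=True)
        sd = np.where(sd > 0, sd, 1.0)
        return (w - mu) / sd

    diff = (_z(window_means(np.abs(slow), sfreq=sfreq, tmin=tmin))
            - _z(window_means(np.abs(fast), sfreq=sfreq, tmin=tmin)))
    return _windowed_spatial_mcs(diff, grid, voxel_alpha, 0.01 / 10, n_perm, seed,
                                 band="slow-vs-fast",
                                 directions=("slow>fast", "fast>slow"))


def familiarity_correlation(
    ratings: np.ndarray,               # (n_subj,) familiarity 1-7
    subject_windows: np.ndarray,       # (n_subj, n_dip, n_win) window means
    grid: SourceGrid,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Pearson correlation maps between familiarity and windowed activity.

    Per dipole and tone window, r is computed across subjects; cells with
    p < alpha (two-sided) are binarized by the sign of r and corrected with
    spatial cluster MCS using the 95% maximum-cluster rule (alpha = 0.05).
    Returns the r maps (n_dip, n_win) and the cluster table.
    """
    ratings = np.asarray(ratings, dtype=float)
    X = np.asarray(subject_windows, dtype=float)
    n = ratings.size
    if n < 3:
        raise ValueError("need at least three subjects for a correlation")
    if np.any((ratings < 1) | (ratings > 7)):
        raise ValueError("ratings must lie on the 1-7 scale")
    if np.allclose(ratings.std(), 0.0):
        raise ValueError("degenerate: familiarity ratings have zero variance")
    y = (ratings - ratings.mean()) / ratings.std()
    Xc = X - X.mean(axis=0)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("s,sdw->dw", y, Xc) / (n * np.where(sd > 0, sd, np.inf))
    r = np.clip(np.nan_to_num(r), -0.9999999, 0.9999999)
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    sig = p < alpha

    rng = np.random.default_rng(seed)
    valid = grid.validity_mask()
    rows = []
    for w in range(X.shape[2]):
        for mask, direction in ((sig[:, w] & (r[:, w] > 0), "positive"),
                                (sig[:, w] & (r[:, w] < 0), "negative")):
            vol = grid.embed(mask.astype(float)).astype(np.uint8)
            bmap = BinaryMap(vol, valid, direction)
            clusters = run_mcs(bmap, n_perm=n_perm, alpha=alpha, seed=rng)
            if not clusters:
                continue
            tab = cluster_table(clusters)
            tab.insert(0, "window", w + 1)
            tab["roi_majority"] = [_roi_votes(c.members, grid) for c in clusters]
            rows.append(tab)
    cols = ["window", "cluster_number", "size", "n_channels_or_voxels",
            "time_interval_s", "p_value", "significant", "direction", "roi_majority"]
    table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=cols)
    return r, table
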
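"""Synthetic MEG cohort generator.

Builds a spherical head model (sources on a regular cubic grid inside a
sphere, sensors on a shell above it), the analytic single-sphere current-
dipole forward solution, and simulates a full old/new auditory recognition
cohort: per-trial dipole activity in a slow (whole-sequence envelope) and a
faster (per-tone response) band, sensor noise, behavioral accuracy/reaction
times and familiarity ratings.

Units are SI throughout: positions in meters, dipole moments in A*m,
magnetometer readings in T, planar-gradiometer readings in T/m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "SensorArray",
    "SourceGrid",
    "LeadField",
    "Effect",
    "GroundTruth",
    "Recording",
    "CohortConfig",
    "CohortData",
    "make_sensor_array",
    "make_source_grid",
    "default_roi_spec",
    "compute_lead_field",
    "default_ground_truth",
    "simulate_subject",
    "simulate_cohort",
    "cohort_geometry",
    "iter_subjects",
    "sarvas_field",
]

CONDITIONS = ("memorized_tonal", "novel_tonal", "memorized_atonal", "novel_atonal")

MU0_OVER_4PI = 1e-7


# ---------------------------------------------------------------------------
# geometry


def _tangential_basis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Radial unit vector and two orthogonal tangential unit vectors per point."""
    r = np.linalg.norm(points, axis=-1, keepdims=True)
    radial = np.divide(points, r, out=np.zeros_like(points), where=r > 0)
    # pick a reference axis not parallel to the radial direction
    ref = np.tile(np.array([0.0, 0.0, 1.0]), (len(points), 1))
    near_pole = np.abs(radial[:, 2]) > 0.9
    ref[near_pole] = [1.0, 0.0, 0.0]
    t1 = np.cross(ref, radial)
    n1 = np.linalg.norm(t1, axis=-1, keepdims=True)
    t1 = np.divide(t1, n1, out=np.zeros_like(t1), where=n1 > 0)
    t2 = np.cross(radial, t1)
    return radial, t1, t2


@dataclass
class SensorArray:
    """306-channel-style array: planar-gradiometer pairs plus magnetometers.

    Positions sit quasi-uniformly (Fibonacci spiral) on the upper hemisphere
    of a shell outside the head sphere. The two gradiometers of a pair share
    the position and have orthogonal tangential orientations; each position
    also carries one radial magnetometer. Channel ordering: all gradiometers
    (pairs interleaved: a0, b0, a1, b1, ...) followed by all magnetometers.
    """

    positions: np.ndarray            # (n_pos, 3) m
    radial: np.ndarray               # (n_pos, 3) unit, outward
    tangent1: np.ndarray             # (n_pos, 3) unit
    tangent2: np.ndarray             # (n_pos, 3) unit
    layout: np.ndarray               # (n_pos, 2) int (row, col) on a regular grid
    layout_shape: tuple[int, int]
    head_radius: float
    shell_radius: float
    grad_baseline: float = 0.017     # m, planar finite-difference baseline

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def n_channels(self) -> int:
        return 3 * self.n_positions

    @property
    def grad_indices(self) -> np.ndarray:
        return np.arange(2 * self.n_positions)

    @property
    def mag_indices(self) -> np.ndarray:
        return np.arange(2 * self.n_positions, 3 * self.n_positions)

    @property
    def channel_names(self) -> list[str]:
        names = []
        for i in range(self.n_positions):
            names += [f"G{i:03d}a", f"G{i:03d}b"]
        names += [f"M{i:03d}" for i in range(self.n_positions)]
        return names

    def pair_id(self, grad_channel: int) -> int:
        return grad_channel // 2


def make_sensor_array(
    n_positions: int = 102,
    head_radius: float = 0.08,
    sensor_shell_radius: float = 0.102,
    grad_baseline: float = 0.017,
) -> SensorArray:
    """Quasi-uniform upper-hemisphere sensor array with a 2D layout embedding.

    Layout coordinates come from an azimuthal-equidistant projection of the
    positions, snapped to the smallest regular grid on which every position
    occupies its own cell.
    """
    if n_positions < 4:
        raise ValueError("need at least 4 sensor positions")
    if not sensor_shell_radius > head_radius > 0:
        raise ValueError("require sensor_shell_radius > head_radius > 0")
    i = np.arange(n_positions)
    z = (i + 0.5) / n_positions            # uniform area on the upper hemisphere
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    s = np.sqrt(1.0 - z**2)
    pos = sensor_shell_radius * np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)
    radial, t1, t2 = _tangential_basis(pos)

    # azimuthal-equidistant projection from the pole: radius = polar angle
    rho = np.arccos(np.clip(z, -1, 1))
    px, py = rho * np.cos(phi), rho * np.sin(phi)
    extent = max(px.max() - px.min(), py.max() - py.min()) + 1e-9
    m = int(np.ceil(np.sqrt(n_positions)))
    while True:
        rows = np.minimum(((py - py.min()) / extent * m).astype(int), m - 1)
        cols = np.minimum(((px - px.min()) / extent * m).astype(int), m - 1)
        cells = rows * m + cols
        if len(np.unique(cells)) == n_positions:
            break
        m += 1
    layout = np.stack([rows, cols], axis=1)
    return SensorArray(pos, radial, t1, t2, layout, (m, m),
                       head_radius, sensor_shell_radius, grad_baseline)


@dataclass
class SourceGrid:
    """Dipoles on a regular cubic grid inside a sphere, with ROI labels."""

    positions: np.ndarray        # (n_dipoles, 3) m
    spacing: float               # m
    radius: float                # m
    labels: np.ndarray           # (n_dipoles,) str — compact ROI patches ('none' outside)
    ijk: np.ndarray              # (n_dipoles, 3) int indices into the bounding box
    shape: tuple[int, int, int]  # bounding-box shape for 3D embedding
    atlas: np.ndarray | None = None  # (n_dipoles,) str — exhaustive nearest-ROI partition

    @property
    def n_dipoles(self) -> int:
        return len(self.positions)

    def roi_indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def validity_mask(self) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        mask[tuple(self.ijk.T)] = True
        return mask

    def embed(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter per-dipole values into the 3D bounding-box array."""
        out = np.full(self.shape, fill, dtype=float)
        out[tuple(self.ijk.T)] = values
        return out


def default_roi_spec(radius_mm: float) -> list[tuple[str, tuple[float, float, float], float]]:
    """Named spherical patches standing in for anatomical regions.

    Fractions of the head radius place bilateral auditory patches laterally,
    hippocampal patches deep in the medial temporal region, and a midline
    cingulate patch; everything else is labelled ``none``.
    """
    r = radius_mm
    return [
        ("auditory_L", (-0.62 * r, -0.25 * r, 0.10 * r), 0.24 * r),
        ("auditory_R", (0.62 * r, -0.25 * r, 0.10 * r), 0.24 * r),
        ("hippocampus_L", (-0.32 * r, -0.22 * r, -0.15 * r), 0.20 * r),
        ("hippocampus_R", (0.32 * r, -0.22 * r, -0.15 * r), 0.20 * r),
        ("cingulate", (0.0, -0.05 * r, 0.45 * r), 0.24 * r),
    ]


def make_source_grid(
    spacing_mm: float = 8.0,
    radius_mm: float = 76.0,
    roi_spec: Sequence[tuple[str, tuple[float, float, float], float]] | None = None,
) -> SourceGrid:
    """Regular cubic dipole grid strictly inside a sphere, ROI-labelled.

    ``roi_spec`` lists (label, center_mm, radius_mm) spherical patches;
    overlaps resolve to the first-listed patch (with a warning).
    """
    if not 0 < spacing_mm < radius_mm:
        if spacing_mm <= 0:
            raise ValueError("spacing must be positive")
        # spacing >= radius still yields at least the origin
    if roi_spec is None:
        roi_spec = default_roi_spec(radius_mm)
    n = int(np.floor(radius_mm / spacing_mm)) if spacing_mm < radius_mm else 0
    axis = np.arange(-n, n + 1) * spacing_mm
    X, Y, Z = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    inside = np.linalg.norm(pts, axis=1) < radius_mm
    pts = pts[inside]
    ijk = (pts / spacing_mm + n + 0.5).astype(int)
    shape = (2 * n + 1,) * 3

    labels = np.full(len(pts), "none", dtype=object)
    claimed = np.zeros(len(pts), dtype=bool)
    for name, center, rad in roi_spec:
        hit = np.linalg.norm(pts - np.asarray(center), axis=1) <= rad
        overlap = hit & claimed
        if overlap.any():
            warnings.warn(f"ROI patch '{name}' overlaps an earlier patch on "
                          f"{int(overlap.sum())} dipoles; first-listed wins")
        labels[hit & ~claimed] = name
        claimed |= hit
    # atlas-style exhaustive partition: every dipole takes the nearest ROI
    # center's label (the way an anatomical-atlas lookup labels any voxel)
    centers = np.stack([np.asarray(c) for _, c, _ in roi_spec])
    names = [n for n, _, _ in roi_spec]
    dists = np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2)
    atlas = np.array([names[j] for j in dists.argmin(axis=1)], dtype=str)
    return SourceGrid(pts * 1e-3, spacing_mm * 1e-3, radius_mm * 1e-3,
                      labels.astype(str), ijk, shape, atlas)


# ---------------------------------------------------------------------------
# forward model


def sarvas_field(points: np.ndarray, dipole_pos: np.ndarray, moments: np.ndarray) -> np.ndarray:
    """External magnetic field of current dipoles in a homogeneous sphere.

    Closed-form solution for a spherically symmetric conductor centred at the
    origin; the result is independent of the conductor radius and vanishes
    identically for radial dipole moments.

    Parameters are ``points`` (P, 3) field points outside the sphere,
    ``dipole_pos`` (D, 3) dipole locations, ``moments`` (D, 3) dipole moments
    in A*m. Returns the field (P, D, 3) in tesla.
    """
    r = np.asarray(points, float)[:, None, :]        # (P,1,3)
    rq = np.asarray(dipole_pos, float)[None, :, :]   # (1,D,3)
    q = np.asarray(moments, float)                   # (D,3)
    a_vec = r - rq
    a = np.linalg.norm(a_vec, axis=-1)               # (P,D)
    rn = np.linalg.norm(r, axis=-1)                  # (P,1)
    rq_dot_r = (r * rq).sum(-1)                      # (P,D)
    a_dot_r = (a_vec * r).sum(-1)
    F = a * (rn * a + rn**2 - rq_dot_r)              # (P,D)
    with np.errstate(divide="ignore", invalid="ignore"):
        c1 = a**2 / rn + a_dot_r / a + 2 * a + 2 * rn
        c2 = a + 2 * rn + a_dot_r / a
    gradF = c1[..., None] * r - c2[..., None] * rq   # (P,D,3)
    qxrq = np.cross(q, dipole_pos)                   # (D,3)
    qxrq_dot_r = np.einsum("dk,pk->pd", qxrq, points)
    with np.errstate(divide="ignore", invalid="ignore"):
        B = MU0_OVER_4PI / F[..., None] ** 2 * (
            F[..., None] * qxrq[None, :, :] - qxrq_dot_r[..., None] * gradF
        )
    # dipole at the origin (or radial moment there): field is identically zero
    B = np.where(np.isfinite(B), B, 0.0)
    return B


@dataclass
class LeadField:
    """Linear map from per-dipole tangential moments to sensor readings.

    ``matrix`` has shape (n_channels, n_dipoles, 2): the two columns per
    dipole correspond to unit moments (1 A*m) along the dipole's two
    tangential unit vectors. Radial moments produce no external field in a
    spherical conductor and are therefore not represented.
    """

    matrix: np.ndarray               # (n_channels, n_dipoles, 2)
    dipole_tangents: np.ndarray      # (n_dipoles, 2, 3)

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_dipoles(self) -> int:
        return self.matrix.shape[1]

    def column(self, dipole: int, orientation: np.ndarray) -> np.ndarray:
        """Lead-field column for a unit moment along a tangential orientation
        expressed as coefficients (2,) in the dipole's tangent basis."""
        return self.matrix[:, dipole, :] @ np.asarray(orientation, float)

    def project(self, dipole_idx: np.ndarray, orientations: np.ndarray,
                amplitudes: np.ndarray) -> np.ndarray:
        """Sensor time series for dipoles ``dipole_idx`` with fixed tangential
        ``orientations`` (n_active, 2) and time-varying ``amplitudes``
        (n_active, n_samples) in A*m."""
        cols = np.einsum("cdo,do->cd", self.matrix[:, dipole_idx, :], orientations)
        return cols @ amplitudes


def compute_lead_field(grid: SourceGrid, sensors: SensorArray) -> LeadField:
    """Analytic single-sphere lead field for the grid/array pair.

    Magnetometers read the field along their (radial) orientation;
    each planar gradiometer reads the finite difference of the radial field
    component across its tangential baseline.
    """
    if np.any(np.linalg.norm(grid.positions, axis=1) >= sensors.head_radius):
        raise ValueError("all dipoles must lie strictly inside the head sphere")
    d = sensors.grad_baseline
    pos = sensors.positions
    # evaluation points: mag centers plus the two offset points of each gradiometer
    eval_points = [pos]
    for t in (sensors.tangent1, sensors.tangent2):
        eval_points += [pos + 0.5 * d * t, pos - 0.5 * d * t]
    P = np.concatenate(eval_points, axis=0)          # (5*n_pos, 3)
    n_pos = sensors.n_positions

    _, dt1, dt2 = _tangential_basis(grid.positions)
    n_dip = grid.n_dipoles
    matrix = np.empty((sensors.n_channels, n_dip, 2))
    for o, tangent in enumerate((dt1, dt2)):
        B = sarvas_field(P, grid.positions, tangent)   # (5*n_pos, n_dip, 3)
        Bn = np.einsum("pdk,pk->pd", B, np.tile(sensors.radial, (5, 1)))
        mag = Bn[:n_pos]
        g1 = (Bn[n_pos:2 * n_pos] - Bn[2 * n_pos:3 * n_pos]) / d
        g2 = (Bn[3 * n_pos:4 * n_pos] - Bn[4 * n_pos:5 * n_pos]) / d
        grads = np.empty((2 * n_pos, n_dip))
        grads[0::2] = g1
        grads[1::2] = g2
        matrix[:2 * n_pos, :, o] = grads
        matrix[2 * n_pos:, :, o] = mag
    tangents = np.stack([dt1, dt2], axis=1)
    return LeadField(matrix, tangents)


# ---------------------------------------------------------------------------
# ground truth and cohort configuration


@dataclass(frozen=True)
class Effect:
    """One condition-specific source: an ROI active in one band with a
    per-tone-window amplitude envelope (A*m, >= 0, five windows)."""

    roi: str
    band: str                         # 'slow' or 'fast'
    window_amplitudes: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.band not in ("slow", "fast"):
            raise ValueError("band must be 'slow' or 'fast'")
        if len(self.window_amplitudes) != 5:
            raise ValueError("five tone-window amplitudes required")
        if any(a < 0 for a in self.window_amplitudes):
            raise ValueError("amplitudes must be >= 0")


@dataclass
class GroundTruth:
    """Per-condition dipole-level effects plus the orientation seed that fixes
    each ROI dipole's tangential orientation across subjects and trials."""

    effects: dict[str, tuple[Effect, ...]]
    orientation_seed: int = 7

    def __post_init__(self) -> None:
        for cond in self.effects:
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")


NAM = 1e-9  # nA*m in A*m


def default_ground_truth(
    baseline_fast: float = 25 * NAM,
    baseline_slow: float = 15 * NAM,
    memory_effect: float = 30 * NAM,
    auditory_effect: float = 30 * NAM,
) -> GroundTruth:
    """The simulated dissociation: every condition evokes bilateral auditory
    responses in both bands; memorized-tonal adds a slow-band effect in the
    memory regions (hippocampus + cingulate) at tone windows 3-5;
    memorized-atonal adds a slow-band effect in right auditory cortex at all
    windows."""
    base = tuple(
        Effect(roi, band, (amp,) * 5)
        for roi in ("auditory_L", "auditory_R")
        for band, amp in (("fast", baseline_fast), ("slow", baseline_slow))
    )
    mem = (
        Effect("hippocampus_L", "slow", (0, 0, memory_effect, memory_effect, memory_effect)),
        Effect("hippocampus_R", "slow", (0, 0, memory_effect, memory_effect, memory_effect)),
        Effect("cingulate", "slow", (0, 0, memory_effect, memory_effect, memory_effect)),
    )
    aud = (Effect("auditory_R", "slow", (auditory_effect,) * 5),)
    return GroundTruth(effects={
        "memorized_tonal": base + mem,
        "novel_tonal": base,
        "memorized_atonal": base + aud,
        "novel_atonal": base,
    })


@dataclass
class CohortConfig:
    """Everything the simulator needs, including the master RNG seed.

    Behavioral defaults follow the study conditions: accuracy means per
    condition (of 40 trials) 34.34 / 34.41 / 30.98 / 34.51 with between-
    subject SDs 5.95 / 6.04 / 5.46 / 4.26, and reaction-time means
    1735.17 / 1799.52 / 1879.44 / 1873.78 ms with SDs ~250-267 ms, ordered
    (memorized_tonal, novel_tonal, memorized_atonal, novel_atonal).
    """

    n_subjects: int = 71
    n_sensor_positions: int = 102
    head_radius: float = 0.08
    sensor_shell_radius: float = 0.102
    grid_spacing_mm: float = 8.0
    grid_radius_mm: float = 76.0
    sfreq: float = 150.0
    trial_interval_s: float = 1.6
    n_trials_per_condition: int = 40
    noise_sd_grad: float = 2e-12      # T/m per sample, white component
    noise_sd_mag: float = 1e-13       # T per sample, white component
    pink_sd_grad: float = 2e-11       # T/m RMS, 1/f (brain + environment) component
    pink_sd_mag: float = 1e-12        # T RMS, 1/f component
    pink_corner_hz: float = 0.03      # spectrum flattens below this frequency
    inter_subject_amp_sd: float = 0.2
    trial_amp_jitter_sd: float = 0.1
    accuracy_means: tuple[float, ...] = (34.34, 34.41, 30.98, 34.51)
    accuracy_sds: tuple[float, ...] = (5.95, 6.04, 5.46, 4.26)
    rt_means_ms: tuple[float, ...] = (1735.17, 1799.52, 1879.44, 1873.78)
    rt_sds_ms: tuple[float, ...] = (259.91, 267.14, 259.34, 250.48)
    rt_within_sd_ms: float = 300.0
    familiarity_probs: tuple[float, ...] = (0.15, 0.20, 0.25, 0.20, 0.10, 0.07, 0.03)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(sd < 0 for sd in (self.noise_sd_grad, self.noise_sd_mag,
                                 self.inter_subject_amp_sd, self.trial_amp_jitter_sd)):
            raise ValueError("standard deviations must be >= 0")
        if any(not 0 <= m <= 40 for m in self.accuracy_means):
            raise ValueError("accuracy means must lie in [0, 40]")
        if abs(sum(self.familiarity_probs) - 1.0) > 1e-9 or len(self.familiarity_probs) != 7:
            raise ValueError("familiarity_probs must be 7 probabilities summing to 1")


@dataclass
class Recording:
    """Continuous multichannel recording with event markers."""

    data: np.ndarray                 # (n_channels, n_samples) float32
    sfreq: float
    event_samples: np.ndarray        # (n_events,) int
    event_conditions: np.ndarray     # (n_events,) str
    event_correct: np.ndarray        # (n_events,) bool
    subject_id: int
    seed: int

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# waveforms

TONE_DUR_S = 0.250
N_TONES = 5
TRIAL_DUR_S = N_TONES * TONE_DUR_S   # 1.25 s excerpt
SUSTAIN_S = 0.250                    # slow activity persists into the response period
TEMPLATE_DUR_S = TRIAL_DUR_S + SUSTAIN_S


def _slow_waveform(window_amps: np.ndarray, sfreq: float) -> np.ndarray:
    """Tone-window step envelope smoothed into the slow band (0.1-1 Hz-ish).

    The last window's amplitude is sustained 250 ms past the excerpt end
    (recognition-related slow activity does not switch off with the final
    tone), so the fifth tone window is not eroded by the smoothing rolloff.
    """
    n = int(round(TEMPLATE_DUR_S * sfreq))
    t = np.arange(n) / sfreq
    wav = window_amps[np.minimum((t / TONE_DUR_S).astype(int), N_TONES - 1)]
    k = int(round(0.3 * sfreq)) | 1              # 300 ms Hann smoother
    kernel = np.hanning(k + 2)[1:-1]
    kernel /= kernel.sum()
    pad = np.r_[np.zeros(k), wav, np.full(k, wav[-1])]
    return np.convolve(pad, kernel, mode="same")[k:k + n]


def _fast_waveform(window_amps: np.ndarray, sfreq: float) -> np.ndarray:
    """One damped ~5 Hz response per tone onset, scaled per window."""
    n = int(round(TEMPLATE_DUR_S * sfreq))
    t = np.arange(n) / sfreq
    wav = np.zeros(n)
    for k in range(N_TONES):
        t0 = k * TONE_DUR_S
        rel = t - t0
        burst = np.sin(2 * np.pi * 5.0 * rel) * np.exp(-0.5 * ((rel - 0.10) / 0.045) ** 2)
        wav += window_amps[k] * burst
    return wav


def _condition_templates(
    gt: GroundTruth, grid: SourceGrid, lead: LeadField, sfreq: float,
    subject_id: int = 0,
) -> dict[str, np.ndarray]:
    """Noise-free sensor-space trial template per condition (n_ch, n_samples).

    Three sources of anatomical/physiological variability are drawn per
    subject (seeded by the ground-truth orientation seed and the subject
    id) and shared across that subject's conditions and trials:

    * tangential dipole orientations (cortical folding differs across heads);
    * a response-latency offset per (ROI, band), up to +/-80 ms — regional
      responses are strongly but not perfectly coherent across regions;
    * a gain factor per (ROI, band).

    Without the latency/gain variability all regions would be perfectly
    coherent, which no real brain is and which makes minimum-variance
    beamforming degenerate (coherent-source cancellation).
    """
    rng = np.random.default_rng([gt.orientation_seed, subject_id])
    theta = rng.uniform(0, 2 * np.pi, size=grid.n_dipoles)
    orient = np.stack([np.cos(theta), np.sin(theta)], axis=1)  # (n_dip, 2)
    pairs = sorted({(e.roi, e.band) for effs in gt.effects.values() for e in effs})
    lags = {p: int(round(rng.uniform(-0.08, 0.08) * sfreq)) for p in pairs}
    gains = {p: max(0.2, rng.normal(1.0, 0.2)) for p in pairs}
    n_samp = int(round(TEMPLATE_DUR_S * sfreq))
    out: dict[str, np.ndarray] = {}
    for cond in CONDITIONS:
        template = np.zeros((lead.n_channels, n_samp))
        for eff in gt.effects.get(cond, ()):
            idx = grid.roi_indices(eff.roi)
            if idx.size == 0:
                warnings.warn(f"ROI '{eff.roi}' has no dipoles on this grid; effect skipped")
                continue
            amps = np.asarray(eff.window_amplitudes, float)
            wav = _slow_waveform(amps, sfreq) if eff.band == "slow" else _fast_waveform(amps, sfreq)
            lag = lags[(eff.roi, eff.band)]
            wav = np.roll(wav, lag)
            if lag > 0:
                wav[:lag] = 0.0
            elif lag < 0:
                wav[lag:] = 0.0
            wav = gains[(eff.roi, eff.band)] * wav
            template += lead.project(idx, orient[idx], np.tile(wav, (idx.size, 1)))
        out[cond] = template
    return out


# ---------------------------------------------------------------------------
# subject & cohort simulation


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                sfreq: float, rms: float, corner_hz: float) -> np.ndarray:
    """1/f-shaped Gaussian noise, RMS-normalized per channel.

    MEG background activity (brain plus environment) is strongly colored;
    without it the slow-band covariance would be evoked-dominated, which no
    real recording is. Spectral shaping: amplitude ~ 1/sqrt(f), flat below
    ``corner_hz``.
    """
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sfreq)
    shape = 1.0 / np.sqrt(np.maximum(freqs, corner_hz))
    shape[0] = 0.0                      # no DC
    white = rng.normal(size=(n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1) * shape
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    x *= rms / x.std(axis=1, keepdims=True)
    return x


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def simulate_subject(
    gt: GroundTruth,
    cfg: CohortConfig,
    grid: SourceGrid,
    sensors: SensorArray,
    lead: LeadField,
    subject_seed: int | np.random.SeedSequence,
    subject_id: int = 0,
    templates: dict[str, np.ndarray] | None = None,
) -> tuple[Recording, pd.DataFrame, int]:
    """One subject: continuous recording, behavioral rows, familiarity rating.

    The 160 trials run as two 80-trial blocks (tonal then atonal), each with
    40 memorized and 40 novel excerpts in random order. Sources are the
    ground-truth condition templates scaled by a subject gain and per-trial
    jitter, projected through the lead field, plus iid Gaussian sensor noise
    per channel type. Fully reproducible under the given seed.
    """
    ss = subject_seed if isinstance(subject_seed, np.random.SeedSequence) else np.random.SeedSequence(subject_seed)
    rng = np.random.default_rng(ss)
    seed_repr = int(ss.entropy) if ss.entropy is not None and int(ss.entropy) < 2**31 else subject_id

    if templates is None:
        templates = _condition_templates(gt, grid, lead, cfg.sfreq, subject_id)
    n_trial = next(iter(templates.values())).shape[1]
    npc = cfg.n_trials_per_condition

    order = []
    for piece in ("tonal", "atonal"):
        block = [f"memorized_{piece}"] * npc + [f"novel_{piece}"] * npc
        rng.shuffle(block)
        order += block
    n_events = len(order)

    step = int(round(cfg.trial_interval_s * cfg.sfreq))
    first = int(round(0.5 * cfg.sfreq))          # baseline must fit before the first event
    onsets = first + step * np.arange(n_events)
    n_samples = int(onsets[-1] + n_trial + round(0.5 * cfg.sfreq))

    gain = max(0.1, rng.normal(1.0, cfg.inter_subject_amp_sd))
    data = np.zeros((sensors.n_channels, n_samples), dtype=np.float64)
    for onset, cond in zip(onsets, order):
        jitter = max(0.0, 1.0 + rng.normal(0.0, cfg.trial_amp_jitter_sd))
        data[:, onset:onset + n_trial] += gain * jitter * templates[cond]
    if cfg.noise_sd_grad > 0:
        data[sensors.grad_indices] += rng.normal(0.0, cfg.noise_sd_grad,
                                                 size=(len(sensors.grad_indices), n_samples))
    if cfg.noise_sd_mag > 0:
        data[sensors.mag_indices] += rng.normal(0.0, cfg.noise_sd_mag,
                                                size=(len(sensors.mag_indices), n_samples))
    if cfg.pink_sd_grad > 0:
        data[sensors.grad_indices] += _pink_noise(
            rng, len(sensors.grad_indices), n_samples, cfg.sfreq,
            cfg.pink_sd_grad, cfg.pink_corner_hz)
    if cfg.pink_sd_mag > 0:
        data[sensors.mag_indices] += _pink_noise(
            rng, len(sensors.mag_indices), n_samples, cfg.sfreq,
            cfg.pink_sd_mag, cfg.pink_corner_hz)

    # behavior: per-subject accuracy probability per condition, then Bernoulli trials
    cond_idx = {c: k for k, c in enumerate(CONDITIONS)}
    p_subj = {c: float(np.clip(rng.normal(cfg.accuracy_means[k] / 40.0,
                                          cfg.accuracy_sds[k] / 40.0), 0.05, 0.999))
              for c, k in cond_idx.items()}
    rt_subj = {c: max(300.0, rng.normal(cfg.rt_means_ms[k], cfg.rt_sds_ms[k]))
               for c, k in cond_idx.items()}
    correct = np.array([rng.random() < p_subj[c] for c in order])
    mu_sig = {c: _lognormal_params(rt_subj[c], cfg.rt_within_sd_ms) for c in order}
    rts = np.array([rng.lognormal(*mu_sig[c]) for c in order])

    conds = np.array(order)
    rows = []
    for c in CONDITIONS:
        sel = conds == c
        rows.append({
            "subject": subject_id, "condition": c,
            "n_correct": int(correct[sel].sum()),
            "n_trials": int(sel.sum()),
            "mean_rt_ms": float(rts[sel & correct].mean()) if (sel & correct).any()
            else float(rts[sel].mean()),
        })
    behavior = pd.DataFrame(rows)
    familiarity = int(rng.choice(np.arange(1, 8), p=np.asarray(cfg.familiarity_probs)))

    rec = Recording(data.astype(np.float32), cfg.sfreq, onsets.astype(int),
                    conds, correct, subject_id, seed_repr)
    return rec, behavior, familiarity


@dataclass
class CohortData:
    """A simulated cohort bundled with its geometry and forward model."""

    config: CohortConfig
    ground_truth: GroundTruth
    sensors: SensorArray
    grid: SourceGrid
    lead_field: LeadField
    recordings: list[Recording]
    behavior: pd.DataFrame
    familiarity: pd.Series           # index: subject id, values 1-7


def cohort_geometry(cfg: CohortConfig) -> tuple[SensorArray, SourceGrid, LeadField]:
    sensors = make_sensor_array(cfg.n_sensor_positions, cfg.head_radius,
                                cfg.sensor_shell_radius)
    grid = make_source_grid(cfg.grid_spacing_mm, cfg.grid_radius_mm)
    lead = compute_lead_field(grid, sensors)
    return sensors, grid, lead


def iter_subjects(
    cfg: CohortConfig,
    gt: GroundTruth | None = None,
    geometry: tuple[SensorArray, SourceGrid, LeadField] | None = None,
) -> Iterator[tuple[Recording, pd.DataFrame, int]]:
    """Stream subjects one at a time (memory-friendly for large cohorts)."""
    if gt is None:
        gt = default_ground_truth()
    sensors, grid, lead = geometry if geometry is not None else cohort_geometry(cfg)
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)
    for sid, child in enumerate(children):
        yield simulate_subject(gt, cfg, grid, sensors, lead, child, sid)


def simulate_cohort(cfg: CohortConfig, gt: GroundTruth | None = None) -> CohortData:
    """Simulate the full cohort (default 71 subjects), deterministically
    spawning one child seed per subject from the master seed."""
    if gt is None:
        gt = default_ground_truth()
    geometry = cohort_geometry(cfg)
    recs, beh, fam = [], [], {}
    for rec, rows, rating in iter_subjects(cfg, gt, geometry):
        recs.append(rec)
        beh.append(rows)
        fam[rec.subject_id] = rating
    sensors, grid, lead = geometry
    return CohortData(cfg, gt, sensors, grid, lead, recs,
                      pd.concat(beh, ignore_index=True),
                      pd.Series(fam, name="familiarity"))
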
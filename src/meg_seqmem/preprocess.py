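"""Event-related-field preprocessing.

Band-pass filtering of continuous recordings (zero-phase Butterworth),
epoching with baseline correction, correct-trial selection, condition
averaging, and root-sum-square combination of planar-gradiometer pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .megsim import CONDITIONS, Recording, SensorArray

__all__ = ["EpochSet", "Evoked", "bandpass", "epoch", "select_correct",
           "average_condition", "combine_planar", "BANDS"]

log = logging.getLogger(__name__)

#: Named analysis bands (Hz): slow whole-sequence band, faster per-tone band,
#: and the standard delta/theta comparison bands.
BANDS: dict[str, tuple[float, float]] = {
    "slow": (0.1, 1.0),
    "fast": (2.0, 8.0),
    "delta": (1.0, 4.0),
    "theta": (5.0, 8.0),
}


@dataclass
class EpochSet:
    """Trials x channels x samples, time-locked to excerpt onset.

    The time axis runs from ``tmin`` (default -100 ms) to ``tmax`` (default
    +1250 ms); each epoch is baseline-corrected by the mean of its pre-onset
    window.
    """

    data: np.ndarray                 # (n_trials, n_channels, n_samples)
    sfreq: float
    tmin: float
    conditions: np.ndarray           # (n_trials,) str
    correct: np.ndarray              # (n_trials,) bool
    band: str = "broadband"

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[2]) / self.sfreq


@dataclass
class Evoked:
    """Condition-average (channels x samples)."""

    data: np.ndarray
    sfreq: float
    tmin: float
    condition: str
    n_trials: int
    band: str = "broadband"
    combined: bool = False

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("an Evoked must average at least one trial")

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[1]) / self.sfreq


def bandpass(rec: Recording, low: float, high: float, order: int = 4,
             band_label: str | None = None) -> Recording:
    """Zero-phase Butterworth band-pass of the continuous data.

    Forward-backward filtering (filtfilt) preserves event-related-field
    latencies; reflection padding of at least three time constants of the
    low edge suppresses edge transients.
    """
    nyq = rec.sfreq / 2.0
    if not 0 <= low < high:
        raise ValueError("require 0 <= low < high")
    if high >= nyq:
        raise ValueError(f"high edge {high} Hz must be below Nyquist ({nyq} Hz)")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.sfreq, output="sos")
    padlen = min(rec.n_samples - 1, int(3 * rec.sfreq / max(low, 0.1)))
    out = signal.sosfiltfilt(sos, rec.data.astype(np.float64), axis=1, padlen=padlen)
    return Recording(out.astype(np.float32), rec.sfreq, rec.event_samples,
                     rec.event_conditions, rec.event_correct, rec.subject_id, rec.seed)


def epoch(rec: Recording, tmin: float = -0.100, tmax: float = 1.250) -> EpochSet:
    """Cut one epoch per event and baseline-correct it.

    Sample-count convention: ``floor((tmax - tmin) * sfreq) + 1`` samples with
    the onset sample included at t = 0 (203 samples for the default 1350-ms
    epoch at 150 Hz). Events too close to the recording edge are dropped with
    a logged count. Baseline = mean of the pre-onset samples, per channel and
    trial.
    """
    n_samp = int(np.floor((tmax - tmin) * rec.sfreq)) + 1
    offset = int(np.round(tmin * rec.sfreq))
    starts = rec.event_samples + offset
    keep = (starts >= 0) & (starts + n_samp <= rec.n_samples)
    if not keep.all():
        log.warning("dropped %d events too close to the recording edge",
                    int((~keep).sum()))
    starts = starts[keep]
    idx = starts[:, None] + np.arange(n_samp)[None, :]
    data = rec.data.astype(np.float64)[:, idx].transpose(1, 0, 2)
    n_base = int(np.round(-tmin * rec.sfreq))      # samples strictly before onset
    if n_base > 0:
        data -= data[:, :, :n_base].mean(axis=2, keepdims=True)
    return EpochSet(data, rec.sfreq, tmin,
                    rec.event_conditions[keep], rec.event_correct[keep])


def select_correct(ep: EpochSet) -> EpochSet:
    """Keep correctly answered trials only (order preserved).

    Raises if any condition present in the input loses all of its trials,
    naming the condition.
    """
    mask = ep.correct.astype(bool)
    for cond in np.unique(ep.conditions):
        sel = ep.conditions == cond
        if sel.any() and not (sel & mask).any():
            raise ValueError(f"no correct trials left in condition '{cond}'")
    return EpochSet(ep.data[mask], ep.sfreq, ep.tmin,
                    ep.conditions[mask], ep.correct[mask], ep.band)


def average_condition(ep: EpochSet, condition: str) -> Evoked:
    """Arithmetic mean over the trials of one condition."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition '{condition}'; expected one of {CONDITIONS}")
    sel = ep.conditions == condition
    if not sel.any():
        raise ValueError(f"no trials of condition '{condition}'")
    return Evoked(ep.data[sel].mean(axis=0), ep.sfreq, ep.tmin,
                  condition, int(sel.sum()), ep.band)


def combine_planar(ev: Evoked, sensors: SensorArray) -> Evoked:
    """Root-sum-square combination of each planar-gradiometer pair.

    Output has one channel per sensor position (sqrt(g1^2 + g2^2) per
    sample); magnetometer channels are dropped. The result is everywhere
    non-negative and invariant to sign flips of either gradiometer.
    """
    if ev.combined:
        raise ValueError("Evoked is already planar-combined")
    if ev.data.shape[0] != sensors.n_channels:
        raise ValueError(
            f"channel mismatch: Evoked has {ev.data.shape[0]} channels, "
            f"array defines {sensors.n_channels} (is a gradiometer unpaired?)")
    g = ev.data[sensors.grad_indices]
    combined = np.sqrt(g[0::2] ** 2 + g[1::2] ** 2)
    return Evoked(combined, ev.sfreq, ev.tmin, ev.condition, ev.n_trials,
                  ev.band, combined=True)
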
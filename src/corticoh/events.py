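"""Spike-locked epoching of scalp or source recordings.

Analysis is anchored on interictal spike peak times: each spike yields a
3-s window (1.5 s either side of the peak), which is then carved into
three contiguous 1-s intervals — pre-spike [t-1.5, t-0.5), spike
[t-0.5, t+0.5) and post-spike [t+0.5, t+1.5). One-second intervals give
an exact 1 Hz spectral resolution downstream. Interval boundaries are
half-open and computed as round(fs * t) sample indices, so the three
intervals tile the segment with no gap or overlap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("corticoh.events")

__all__ = [
    "SensorRecording",
    "EpochSet",
    "segment_spikes",
    "carve_intervals",
    "half_peak_time",
    "INTERVALS",
]

INTERVALS = ("pre", "spike", "post")


@dataclass
class SensorRecording:
    """Multichannel recording with spike event times.

    ``data`` is channels x samples in microvolts; ``spike_times`` are the
    spike *peak* times in seconds from the start of the recording.
    """

    data: np.ndarray
    fs: float
    spike_times: np.ndarray
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        dur = self.duration
        if np.any(self.spike_times < 0) or np.any(self.spike_times >= dur):
            raise ValueError("spike times must lie within [0, duration)")
        if self.channel_names is None:
            self.channel_names = [f"E{i + 1}" for i in range(len(self.data))]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Per-spike epochs for the three analysis intervals.

    ``epochs[interval]`` is (n_spikes, n_signals, n_samples); all three
    intervals have identical sample counts and tile the central 3 s of
    each spike segment contiguously.
    """

    epochs: dict[str, np.ndarray]
    fs: float
    spike_times: np.ndarray
    interval_s: float = 1.0
    meta: dict = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return self.epochs["spike"].shape[0]

    def __post_init__(self) -> None:
        shapes = {k: v.shape for k, v in self.epochs.items()}
        if len({s for s in shapes.values()}) != 1:
            raise ValueError(f"interval epoch shapes differ: {shapes}")


def _epoch_len(fs: float, seconds: float = 1.0) -> int:
    """Samples per interval; warns when fs*seconds is not an integer."""
    exact = fs * seconds
    n = int(round(exact))
    if abs(exact - n) > 1e-9:
        n = int(math.floor(exact))
        logger.warning(
            "fs*%.3gs = %.6g is not an integer; epochs use %d samples and "
            "spectral bin spacing deviates from exactly 1 Hz", seconds, exact, n)
    return n


def segment_spikes(rec: SensorRecording, pre_s: float = 1.5,
                   post_s: float = 1.5) -> tuple[np.ndarray, np.ndarray]:
    """Cut one segment [t - pre_s, t + post_s) per usable spike.

    Spikes too close to either end of the recording are dropped with a
    warning. Returns ``(segments, kept_times)`` with segments of shape
    (n_spikes, n_channels, round(fs*(pre_s+post_s))).

    Raises
    ------
    ValueError
        If no spike has the full window available.
    """
    n_len = int(round(rec.fs * (pre_s + post_s)))
    n_pre = int(round(rec.fs * pre_s))
    segments, kept = [], []
    for t in rec.spike_times:
        start = int(round(t * rec.fs)) - n_pre
        stop = start + n_len
        if start < 0 or stop > rec.n_samples:
            logger.warning("spike at %.3f s too close to the recording edge "
                           "(need %.2g s margin); dropped", t, max(pre_s, post_s))
            continue
        segments.append(rec.data[:, start:stop])
        kept.append(t)
    if not segments:
        raise ValueError("no spike has the full segmentation window available")
    return np.stack(segments), np.asarray(kept)


def carve_intervals(segment: np.ndarray, fs: float,
                    pre_s: float = 1.5) -> dict[str, np.ndarray]:
    """Carve a spike-centered segment into pre/spike/post 1-s epochs.

    The segment is assumed to start ``pre_s`` seconds before the spike
    peak. Boundaries fall at round(fs * {pre_s-1.5, pre_s-0.5, pre_s+0.5,
    pre_s+1.5}) relative samples, giving three contiguous, non-overlapping
    epochs of equal length.
    """
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    n = segment.shape[-1]
    if n < int(round(fs * 3.0)):
        raise ValueError(
            f"segment of {n} samples is shorter than the 3 s needed for "
            "pre/spike/post intervals")
    n_int = _epoch_len(fs, 1.0)
    offsets = {
        "pre": int(round(fs * (pre_s - 1.5))),
        "spike": int(round(fs * (pre_s - 0.5))),
        "post": int(round(fs * (pre_s + 0.5))),
    }
    out = {}
    for name, start in offsets.items():
        if start < 0 or start + n_int > n:
            raise ValueError(f"interval '{name}' falls outside the segment")
        out[name] = segment[:, start:start + n_int]
    return out


def epochs_from_recording(rec: SensorRecording, pre_s: float = 1.5,
                          post_s: float = 1.5) -> EpochSet:
    """segment_spikes + carve_intervals for every usable spike."""
    segments, kept = segment_spikes(rec, pre_s, post_s)
    per_interval: dict[str, list[np.ndarray]] = {k: [] for k in INTERVALS}
    for seg in segments:
        carved = carve_intervals(seg, rec.fs, pre_s)
        for k in INTERVALS:
            per_interval[k].append(carved[k])
    return EpochSet(
        epochs={k: np.stack(v) for k, v in per_interval.items()},
        fs=rec.fs,
        spike_times=kept,
        meta={"pre_s": pre_s, "post_s": post_s},
    )


def half_peak_time(waveform: np.ndarray, fs: float,
                   polarity: str = "auto") -> float:
    """Time where the rising phase crosses 50% of the spike peak.

    Localization at the half-peak point on the rising phase is less
    contaminated by propagated activity than the peak itself. The peak is
    the extremum of the chosen polarity ("pos", "neg", or "auto" = largest
    absolute value); the crossing closest to the peak is found walking
    back from it and linearly interpolated between samples.
    """
    x = np.asarray(waveform, dtype=float)
    if x.ndim != 1:
        raise ValueError("waveform must be 1-D")
    if np.ptp(x) == 0:
        raise ValueError("flat waveform has no spike peak")
    if polarity == "pos":
        y = x
    elif polarity == "neg":
        y = -x
    elif polarity == "auto":
        y = x if abs(x.max()) >= abs(x.min()) else -x
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    p = int(np.argmax(y))
    if p == 0:
        raise ValueError("peak at the first sample: no rising phase")
    half = 0.5 * y[p]
    i = p
    while i > 0 and y[i - 1] >= half:
        i -= 1
    if i == 0 and y[0] >= half:
        raise ValueError("waveform never drops below half peak before it")
    # linear interpolation between samples i-1 and i
    lo, hi = y[i - 1], y[i]
    frac = (half - lo) / (hi - lo)
    return ((i - 1) + frac) / fs
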
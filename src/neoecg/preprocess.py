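"""Segment extraction, the denoising filter cascade, and amplitude normalization.

Stages mirror standard neonatal ECG practice: 10 s excerpts adjacent to each
blood-gas sampling event are filtered with a 0.5 Hz high-pass (baseline
wander), 100 Hz low-pass (EMG), 50 Hz notch (mains) and a Savitzky-Golay
smoother, then min-max normalized to [0, 1] with the affine map stored so
physical amplitudes remain recoverable.  All IIR stages are applied
forward-backward (zero phase) so fiducial timing downstream is unbiased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "ECGRecord",
    "ECGSegment",
    "FilterConfig",
    "DegenerateSignalError",
    "extract_segments",
    "filter_segment",
    "normalize",
    "denormalize",
]

logger = logging.getLogger(__name__)

PH_BOUNDS = (6.5, 8.0)


class DegenerateSignalError(ValueError):
    """Signal is constant (or otherwise unusable) where variation is required."""


@dataclass(frozen=True)
class ECGRecord:
    """Multichannel sampled ECG: ``data`` is (n_samples, n_channels) in mV."""

    data: np.ndarray
    fs: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim == 1:
            d = d[:, None]
        if d.ndim != 2:
            raise ValueError("data must be 1-D or (n_samples, n_channels)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be > 0")
        object.__setattr__(self, "data", d)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def time(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.fs

    def channel(self, index: int) -> np.ndarray:
        return self.data[:, index]


@dataclass
class ECGSegment:
    """A single-channel excerpt tied to one blood-gas event.

    ``offset``/``scale`` record the affine map back to physical units:
    physical = samples * scale + offset (identity until :func:`normalize`).
    """

    samples: np.ndarray
    fs: float
    event_id: str
    ph: float
    side: str  # "preceding" | "following"
    offset: float = 0.0
    scale: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not (PH_BOUNDS[0] <= self.ph <= PH_BOUNDS[1]):
            raise ValueError(f"pH {self.ph} outside plausibility bounds {PH_BOUNDS}")
        if self.side not in ("preceding", "following"):
            raise ValueError("side must be 'preceding' or 'following'")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def physical(self) -> np.ndarray:
        """Samples mapped back to mV through the stored affine map."""
        return self.samples * self.scale + self.offset


def extract_segments(
    record: ECGRecord,
    events: pd.DataFrame,
    seg_len: float = 10.0,
    channel: int = 0,
    sides: tuple[str, ...] = ("preceding", "following"),
    min_len: float = 8.0,
) -> list[ECGSegment]:
    """Cut up to two ``seg_len``-second excerpts around each blood-gas event.

    For an event at time t the preceding side is [t - seg_len, t) and the
    following side is [t, t + seg_len) in record time.  Edge-truncated sides
    are kept when at least ``min_len`` seconds long, else dropped; events
    outside the record span are skipped with a warning.
    """
    if seg_len <= 0:
        raise ValueError("segment length must be > 0")
    x = record.channel(channel)
    t0, t1 = record.start_time, record.start_time + record.duration
    out: list[ECGSegment] = []
    for row_idx, row in events.reset_index(drop=True).iterrows():
        t_ev, ph = float(row["time_s"]), float(row["ph"])
        if not (t0 <= t_ev <= t1):
            logger.warning("event %d at t=%.3f s outside record span [%.3f, %.3f]; skipped",
                           row_idx, t_ev, t0, t1)
            continue
        windows = {"preceding": (t_ev - seg_len, t_ev), "following": (t_ev, t_ev + seg_len)}
        for side in sides:
            lo_t, hi_t = windows[side]
            lo = max(int(round((lo_t - t0) * record.fs)), 0)
            hi = min(int(round((hi_t - t0) * record.fs)), record.n_samples)
            if (hi - lo) / record.fs < min_len:
                continue
            out.append(
                ECGSegment(
                    samples=x[lo:hi].copy(),
                    fs=record.fs,
                    event_id=f"ev{row_idx}",
                    ph=ph,
                    side=side,
                    meta={"event_time_s": t_ev, "start_sample": lo},
                )
            )
    return out


@dataclass(frozen=True)
class FilterConfig:
    """Cascade parameters.  Orders/window are conventional ECG choices; the
    cutoffs are the standard baseline/EMG/mains values."""

    highpass_hz: float = 0.5
    lowpass_hz: float = 100.0
    notch_hz: float = 50.0
    notch_q: float = 30.0
    butter_order: int = 4
    savgol_window: int = 15
    savgol_order: int = 3


def filter_segment(segment: ECGSegment, config: FilterConfig = FilterConfig()) -> ECGSegment:
    """Apply the zero-phase cascade: high-pass, low-pass, notch, Savitzky-Golay.

    Output length equals input length; peak positions are preserved
    (forward-backward filtering has zero phase).  Requires fs > 200 Hz so the
    100 Hz low-pass cutoff sits below Nyquist.
    """
    if segment.fs <= 2 * config.lowpass_hz:
        raise ValueError(
            f"sampling rate {segment.fs} Hz too low for a {config.lowpass_hz} Hz low-pass"
        )
    x = segment.samples
    sos_hp = signal.butter(config.butter_order, config.highpass_hz, "highpass", fs=segment.fs, output="sos")
    sos_lp = signal.butter(config.butter_order, config.lowpass_hz, "lowpass", fs=segment.fs, output="sos")
    b_n, a_n = signal.iirnotch(config.notch_hz, config.notch_q, fs=segment.fs)
    y = signal.sosfiltfilt(sos_hp, x)
    y = signal.sosfiltfilt(sos_lp, y)
    y = signal.filtfilt(b_n, a_n, y)
    y = signal.savgol_filter(y, config.savgol_window, config.savgol_order)
    return replace(segment, samples=y, meta={**segment.meta, "filtered": True})


def normalize(segment: ECGSegment) -> ECGSegment:
    """Min-max map to [0, 1], composing the affine metadata so that
    ``physical()`` still recovers mV.  Idempotent for an already-[0,1] signal."""
    x = segment.samples
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo <= 0:
        raise DegenerateSignalError("cannot normalize a constant signal")
    y = (x - lo) / (hi - lo)
    return replace(
        segment,
        samples=y,
        offset=segment.offset + segment.scale * lo,
        scale=segment.scale * (hi - lo),
    )


def denormalize(segment: ECGSegment) -> ECGSegment:
    """Undo :func:`normalize`: restore physical amplitudes and identity metadata."""
    return replace(segment, samples=segment.physical(), offset=0.0, scale=1.0)
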
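"""Pan-Tompkins-style QRS detection, Q/R/S localization and quality gating.

The detector follows the classic stages: 5-15 Hz band-pass emphasis, a
five-point derivative, squaring (the nonlinear transform), a 150 ms
moving-window integration, and dual adaptive thresholds with signal/noise
level tracking, a 200 ms refractory period and RR-based search-back.  All
thresholds track signal level, so detection is invariant to positive
amplitude scaling, and centered (zero-delay) stages keep it shift-equivariant.

Q and S are the signal minima between the QRS onset/offset and the R apex;
onset and offset come from a 10%-of-max derivative criterion scanned outward
from the points of steepest up/down slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import ECGSegment

__all__ = [
    "DetectorConfig",
    "GateConfig",
    "QRSAnnotation",
    "InsufficientBeatsError",
    "detect_r_peaks",
    "locate_qrs_points",
    "quality_gate",
]


class InsufficientBeatsError(ValueError):
    """Fewer beats than the operation requires."""


@dataclass(frozen=True)
class DetectorConfig:
    bandpass_hz: tuple[float, float] = (5.0, 15.0)
    integration_window_s: float = 0.150
    refractory_s: float = 0.200
    searchback_factor: float = 1.66
    threshold_fraction: float = 0.25  # THR = noise + fraction * (signal - noise)
    refine_window_s: float = 0.060
    # no reliable call where the integration window is truncated by the
    # segment boundary (a clipped QRS there masquerades as an ectopic beat)
    edge_guard_s: float = 0.150


@dataclass(frozen=True)
class GateConfig:
    min_beats: int = 6
    hr_range_bpm: tuple[float, float] = (60.0, 250.0)
    missed_cycle_factor: float = 1.8
    max_rr_cv: float = 0.25


@dataclass
class QRSAnnotation:
    """Per-beat fiducials (sample indices) plus rhythm summaries."""

    onset: np.ndarray
    q: np.ndarray
    r: np.ndarray
    s: np.ndarray
    offset: np.ndarray
    fs: float
    verdict: str = "accepted"
    reason: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def n_beats(self) -> int:
        return int(self.r.size)

    @property
    def rr(self) -> np.ndarray:
        """RR intervals in seconds."""
        return np.diff(self.r) / self.fs

    @property
    def rravg(self) -> float:
        return float(np.mean(self.rr)) if self.rr.size else float("nan")

    @property
    def hr(self) -> float:
        """Average heart rate, bpm (= 60 / RRAvg)."""
        return 60.0 / self.rravg

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beat": np.arange(self.n_beats), "onset": self.onset, "q": self.q,
             "r": self.r, "s": self.s, "offset": self.offset}
        )


def _bandpass(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    sos = signal.butter(2, band, "bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def _transform(x: np.ndarray, fs: float, config: DetectorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Band-pass -> derivative -> square -> centered moving-window integration."""
    bp = _bandpass(x, fs, config.bandpass_hz)
    # classic five-point derivative kernel, gain normalized by fs
    kernel = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (fs / 8.0)
    deriv = np.convolve(bp, kernel[::-1], mode="same")
    squared = deriv * deriv
    win = max(int(round(config.integration_window_s * fs)), 1)
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")
    return bp, mwi


def detect_r_peaks(
    segment: ECGSegment, config: DetectorConfig = DetectorConfig()
) -> np.ndarray:
    """Detect R peaks; returns sorted sample indices (possibly empty).

    Candidate peaks of the integrated signal are classified against an
    adaptive threshold THR = NPK + 0.25 (SPK - NPK), with running signal
    (SPK) and noise (NPK) level estimates, a refractory period, and a
    search-back pass at half threshold when an expected beat (1.66x the
    running RR average) is overdue.  Accepted candidates are refined to the
    local maximum of the input waveform.
    """
    x = np.asarray(segment.samples, dtype=float)
    fs = segment.fs
    if x.size == 0 or not np.any(x != x[0]):
        return np.array([], dtype=int)
    bp, mwi = _transform(x, fs, config)
    if np.max(mwi) <= 0:
        return np.array([], dtype=int)

    refractory = int(round(config.refractory_s * fs))
    cand, _ = signal.find_peaks(mwi, distance=max(refractory // 2, 1))
    if cand.size == 0:
        return np.array([], dtype=int)

    # level initialization from the signal itself (scale-invariant)
    spk = float(np.percentile(mwi, 98))
    npk = float(np.median(mwi))
    frac = config.threshold_fraction

    accepted: list[int] = []
    pending_noise: list[tuple[int, float]] = []  # sub-threshold candidates for search-back
    rr_hist: list[float] = []

    def threshold() -> float:
        return npk + frac * (spk - npk)

    for idx in cand:
        peak = mwi[idx]
        if accepted and idx - accepted[-1] < refractory:
            continue
        if peak >= threshold():
            if accepted:
                rr_hist.append((idx - accepted[-1]) / fs)
            accepted.append(int(idx))
            spk = 0.125 * peak + 0.875 * spk
            pending_noise.clear()
        else:
            # search-back: if the expected beat is overdue, accept the best
            # sub-threshold candidate above half threshold
            pending_noise.append((int(idx), float(peak)))
            if accepted and rr_hist:
                rr_avg = float(np.mean(rr_hist[-8:]))
                overdue = (idx - accepted[-1]) / fs > config.searchback_factor * rr_avg
                if overdue:
                    viable = [(i, p) for i, p in pending_noise
                              if p >= 0.5 * threshold() and i - accepted[-1] >= refractory]
                    if viable:
                        i_best, p_best = max(viable, key=lambda ip: ip[1])
                        rr_hist.append((i_best - accepted[-1]) / fs)
                        accepted.append(i_best)
                        spk = 0.25 * p_best + 0.75 * spk
                        pending_noise.clear()
                        continue
            npk = 0.125 * peak + 0.875 * npk

    if not accepted:
        return np.array([], dtype=int)

    # refine to the local maximum of the (physical-scale) input waveform
    half = int(round(config.refine_window_s * fs))
    refined = []
    for idx in accepted:
        lo, hi = max(idx - half, 0), min(idx + half + 1, x.size)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    # edge transients of the zero-phase filters can push the integrated
    # signal over threshold near the segment boundaries; such candidates
    # have no QRS-band support, so gate on band-passed amplitude relative
    # to the median detected beat (scale-invariant)
    heights = []
    for idx in refined:
        lo, hi = max(idx - half, 0), min(idx + half + 1, bp.size)
        heights.append(np.max(np.abs(bp[lo:hi])))
    med_h = float(np.median(heights))
    guard = int(round(config.edge_guard_s * fs))
    refined = [idx for idx, h in zip(refined, heights)
               if h >= 0.3 * med_h and guard <= idx < x.size - guard]
    refined = np.unique(refined)
    if refined.size == 0:
        return np.array([], dtype=int)
    # drop refinements collapsing onto the same apex
    keep = [int(refined[0])] if refined.size else []
    for idx in refined[1:]:
        if idx - keep[-1] >= refractory:
            keep.append(int(idx))
    return np.asarray(keep, dtype=int)


def _fiducials_around(
    deriv: np.ndarray, x: np.ndarray, r: int, fs: float, half_win_s: float = 0.080,
    frac: float = 0.10,
) -> tuple[int, int, int, int]:
    """Onset, Q, S, offset around one R apex via the derivative criterion."""
    w = int(round(half_win_s * fs))
    lo, hi = max(r - w, 0), min(r + w + 1, x.size)
    pre = np.abs(deriv[lo:r]) if r > lo else np.array([1.0])
    post = np.abs(deriv[r + 1:hi]) if hi > r + 1 else np.array([1.0])

    if pre.size:
        i_up = lo + int(np.argmax(pre))
        th = frac * pre.max()
        below = np.nonzero(np.abs(deriv[lo:i_up]) < th)[0]
        onset = lo + int(below[-1]) if below.size else lo
    else:
        onset = lo
    if post.size:
        i_down = r + 1 + int(np.argmax(post))
        th = frac * post.max()
        below = np.nonzero(np.abs(deriv[i_down + 1:hi]) < th)[0]
        offset = i_down + 1 + int(below[0]) if below.size else hi - 1
    else:
        offset = hi - 1
    onset = min(onset, r - 2) if r - 2 > lo else max(lo, r - 2)
    offset = max(offset, r + 2) if r + 2 < hi else min(hi - 1, r + 2)

    q = onset + int(np.argmin(x[onset:r])) if r > onset else max(r - 1, 0)
    s = r + 1 + int(np.argmin(x[r + 1:offset + 1])) if offset > r else min(r + 1, x.size - 1)
    return onset, q, s, offset


def locate_qrs_points(
    segment: ECGSegment, r_peaks: np.ndarray, config: DetectorConfig = DetectorConfig()
) -> QRSAnnotation:
    """Locate onset, Q, S, offset for every detected R peak.

    Q is the minimum between QRS onset and R; S the minimum between R and
    QRS offset; onset/offset by the 10% derivative criterion on the
    band-passed waveform.  Requires at least 2 R peaks.
    """
    r_peaks = np.asarray(r_peaks, dtype=int)
    if r_peaks.size < 2:
        raise InsufficientBeatsError("at least 2 R peaks are required")
    x = np.asarray(segment.samples, dtype=float)
    bp = _bandpass(x, segment.fs, config.bandpass_hz)
    deriv = np.gradient(bp) * segment.fs
    onset, q, s, offset = [], [], [], []
    for r in r_peaks:
        o, qi, si, f = _fiducials_around(deriv, x, int(r), segment.fs)
        onset.append(o), q.append(qi), s.append(si), offset.append(f)
    return QRSAnnotation(
        onset=np.asarray(onset), q=np.asarray(q), r=r_peaks,
        s=np.asarray(s), offset=np.asarray(offset), fs=segment.fs,
    )


def quality_gate(
    ann: QRSAnnotation, segment: ECGSegment, config: GateConfig = GateConfig()
) -> QRSAnnotation:
    """Accept or reject a segment; the verdict carries the firing rule.

    Rules (any one rejects): too few beats; implied HR outside the neonatal
    plausibility band; an RR gap > 1.8x the median RR (a missed cycle);
    RR coefficient of variation > 0.25 (rhythm/noise instability).
    """
    reason = ""
    expected_min = config.min_beats * segment.duration / 10.0
    if ann.n_beats < max(config.min_beats, 2) or ann.n_beats < expected_min:
        reason = "beat-count"
    else:
        rr = ann.rr
        hr = ann.hr
        if not (config.hr_range_bpm[0] <= hr <= config.hr_range_bpm[1]):
            reason = "hr-range"
        elif np.any(rr > config.missed_cycle_factor * np.median(rr)):
            reason = "missed-cycle"
        elif np.std(rr) / np.mean(rr) > config.max_rr_cv:
            reason = "rr-variability"
    ann.verdict = "rejected" if reason else "accepted"
    ann.reason = reason
    return ann
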
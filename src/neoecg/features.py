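"""T-wave delineation on the representative cycle and the ten morphology features.

Features (one row per accepted segment): T/QRS, T Amplitude, Tslope,
Tslope/T, Tslope/|T|, Tslope/sqrt|T|, HR, QT, QTc (Bazett: QT / sqrt(RRAvg)),
and RRAvg.  Amplitudes are measured on the de-normalized (physical, mV)
cycle relative to an isoelectric baseline (median of the 40 ms preceding
QRS onset); T amplitude is kept signed so an inverted T is negative.

Delineation conventions (the clinical literature leaves all of these open;
each is configurable):

* T search window: [R + 80 ms, R + 0.6 RRAvg];
* T peak: extremum of largest absolute baseline-relative amplitude;
* Tslope: steepest signed slope on the limb returning to baseline after the
  T peak, from least-squares line fits over a 20 ms sliding window -- short
  relative to the narrow neonatal T wave, so the fitted slope tracks the
  analytic Gaussian extremal slope a e^{-1/2} / w within a few percent;
* T-end: tangent method -- the steepest-slope tangent intersected with the
  baseline;
* QT: QRS onset to T-end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cycle import RepresentativeCycle
from .qrs import QRSAnnotation, _fiducials_around

__all__ = [
    "TWaveConfig",
    "TWaveAnnotation",
    "FeatureVector",
    "DelineationError",
    "delineate_t",
    "compute_features",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = [
    "segment_id", "t_qrs", "t_amplitude", "tslope", "tslope_t", "tslope_abs_t",
    "tslope_sqrt_abs_t", "hr", "qt", "qtc", "rravg", "ph", "group",
]

#: feature columns entering the group comparison, in report order
STAT_FEATURES = [
    "t_qrs", "t_amplitude", "tslope", "tslope_t", "tslope_abs_t",
    "hr", "qt", "qtc", "rravg", "tslope_sqrt_abs_t",
]


class DelineationError(ValueError):
    """T-wave search window is empty or unusable."""


@dataclass(frozen=True)
class TWaveConfig:
    window_start_after_r_s: float = 0.080
    window_end_rr_fraction: float = 0.6
    slope_fit_window_s: float = 0.020
    baseline_window_s: float = 0.040


@dataclass
class TWaveAnnotation:
    """Fiducials on the representative cycle (phase-sample indices)."""

    t_peak: int
    t_end: int
    t_amplitude_mv: float
    tslope_mv_per_s: float
    qt_s: float
    baseline_mv: float
    window: tuple[int, int]
    qrs_onset: int
    q: int
    r: int
    s: int
    qrs_offset: int
    low_amplitude: bool = False
    meta: dict = field(default_factory=dict)


def _sliding_slopes(y: np.ndarray, dt: float, k: int) -> np.ndarray:
    """Least-squares slope of each length-k window of y (len = len(y)-k+1)."""
    t = np.arange(k) * dt
    t = t - t.mean()
    denom = float(np.sum(t * t))
    # correlate does not flip its kernel: entry n is sum_k y[n+k] t_c[k]
    return np.correlate(y, t, mode="valid") / denom


def _flattest_level(y: np.ndarray, lo: int, hi: int, k: int) -> tuple[float, float]:
    """Median level and sd of the flattest k-sample window in y[lo:hi+1]."""
    lo, hi = max(lo, 0), min(hi, y.size - 1)
    if hi <= lo:
        return float(y[lo]), 0.0
    if hi - lo < k:
        w = y[lo:hi + 1]
        return float(np.median(w)), float(np.std(w))
    starts = np.arange(lo, hi - k + 2)
    sds = np.array([np.std(y[st:st + k]) for st in starts])
    st = int(starts[np.argmin(sds)])
    return float(np.median(y[st:st + k])), float(sds.min())


def delineate_t(
    cycle: RepresentativeCycle, config: TWaveConfig = TWaveConfig()
) -> TWaveAnnotation:
    """Delineate the T wave on the physical-scale representative cycle."""
    y = cycle.physical()
    m, dt = cycle.m, cycle.dt
    fs_eq = 1.0 / dt

    # refine R near its nominal phase, then QRS fiducials on the cycle itself
    r_nom = int(round(0.3 * m))
    search = slice(max(r_nom - m // 16, 0), min(r_nom + m // 16 + 1, m))
    r = search.start + int(np.argmax(y[search]))
    deriv = np.gradient(y) * fs_eq
    onset, q, s, offset = _fiducials_around(deriv, y, r, fs_eq)

    # isoelectric reference: median of three anchors -- the PQ junction, the
    # early ST segment, and the end-of-cycle diastolic tail, each taken as
    # the flattest (minimum-sd) short window of its search region.  At
    # neonatal rates any single anchor can be contaminated (P tail and Q
    # rise crowd the PR segment; a rate-adapted T crowds the ST segment and
    # the tail; the high-pass leaves a residual droop before the QRS), but
    # rarely all three in the same direction, so the median is robust.
    k_flat = max(int(round(0.012 * fs_eq)), 3)
    b_pq, sd_pq = _flattest_level(
        y, onset - int(round(config.baseline_window_s * fs_eq)),
        onset - int(round(0.006 * fs_eq)), k_flat)
    b_st, sd_st = _flattest_level(
        y, s + int(round(0.015 * fs_eq)), s + int(round(0.045 * fs_eq)), k_flat)
    b_tail, sd_tail = _flattest_level(y, int(round(0.90 * m)), m - 1, k_flat)
    baseline = float(np.median([b_pq, b_st, b_tail]))

    w_lo = r + int(round(config.window_start_after_r_s * fs_eq))
    w_hi = min(r + int(round(config.window_end_rr_fraction * cycle.rravg * fs_eq)), m - 1)
    if w_hi <= w_lo + 2:
        raise DelineationError("T-wave search window is empty at this heart rate")
    rel = y[w_lo:w_hi + 1] - baseline
    t_peak = w_lo + int(np.argmax(np.abs(rel)))
    t_amp = float(y[t_peak] - baseline)

    # descending limb: from the peak toward baseline, allow 25% past the window
    limb_hi = min(t_peak + max(int(round(0.25 * (w_hi - w_lo))), 4) + (w_hi - t_peak), m)
    limb = y[t_peak:limb_hi]
    k = max(int(round(config.slope_fit_window_s * fs_eq)), 3)
    if limb.size < k + 1:
        raise DelineationError("descending limb too short for the slope fit")
    slopes = _sliding_slopes(limb, dt, k)
    want_sign = -math.copysign(1.0, t_amp) if t_amp != 0 else -1.0
    signed = slopes * want_sign
    i_best = int(np.argmax(signed))
    tslope = float(slopes[i_best])
    mid = t_peak + i_best + (k - 1) / 2.0
    y_mid = float(np.interp(mid, np.arange(m), y))

    # tangent method: line through the fit-window midpoint at the steepest slope
    if tslope != 0:
        t_end_f = mid + (baseline - y_mid) / (tslope * dt)
    else:
        t_end_f = float(w_hi)
    t_end = int(round(min(max(t_end_f, t_peak + 1), m - 1)))

    qt = (t_end_f - onset) * dt
    noise_sd = float(min(sd_pq, sd_st, sd_tail))
    return TWaveAnnotation(
        t_peak=t_peak, t_end=t_end, t_amplitude_mv=t_amp, tslope_mv_per_s=tslope,
        qt_s=float(qt), baseline_mv=baseline, window=(w_lo, w_hi),
        qrs_onset=onset, q=q, r=r, s=s, qrs_offset=offset,
        low_amplitude=bool(abs(t_amp) < 2.0 * noise_sd),
    )


def compute_features(
    cycle: RepresentativeCycle,
    ann: QRSAnnotation,
    t_ann: TWaveAnnotation,
    ph: float,
    group: str = "",
    segment_id: str = "",
) -> dict:
    """Assemble the ten-feature row for one segment.

    T/QRS uses the QRS peak-to-peak amplitude (R minus the deeper of the
    Q/S troughs) on the physical scale; ratio features with a zero T
    amplitude are recorded as missing (NaN), never infinity.
    """
    y = cycle.physical()
    t_amp = t_ann.t_amplitude_mv
    qrs_pp = float(y[t_ann.r] - min(y[t_ann.q], y[t_ann.s]))
    rravg = ann.rravg
    qt = t_ann.qt_s
    nan = float("nan")
    if t_amp != 0.0:
        tslope_t = t_ann.tslope_mv_per_s / t_amp
        tslope_abs_t = t_ann.tslope_mv_per_s / abs(t_amp)
        tslope_sqrt = t_ann.tslope_mv_per_s / math.sqrt(abs(t_amp))
    else:
        tslope_t = tslope_abs_t = tslope_sqrt = nan
    return {
        "segment_id": segment_id,
        "t_qrs": t_amp / qrs_pp if qrs_pp > 0 else nan,
        "t_amplitude": t_amp,
        "tslope": t_ann.tslope_mv_per_s,
        "tslope_t": tslope_t,
        "tslope_abs_t": tslope_abs_t,
        "tslope_sqrt_abs_t": tslope_sqrt,
        "hr": ann.hr,
        "qt": qt,
        "qtc": qt / math.sqrt(rravg) if rravg > 0 else nan,
        "rravg": rravg,
        "ph": ph,
        "group": group,
    }
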
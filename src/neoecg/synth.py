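"""Synthetic neonatal ECG cohorts with beat-level ground truth.

The generator stands in for bedside neonatal recordings: two-channel ECG
sampled at 256 Hz with an intermittent blood-gas event (a pH measurement)
placed mid-record.  Each beat is a sum of five Gaussian bumps (P, Q, R, S, T)
on a flat baseline, which keeps the quantities the feature stage must recover
-- T-wave peak amplitude, maximum descending T slope, QT interval --
available in closed or near-closed form:

* a Gaussian wave ``a * exp(-(t-c)^2 / (2 w^2))`` has extremal slope
  ``a * exp(-1/2) / w`` exactly one width past its center, and the tangent
  drawn at that point meets the baseline at ``c + 2 w`` (the tangent-method
  T-end);
* the QRS onset convention used downstream (derivative falling below 10% of
  its in-QRS maximum) has no closed form for the Q+R composite, so the true
  onset is solved numerically on the noise-free continuous template.

Ground truth is therefore "what an ideal delineator would measure on the
clean template": recovery errors reported by the test harness isolate the
degradation introduced by filtering, detection and the PCA beat average.

Cohorts follow the three-group acid-base design: acidosis (pH < 7.20),
normal (7.20-7.45) and alkalosis (pH > 7.45), with configurable group sizes
(default 9/83/16) and per-group multiplicative effects on T amplitude,
T slope and QT relative to the normal group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .preprocess import ECGRecord

__all__ = [
    "WaveParams",
    "BeatTemplateParams",
    "NoiseConfig",
    "CohortConfig",
    "GroundTruth",
    "DegenerateMorphologyError",
    "NEONATAL_TEMPLATE",
    "generate_beat",
    "beat_ground_truth",
    "synthesize_record",
    "add_noise",
    "generate_cohort",
    "GROUP_LABELS",
]

GROUP_LABELS = ("acidosis", "normal", "alkalosis")

# slope of a unit Gaussian of unit width at one width past center
_GAUSS_SLOPE = float(np.exp(-0.5))


class DegenerateMorphologyError(ValueError):
    """Beat template waves overlap the cycle boundary beyond tolerance."""


@dataclass(frozen=True)
class WaveParams:
    """One Gaussian wave: amplitude (mV), center offset from R (s), width (s)."""

    amplitude_mv: float
    center_s: float
    width_s: float


@dataclass(frozen=True)
class BeatTemplateParams:
    """P-QRS-T morphology as five Gaussian bumps on a flat baseline.

    Wave centers are offsets from the R apex (R center fixed at 0) and must be
    ordered P < Q < R = 0 < S < T.  Widths are Gaussian sigmas in seconds.
    """

    p: WaveParams
    q: WaveParams
    r: WaveParams
    s: WaveParams
    t: WaveParams
    baseline_mv: float = 0.0

    def __post_init__(self) -> None:
        waves = self.waves()
        if any(w.width_s <= 0 for w in waves.values()):
            raise ValueError("all wave widths must be > 0")
        if self.r.amplitude_mv < 0:
            raise ValueError("R amplitude must be >= 0")
        centers = [waves[k].center_s for k in "pqrst"]
        if self.r.center_s != 0.0:
            raise ValueError("R center must be 0 (waves are R-relative)")
        if not (centers[0] < centers[1] < 0.0 < centers[3] < centers[4]):
            raise ValueError("wave centers must satisfy P < Q < R=0 < S < T")

    def waves(self) -> dict[str, WaveParams]:
        return {"p": self.p, "q": self.q, "r": self.r, "s": self.s, "t": self.t}


#: Plausible term-neonate fixture morphology (conventional amplitudes; the
#: ratio features downstream are amplitude-scale invariant).  Defined at a
#: nominal RR of 0.5 s (HR 120); T timing is Bazett-adapted to the actual RR.
NEONATAL_TEMPLATE = BeatTemplateParams(
    p=WaveParams(0.15, -0.095, 0.016),
    q=WaveParams(-0.08, -0.025, 0.010),
    r=WaveParams(1.00, 0.000, 0.012),
    s=WaveParams(-0.15, 0.025, 0.010),
    t=WaveParams(0.25, 0.180, 0.030),
)

#: RR (s) at which template timing is defined; T timing scales as sqrt(RR/this).
TEMPLATE_RR_S = 0.5


@dataclass(frozen=True)
class NoiseConfig:
    """Additive artifact model: baseline wander + mains interference + EMG.

    All amplitudes in mV; ``emg_sd_mv`` is the standard deviation of white
    broadband muscle noise.  Deterministic for a fixed ``seed``.
    """

    baseline_amplitude_mv: float = 0.05
    baseline_freq_hz: float = 0.25
    powerline_amplitude_mv: float = 0.02
    powerline_freq_hz: float = 50.0
    emg_sd_mv: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.baseline_amplitude_mv, self.powerline_amplitude_mv, self.emg_sd_mv) < 0:
            raise ValueError("noise amplitudes must be >= 0")


@dataclass(frozen=True)
class GroupSpec:
    """Per-group generative parameters, all relative to the normal group."""

    ph_range: tuple[float, float]
    mean_hr_bpm: float = 140.0
    t_amplitude_mult: float = 1.0
    tslope_mult: float = 1.0
    qt_mult: float = 1.0


def _default_groups() -> dict[str, GroupSpec]:
    return {
        "acidosis": GroupSpec(ph_range=(6.90, 7.199)),
        "normal": GroupSpec(ph_range=(7.20, 7.45)),
        "alkalosis": GroupSpec(ph_range=(7.451, 7.70)),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs for a synthetic cohort.

    Defaults mirror the retained-segment group sizes of the clinical study
    design this package emulates (9 acidosis / 83 normal / 16 alkalosis) and
    a term-neonate HR band.  Between-record physiological spread is
    log-normal on T amplitude and T slope (``t_amplitude_cv``) and on QT
    (``qt_cv``), plus a normal HR spread (``hr_sd_bpm``); these give every
    feature a continuous null distribution.
    """

    group_sizes: tuple[int, int, int] = (9, 83, 16)
    groups: dict[str, GroupSpec] = field(default_factory=_default_groups)
    hr_sd_bpm: float = 12.0
    t_amplitude_cv: float = 0.15
    tslope_cv: float = 0.10
    qt_cv: float = 0.04
    rr_jitter: float = 0.02
    duration_s: float = 30.0
    fs_hz: float = 256.0
    template: BeatTemplateParams = NEONATAL_TEMPLATE
    noise: NoiseConfig | None = NoiseConfig()
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "group_sizes", tuple(self.group_sizes))
        defaults = _default_groups()
        groups = dict(defaults)  # partial overrides keep the other groups
        for k, v in self.groups.items():
            if isinstance(v, dict):
                v = dict(v)
                if "ph_range" in v:
                    v["ph_range"] = tuple(v["ph_range"])
                elif k in defaults:
                    v["ph_range"] = defaults[k].ph_range
                v = GroupSpec(**v)
            groups[k] = v
        object.__setattr__(self, "groups", groups)
        if isinstance(self.noise, dict):
            object.__setattr__(self, "noise", NoiseConfig(**self.noise))
        if any(n < 0 for n in self.group_sizes):
            raise ValueError("group sizes must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration must be > 0")
        if self.fs_hz <= 200.0:
            raise ValueError("sampling rate must exceed 200 Hz (2x low-pass cutoff)")
        lo, hi = self.groups["acidosis"].ph_range
        if hi >= 7.20:
            raise ValueError("acidosis pH range must lie below 7.20")
        lo, hi = self.groups["alkalosis"].ph_range
        if lo <= 7.45:
            raise ValueError("alkalosis pH range must lie above 7.45")
        lo, hi = self.groups["normal"].ph_range
        if lo < 7.20 or hi > 7.45:
            raise ValueError("normal pH range must lie within [7.20, 7.45]")


@dataclass
class GroundTruth:
    """Per-beat and per-record truth for parameter-recovery testing."""

    r_times_s: np.ndarray
    qt_s: float
    t_amplitude_mv: float
    tslope_mv_per_s: float
    hr_bpm: float
    ph: float
    group: str

    def __post_init__(self) -> None:
        if np.any(np.diff(self.r_times_s) <= 0):
            raise ValueError("R times must be strictly increasing")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "r_times_s": [float(t) for t in self.r_times_s],
            "qt_s": self.qt_s,
            "t_amplitude_mv": self.t_amplitude_mv,
            "tslope_mv_per_s": self.tslope_mv_per_s,
            "hr_bpm": self.hr_bpm,
            "ph": self.ph,
            "group": self.group,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _gaussian(t: np.ndarray, wave: WaveParams) -> np.ndarray:
    z = (t - wave.center_s) / wave.width_s
    return wave.amplitude_mv * np.exp(-0.5 * z * z)


def _template_value(params: BeatTemplateParams, t: np.ndarray) -> np.ndarray:
    """Noise-free continuous template evaluated at R-relative times ``t``."""
    out = np.full_like(t, params.baseline_mv, dtype=float)
    for wave in params.waves().values():
        out += _gaussian(t, wave)
    return out


def true_qrs_onset(params: BeatTemplateParams, frac: float = 0.1) -> float:
    """QRS onset of the clean template, R-relative seconds (negative).

    Onset is where the template's absolute derivative, scanned backwards from
    the maximum upslope, first drops below ``frac`` of the maximum absolute
    derivative in the pre-R window [R - 80 ms, R) -- the same convention the
    delineator applies to measured cycles.  Solved on a 0.1 ms grid.
    """
    t = np.arange(-0.080, 0.0, 1e-4)
    y = _template_value(params, t)
    d = np.gradient(y, t)
    imax = int(np.argmax(np.abs(d)))
    thresh = frac * np.abs(d[imax])
    below = np.nonzero(np.abs(d[:imax]) < thresh)[0]
    if below.size == 0:
        return float(t[0])
    return float(t[below[-1]])


def beat_ground_truth(params: BeatTemplateParams) -> dict[str, float]:
    """Analytic per-beat truth: T amplitude, max descending T slope, QT.

    Tslope is signed: negative for an upright T (the post-peak limb descends
    toward baseline), positive for an inverted T.  T-end is the exact
    Gaussian tangent intersection ``c_T + 2 w_T``.
    """
    t = params.t
    tslope = -t.amplitude_mv * _GAUSS_SLOPE / t.width_s
    t_end = t.center_s + 2.0 * t.width_s
    onset = true_qrs_onset(params)
    return {
        "t_amplitude_mv": t.amplitude_mv,
        "tslope_mv_per_s": tslope,
        "t_end_s": t_end,
        "qrs_onset_s": onset,
        "qt_s": t_end - onset,
    }


def generate_beat(
    params: BeatTemplateParams, rr: float, fs: float
) -> tuple[np.ndarray, dict[str, float]]:
    """Sample one cardiac cycle spanning [R - 0.3*rr, R + 0.7*rr).

    Returns ``round(rr * fs)`` samples and the analytic ground-truth dict
    (see :func:`beat_ground_truth`).
    """
    if rr < 0.25:
        raise ValueError("rr must be >= 0.25 s")
    if fs < 128:
        raise ValueError("fs must be >= 128 Hz")
    if params.t.center_s + 3.0 * params.t.width_s > 0.7 * rr:
        raise DegenerateMorphologyError(
            "T wave extends past the cycle boundary (T center + 3 widths > 0.7 rr)"
        )
    if params.p.center_s - 3.0 * params.p.width_s < -0.3 * rr:
        raise DegenerateMorphologyError("P wave extends before the cycle start")
    n = int(round(rr * fs))
    t = np.arange(n) / fs - 0.3 * rr
    return _template_value(params, t), beat_ground_truth(params)


def _rate_adapted_template(
    base: BeatTemplateParams,
    rr: float,
    t_amplitude_mv: float,
    tslope_mv_per_s: float,
    qt_s: float,
) -> BeatTemplateParams:
    """Re-parameterize the T wave to hit target amplitude, slope and QT.

    Width follows from amplitude and slope (|slope| = a e^{-1/2} / w); the
    center is then placed so that onset-to-tangent-T-end equals the target QT.
    """
    w = abs(t_amplitude_mv) * _GAUSS_SLOPE / abs(tslope_mv_per_s)
    onset = true_qrs_onset(base)
    center = qt_s + onset - 2.0 * w
    if center <= base.s.center_s + 2 * base.s.width_s:
        raise DegenerateMorphologyError("target QT places the T wave inside the QRS")
    return replace(base, t=WaveParams(t_amplitude_mv, center, w))


def draw_record_params(
    cohort: CohortConfig, group: str, rng: np.random.Generator
) -> dict[str, float]:
    """Draw one record's physiological parameters for ``group``.

    This is the generative layer shared by waveform synthesis and the
    parameter-level null-calibration harness: HR ~ Normal(group mean, sd),
    pH ~ Uniform(group range), T amplitude / T slope / QT log-normal around
    the template values times the group's effect multipliers, with QT
    additionally Bazett rate-adapted (scaled by sqrt(RR / 0.5 s)).
    """
    spec = cohort.groups[group]
    hr = float(np.clip(rng.normal(spec.mean_hr_bpm, cohort.hr_sd_bpm), 80.0, 220.0))
    rr = 60.0 / hr
    ph = float(rng.uniform(*spec.ph_range))
    base = beat_ground_truth(cohort.template)
    rate = np.sqrt(rr / TEMPLATE_RR_S)
    t_amp = (
        cohort.template.t.amplitude_mv
        * spec.t_amplitude_mult
        * float(rng.lognormal(0.0, cohort.t_amplitude_cv))
    )
    tslope = (
        base["tslope_mv_per_s"]
        * spec.tslope_mult
        * (t_amp / cohort.template.t.amplitude_mv if cohort.template.t.amplitude_mv else 1.0)
        * float(rng.lognormal(0.0, cohort.tslope_cv))
    )
    qt = base["qt_s"] * spec.qt_mult * rate * float(rng.lognormal(0.0, cohort.qt_cv))
    return {"hr_bpm": hr, "ph": ph, "t_amplitude_mv": t_amp, "tslope_mv_per_s": tslope, "qt_s": qt}


def synthesize_feature_table(config: CohortConfig, seed: int | None = None) -> "pd.DataFrame":
    """Cohort feature table from the generative layer, without waveforms.

    Draws each record's physiological parameters (:func:`draw_record_params`)
    and maps them to the ten-feature row algebraically -- no synthesis,
    filtering or delineation.  With all effect multipliers at 1.0 the group
    label is independent of every feature, which makes this the cohort-level
    null model for statistical calibration at scale.
    """
    import pandas as pd

    from .features import FEATURE_COLUMNS

    rng = np.random.default_rng(config.seed if seed is None else seed)
    base = beat_ground_truth(config.template)
    qrs_pp = config.template.r.amplitude_mv + abs(
        min(config.template.q.amplitude_mv, config.template.s.amplitude_mv)
    )
    rows = []
    for group, size in zip(GROUP_LABELS, config.group_sizes):
        for i in range(size):
            p = draw_record_params(config, group, rng)
            rr = 60.0 / p["hr_bpm"]
            t_amp, tslope, qt = p["t_amplitude_mv"], p["tslope_mv_per_s"], p["qt_s"]
            rows.append({
                "segment_id": f"{group}{i:03d}",
                "t_qrs": t_amp / qrs_pp,
                "t_amplitude": t_amp,
                "tslope": tslope,
                "tslope_t": tslope / t_amp,
                "tslope_abs_t": tslope / abs(t_amp),
                "tslope_sqrt_abs_t": tslope / np.sqrt(abs(t_amp)),
                "hr": p["hr_bpm"],
                "qt": qt,
                "qtc": qt / np.sqrt(rr),
                "rravg": rr,
                "ph": p["ph"],
                "group": group,
            })
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def synthesize_record(
    cohort: CohortConfig, group: str, seed: int
) -> tuple[ECGRecord, GroundTruth, "pd.DataFrame"]:
    """Synthesize one clean two-channel record for ``group``.

    One blood-gas event (the record's pH) is placed at the record midpoint so
    that both a preceding and a following 10 s segment exist.  Channel 2 is a
    scaled copy of channel 1 (0.85x), a crude stand-in for a second chest
    lead.  Deterministic for a fixed seed.
    """
    import pandas as pd

    if group not in GROUP_LABELS:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    params = draw_record_params(cohort, group, rng)
    rr_nominal = 60.0 / params["hr_bpm"]
    template = _rate_adapted_template(
        cohort.template,
        rr_nominal,
        params["t_amplitude_mv"],
        params["tslope_mv_per_s"],
        params["qt_s"],
    )

    # strictly increasing R times with multiplicative log-normal jitter
    r_times = []
    t = 0.35 * rr_nominal
    sigma = cohort.rr_jitter
    while t < cohort.duration_s - 0.3 * rr_nominal:
        r_times.append(t)
        jitter = float(rng.lognormal(-0.5 * sigma * sigma, sigma)) if sigma > 0 else 1.0
        t += rr_nominal * jitter
    r_times = np.asarray(r_times)

    n = int(round(cohort.duration_s * cohort.fs_hz))
    time = np.arange(n) / cohort.fs_hz
    ch1 = np.full(n, template.baseline_mv)
    for r in r_times:
        for wave in template.waves().values():
            lo = int(np.floor((r + wave.center_s - 5 * wave.width_s) * cohort.fs_hz))
            hi = int(np.ceil((r + wave.center_s + 5 * wave.width_s) * cohort.fs_hz)) + 1
            lo, hi = max(lo, 0), min(hi, n)
            if hi > lo:
                ch1[lo:hi] += _gaussian(time[lo:hi] - r, wave)
    data = np.column_stack([ch1, 0.85 * ch1])
    record = ECGRecord(data=data, fs=cohort.fs_hz, start_time=0.0)

    truth = GroundTruth(
        r_times_s=r_times,
        qt_s=params["qt_s"],
        t_amplitude_mv=params["t_amplitude_mv"],
        tslope_mv_per_s=params["tslope_mv_per_s"],
        hr_bpm=params["hr_bpm"],
        ph=params["ph"],
        group=group,
    )
    events = pd.DataFrame({"time_s": [cohort.duration_s / 2.0], "ph": [params["ph"]]})
    return record, truth, events


def add_noise(record: ECGRecord, noise: NoiseConfig) -> ECGRecord:
    """Add baseline wander, mains interference and broadband EMG noise.

    Strictly additive: subtracting the same realization recovers the input
    bit-exactly.  Sinusoid phases and the EMG stream are independent across
    channels but fully determined by ``noise.seed``.
    """
    rng = np.random.default_rng(noise.seed)
    n, n_ch = record.data.shape
    t = record.time()
    noisy = record.data.copy()
    for c in range(n_ch):
        phase_bw, phase_pl = rng.uniform(0, 2 * np.pi, size=2)
        noisy[:, c] = (
            noisy[:, c]
            + noise.baseline_amplitude_mv * np.sin(2 * np.pi * noise.baseline_freq_hz * t + phase_bw)
            + noise.powerline_amplitude_mv * np.sin(2 * np.pi * noise.powerline_freq_hz * t + phase_pl)
            + noise.emg_sd_mv * rng.standard_normal(n)
        )
    return ECGRecord(data=noisy, fs=record.fs, start_time=record.start_time)


def generate_cohort(
    config: CohortConfig,
) -> list[tuple[ECGRecord, GroundTruth, "pd.DataFrame"]]:
    """Generate the full cohort: records per group as configured.

    Per-record seeds are spawned deterministically from the master seed via
    ``numpy.random.SeedSequence``, so cohorts are reproducible and records
    are independent.
    """
    ss = np.random.SeedSequence(config.seed)
    total = sum(config.group_sizes)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * total)]
    out = []
    i = 0
    for group, size in zip(GROUP_LABELS, config.group_sizes):
        for _ in range(size):
            rec, truth, events = synthesize_record(config, group, child_seeds[2 * i])
            if config.noise is not None:
                rec = add_noise(rec, replace(config.noise, seed=child_seeds[2 * i + 1]))
            out.append((rec, truth, events))
            i += 1
    return out
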
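# Methods

`neoecg` implements an analysis chain for a clinical question: can
morphological ECG features characterize blood pH — and hence acid–base
status — in neonates monitored for birth asphyxia?  The chain turns
two-channel bedside ECG plus an intermittent blood-gas event table into ten
per-segment morphology features and a three-group nonparametric comparison
(acidosis pH < 7.20, normal 7.20–7.45, alkalosis pH > 7.45).  Because real
neonatal recordings of this kind are not publicly available, the package
ships a synthetic-cohort generator with analytic ground truth; every
accuracy claim below is measured against that generator.

## Synthetic cohort model

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) on a flat
baseline.  This is the simplest beat model for which the quantities the
feature stage must recover have (near-)closed forms:

* a Gaussian wave `a·exp(−(t−c)²/(2w²))` attains its extremal slope
  `a·e^(−1/2)/w` exactly one width past the center, and the tangent drawn
  there meets the baseline at `c + 2w` — the tangent-method T-end;
* the QRS-onset convention used by the delineator (derivative falling below
  10% of its in-QRS maximum) has no closed form for the Q+R composite, so
  the true onset is solved on a 0.1 ms grid on the noise-free continuous
  template.

Ground truth is therefore *what an ideal delineator would measure on the
clean template*.  Recovery errors reported by the harness isolate pipeline
degradation (filtering, detection, resampling, PCA averaging) rather than
mixing in an arbitrary alternative definition of QT.

Default template (amplitudes conventional — all ratio features are
scale-invariant): R 1.0 mV (σ 12 ms), Q −0.08 mV, S −0.15 mV (σ 10 ms),
P 0.15 mV (σ 16 ms, center −95 ms), T 0.25 mV (σ 30 ms) placed so the QT
(onset → tangent T-end) is ≈ 0.27 s at RR 0.5 s.  T timing and width are
Bazett rate-adapted (scaled by √(RR/0.5 s)) so the T wave stays inside the
cycle across the neonatal band.

Cohort defaults mirror the study design the package emulates: group sizes
9/83/16 (acidosis/normal/alkalosis), HR ~ Normal(140, 12) bpm clipped to
[80, 220], pH uniform in the group's interval, multiplicative log-normal
between-record spread on T amplitude (CV 0.15), T slope (CV 0.10) and QT
(CV 0.04), and multiplicative RR jitter (log-normal, σ 0.02).  These
spreads are what give every feature a continuous null distribution; they
are fixture choices, not clinical estimates.  Group effects enter as
multiplicative factors on T amplitude, T slope and QT relative to the
normal group (all 1.0 ⇒ a null cohort in which labels are independent of
features).

Noise is strictly additive, per the three artifact classes the filter
cascade targets: sinusoidal baseline wander (default 0.05 mV at 0.25 Hz),
50 Hz mains interference (0.02 mV), and white broadband EMG (sd 0.01 mV).
One blood-gas event is placed mid-record so both a preceding and a
following 10 s segment exist.  Per-record seeds are spawned from the master
seed with `numpy.random.SeedSequence`; identical configuration + seed is
bit-identical.

What the generator does **not** emulate: electrode-motion step artifacts,
arrhythmia, beat-to-beat morphology variation (T-wave alternans), ST-segment
shifts, multi-lead projection geometry, and non-stationary noise.  Passing
tests therefore demonstrate correctness of the pipeline's signal-processing
and statistical contracts, not clinical performance on real neonatal data.

## Preprocessing

10 s segments adjacent to each event ([t−10, t) and [t, t+10)); truncated
edge segments are kept when ≥ 8 s.  Filter cascade, applied
forward–backward (zero phase) so fiducial timing is unbiased: 4th-order
Butterworth high-pass at 0.5 Hz, 4th-order low-pass at 100 Hz, 50 Hz notch
(Q = 30), then Savitzky–Golay smoothing (window 15 samples ≈ 59 ms at
256 Hz, order 3).  Orders, Q and the smoother window are conventional ECG
choices; all are configurable.  Amplitudes are then min–max normalized to
[0, 1] with the affine map stored, so detection operates on normalized
traces while amplitude features are computed on recovered physical mV.

## QRS detection and gating

Classic Pan–Tompkins stages: 5–15 Hz band-pass (zero-phase), five-point
derivative, squaring, 150 ms centered moving-window integration, dual
adaptive thresholds (THR = noise + 0.25·(signal − noise), running
exponential level updates), 200 ms refractory, and search-back at half
threshold when a beat is overdue by 1.66× the running RR average.  Levels
initialize from percentiles of the integrated signal itself, making
detection invariant to positive amplitude scaling.  Detections refine to
the local maximum of the filtered waveform.  Two guards remove artifacts
of finite segments: candidates without QRS-band support (band-passed
amplitude below 30% of the median detected beat) are dropped, and no call
is made within one integration window (150 ms) of a segment edge, where a
boundary-truncated QRS masquerades as an ectopic beat.  Detection metrics
score events outside that edge zone, matched against the full beat lists.

QRS onset/offset use a 10%-of-maximum derivative criterion on the
band-passed signal.  The scan starts from the point of steepest up/down
slope rather than from the R apex: the derivative is ≈ 0 at the apex
itself, so a scan anchored at R would terminate immediately.  Q and S are
the waveform minima between onset→R and R→offset.

A segment is rejected when any rule fires: fewer than 6 beats per 10 s,
implied HR outside [60, 250] bpm, any RR > 1.8× the median RR (missed
cycle), or RR coefficient of variation > 0.25.  Thresholds are this
package's choices and are configurable.

## Representative cycle

Interior beats (first/last dropped) are cut on [R − 0.3·RRAvg,
R + 0.7·RRAvg] — the 30/70 split keeps a rate-adapted T inside the cycle
across the neonatal band — and linearly resampled to M = 256 phase
samples.  The sample covariance across cycles is eigen-decomposed (SVD of
the centered matrix); the representative is the mean cycle plus the
leading component scaled by the mean score, with the eigenvector sign
fixed by positive correlation with the mean cycle, and the retained
component's variance fraction reported.  A degenerate matrix (identical
columns) returns that column with variance fraction 1.  At least 3 usable
cycles are required.

## T-wave delineation and features

On the physical-scale representative cycle: search window
[R + 80 ms, R + 0.6·RRAvg]; T peak is the extremum of largest absolute
baseline-relative amplitude (kept signed, so inverted T waves are
negative); Tslope is the steepest signed slope of the limb returning to
baseline, from least-squares line fits over a 20 ms sliding window; T-end
by the tangent method; QT from QRS onset to T-end; QTc = QT/√RRAvg
(Bazett, RRAvg in seconds).

Two numerical choices deserve explanation:

* **Slope window 20 ms.**  For a Gaussian T of width w the least-squares
  slope over a window of half-width h centered at the steepest point
  approximates the mean derivative there, `a·[g(w+h) − g(w−h)]/(2h)`.
  At the neonatal default w = 30 ms a 40 ms window underestimates the
  extremal slope by ≈ 14%; a 20 ms window by ≈ 3%.  The window must stay
  short relative to the narrow neonatal T wave.

* **Isoelectric baseline: median of three anchors.**  The PQ junction, the
  early ST segment, and the end-of-cycle diastolic tail, each estimated as
  the flattest (minimum-sd) 12 ms window of its search region.  At
  neonatal rates any single anchor can be contaminated — the P tail and Q
  rise crowd the short PR segment, the high-pass leaves a residual droop
  just before the QRS, and a rate-adapted T crowds the ST segment and the
  tail — but rarely all three in the same direction, so their median is
  robust.  On clean default cohorts this brings the median T-amplitude
  error to ≈ 3% (a single PR-segment median is biased −5…−7%).

Features per segment: T/QRS (T amplitude over QRS peak-to-peak, R minus
the deeper of Q/S), T amplitude, Tslope, Tslope/T, Tslope/|T|,
Tslope/√|T|, HR, QT, QTc, RRAvg.  A zero T amplitude records the ratio
features as missing, never infinite.

Measured accuracy on the clean default cohort (30 records): median |HR
error| ≈ 0.4 bpm, |QT error| ≈ 7 ms, T amplitude ≈ 3–4% relative, Tslope
≈ 4% of the analytic value.  Known limitation: above ≈ 165 bpm the cycle
has no isoelectric gap anywhere (P–QRS–T–P fully congested) and
T-amplitude accuracy degrades to ≈ 8–10%.

## Group statistics

Tie-corrected Kruskal–Wallis omnibus per feature
(H = [12/(N(N+1))]·Σ nᵢ(r̄ᵢ − (N+1)/2)² / (1 − Σ(t³−t)/(N³−N)), chi-square
with k−1 df; all-identical values define H = 0, p = 1), followed — only
when the omnibus p < α, matching the conditional post-hoc convention —
by Dunn pairwise z-tests with the tie-corrected standard error and Šidák
adjustment p' = 1 − (1−p)^m over the m = k(k−1)/2 pairs.  Simultaneous
comparison intervals use α* = 1 − (1−α)^(1/m); by construction
"adjusted p < α" and "interval excludes 0" coincide exactly.  Boundary pH
values 7.20/7.45 map to normal (flag to switch).  Quartiles are linear
interpolation (type 7).  No multiplicity correction is applied *across*
the ten features, matching the emulated analysis design.

## Evaluation harnesses and problem sizes

`neoecg.harness` regenerates every headline metric from scratch; problem
sizes are desk-scale choices: detection over 50 seeded segments spanning
HR 100–180; recovery over 30 clean records; PCA fidelity over 20 noisy
cycle matrices at SNR 10 dB; null calibration over 1000 simulated cohorts
at the 9/83/16 group sizes — simulated at the cohort-parameter level (the
generator's per-record draws with all effect multipliers 1.0), since the
type-I error of the rank tests depends only on label–feature independence,
not on the waveform rendering around it; and end-to-end effect detection
over 200 full waveform-pipeline runs per arm with 21 s records.  The
effect arm halves the acidosis group's T amplitude; the null arm sets all
multipliers to 1.0.

## Known limitations

* The generator's stereotyped Gaussian morphology makes delineation easier
  than real neonatal ECG; accuracy numbers are upper bounds.
* WFDB input requires the optional `wfdb` package; the native format is
  plain CSV.
* The quality gate's thresholds target gross failure (flat leads, missed
  cycles), not graded signal-quality indices.
* Chi-square reference for H is asymptotic; with the smallest group at
  n = 9 the measured type-I error is ≈ 0.044 at α = 0.05 (slightly
  conservative), per the calibration harness.
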
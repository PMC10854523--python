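# Methods

## Signal model of the synthetic generator

Each simulated channel is

```
x(t) = A_theta cos(theta(t))
     + A_hf [ (1 - chi) + chi (1 + cos(theta(t) - phi)) / 2 ] sin(2 pi f_A t)
     + eps(t)
```

with coupling depth `chi` in [0, 1], preferred phase `phi`, and white Gaussian
noise `eps` (an optional pink-noise flag substitutes 1/f-shaped noise). The
raised-cosine amplitude law yields a unimodal phase–amplitude distribution;
at `chi = 0` the fast envelope is constant (no coupling), at `chi = 1` it
vanishes at the anti-preferred phase. The slow carrier is written as a
cosine of its instantaneous phase so that the Hilbert phase of the filtered
theta equals `theta(t)` and the envelope peak falls exactly at phase `phi` —
the quantity the circular analysis is supposed to recover.

The theta phase is quasi-periodic, not strictly sinusoidal:
`theta(t) = 2 pi f_p t + 2 pi ∫ d(s) ds`, where the instantaneous-frequency
deviation `d` is an Ornstein–Uhlenbeck process (SD 0.5 Hz, correlation time
0.5 s by default). This matters twice. First, real hippocampal theta
wanders in frequency, and a smooth wander leaves the theta spectrum
concentrated near `f_p` without leaking power into distant amplitude bands.
Second, the circular time-shift surrogate is only a valid null when the
phase decorrelates over the shift: shifting a strictly periodic carrier
merely rotates the preferred phase and leaves MI unchanged, which would make
surrogate thresholds meaningless.

Default amplitudes are a 50 µV theta, a 10 µV fast band, and 15 µV noise SD —
plausible for hippocampal LFP; no published amplitude calibration exists for
pigeon recordings, so these are stated conditions rather than fitted values.
Simulated GPS tracks march from the release point toward the loft at a
nominal 15 m/s with per-fix ground-speed variability (SD 1.5 m/s) and
Gaussian lateral jitter (20 m default); speed variability is required for
any speed-correlation analysis to be defined, and it is generated
independently of coupling depth so the speed–MI null holds by construction.
All generators require an explicit seed; unseeded calls raise.

Maze sessions inject the configured coupling only inside each event's
analysis window at navigation positions and an uncoupled (depth-0) fast band
at the goal position; flight sessions couple the designated channel only
while the concurrent GPS fix is in the chosen phases (ER by default). What
the generator does **not** emulate: 1/f background by default, movement and
muscle artifacts, non-sinusoidal theta waveform asymmetry (a known source of
spurious PAC in real data), volume conduction between channels, or
electrode drift. Passing tests therefore demonstrate that the estimator
chain recovers known coupling under realistic noise — not that real
recordings are free of those confounds.

## The coupling estimator

The pipeline follows the standard KL-modulation-index recipe: 4th-order
Butterworth band-pass applied forward–backward (zero phase), Hilbert
analytic signal for phase and envelope, 50 ms trimmed from each end of every
extracted series, phase binned into 18 × 20° bins with edges starting at
−180°, mean envelope per bin normalized to the distribution P, and
`MI = (log N − H(P)) / log N` with natural logs and `0 log 0 = 0`. An epoch
whose phase series leaves any bin empty raises rather than returning a
biased P. MI values are clamped to [0, 1] against float round-off at the
endpoints.

Comodulograms use phase bands of center ± 1 Hz and amplitude bands of center
± 15 Hz — wide enough to pass the modulation sidebands at `f_A ± f_p`. Cells
whose band would reach 0 Hz or Nyquist are NaN, never silently zero. For the
same sideband reason, the epoch pipeline extracts amplitude with the band of
interest widened by the top of the phase band on each side
(`AnalysisConfig.amp_filter_band`): the flight bands (theta 5–10 Hz, beta2
20–30 Hz) would otherwise place the sidebands outside the filter and destroy
the coupling being measured. `mi_for_pair` filters exactly the requested
band, so callers control the trade-off explicitly.

Per-epoch MI values are averaged within session before any cross-session
averaging; comodulograms inside the pipeline are means of per-epoch maps.
The cross-trial statistic is the Pearson correlation (Spearman available via
config) between a trial's P and the standard distribution — the renormalized
bin-wise mean P of the reference condition (first navigation position /
ER on the first path). Correlation of a zero-variance (uniform) P is
undefined and reported as NaN, never 0. The surrogate null circularly
shifts the envelope relative to the phase by a uniform random offset of at
least 100 ms, preserving both marginals while destroying their alignment.

## Behavioral segmentation

Maze epochs are 1000 ms windows from 250 ms before to 750 ms after each
infrared-detector first contact (repeat contacts within 1 s are collapsed);
windows running off the recording are dropped with a logged reason. Maze
speed is detector spacing divided by crossing interval, with the geometry
user-supplied. Flights split by distance: decision-making (DM) within 300 m
of the release site, local navigation (LN) within 200 m of the loft,
en route (ER) between. Labels partition every track; in the (geometrically
irrelevant) case of overlapping radii the tie resolves temporally. Flight
epochs are non-overlapping 1 s windows labeled by their fixes; windows whose
fixes span a phase boundary are dropped. DM epochs are computed but excluded
from coupling statistics by default (the bird is still choosing a
direction); a config flag includes them. Trajectory similarity is the
symmetric mean nearest-neighbor haversine distance (Earth radius 6371 km),
with < 200 m counting as the same path. Channels are screened per recording:
flat-run fraction > 10% or robust SD (1.4826 × MAD) above 5× the channel
median flags a channel; both thresholds are configurable since the field has
no standard criterion.

## Circular statistics and group tests

Fast-envelope peaks are local maxima above mean + 2 SD of the envelope
(threshold configurable; a height criterion presumes noisy envelopes and
degenerates on nearly noise-free synthetic signals — see the tests, which
exercise recovery at the generator's default noise). The summary is the mean
resultant vector `avgAng = atan2(Σ sin, Σ cos)`, `r = |Σ e^{iθ}|/n`, the
Fisher/Zar arccos-based 95% CI for the mean direction (undefined, and
flagged NaN, for dispersed samples), and the Rayleigh test `z = n r²` with
the small-sample approximation
`p = exp(√(1 + 4n + 4(n² − R²)) − (1 + 2n))`.

Group tests are two-sided throughout: Kruskal–Wallis (chi-square
approximation, df = k − 1) with Dunn's rank-mean z post hoc
(tie-corrected, Bonferroni-adjusted across pairs — the adjustment choice is
ours, as none is standard), Mann–Whitney U reporting min(U₁, U₂) and the
tie-corrected normal-approximation Z (p exact for small untied samples), and
Spearman rank correlation with NaN for constant input.

## Numerical choices and problem sizes

Phase convention: 0 at the positive peak (cosine convention), radians in
[−π, π) internally, degrees in displays. Welch PSDs use 1 s Hann windows at
50% overlap. Band-pass corners sit at −3 dB per pass (−6 dB zero-phase), so
"in band" means strictly inside the corners. Channel-selection ties break
to the lowest channel id and are logged. Config files are flat `key=value`
text; every exported CSV carries an MD5 hash of the config in a header
comment, and a fixed seed makes full pipeline runs byte-identical.

Tests and examples run on deliberately modest problem sizes — 10 s
continuous signals, sessions of 10–20 trials on 2–16 channels, single
flights of ~100 s, 20–200 surrogates, 2000 null replicates for test
calibration — chosen so the whole suite completes in well under a minute of
compute while every recovery margin (argmax hit, monotonicity, null
separation) remains wide.

## Known limitations

- The estimator battery is KL-MI only; mean-vector-length, GLM-PAC, and
  phase-locking alternatives are out of scope, as is cross-structure PAC.
- Pearson correlation across 18 bins has low resolution for distributions
  that differ only in fine structure.
- The bad-channel screen targets flatlines and gross amplitude artifacts; it
  will not catch subtler problems (line noise, intermittent ringing).
- Flight-epoch labeling assumes the neural and GPS clocks are already on one
  time base; no drift estimation is attempted.
- The generator's white/pink noise and sinusoidal fast carrier are idealized;
  none of the waveform-asymmetry confounds of real LFPs are modeled.
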
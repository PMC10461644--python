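# Methods

This note documents the models, estimators and numerical choices behind
`retinaphys`, and what the synthetic validations do and do not establish about
real recordings.

## Data model and formats

Recordings are uniform-rate multi-channel voltage traces (µV for
extracellular, mV for intracellular; no implicit conversion). Time is seconds
from recording start, samples are 0-based, and every window is half-open
`[start, end)`. Two trace formats round-trip bit-exactly: a columnar text file
(one header line with rate and channel names, one row per sample) and an HDF5
container (one chunked dataset per channel, metadata as attributes). Stimulus
logs are TSV tables of (onset, duration, wavelength, flux, background), where
flux is the step photon flux L_max and background the ambient L_min;
Michelson contrast C = (L_max − L_min)/(L_max + L_min), with a protocol
validator for the 0.8–0.9 band used in light-step experiments.

## mERG pipeline

The mERG band is isolated with a second-order Butterworth low-pass at 20 Hz
and decimated from 25 kHz to 5 kHz (integer factor; the 20 Hz band makes an
extra anti-alias stage unnecessary). Filtering is **zero-phase**
(forward–backward `sosfiltfilt`) by default so the A-wave trough latency is
not shifted by filter delay; note this squares the magnitude response, so a
sinusoid at the cutoff is attenuated 6.02 dB instead of 3.01 dB. A single-pass
mode is provided for comparison with causal-filter analyses.

A-wave amplitude is `min(v[onset, onset+50 ms)) − mean(v[onset−1 s, onset))`.
The "maximal negative deflection" is the *signed* minimum, not the extremum of
|v|: the A-wave is defined as photoreceptor-hyperpolarization-driven
negativity. The measure is invariant to any constant offset.

Bleach-recovery analysis groups per-electrode amplitudes by protocol stage
(`dark`, `post_bleach`, `recovered`), reports stage means and
`recovery % = 100·mean(recovered)/mean(dark)`, and compares stages with a
Friedman test (electrodes as subjects — each electrode is treated as an
independent unit) followed by pairwise Wilcoxon signed-rank tests with Holm
adjustment. Electrodes missing a stage are excluded and reported.

**Filter loss caveat.** Any trough reached within 50 ms of onset has spectral
content at ~10–20 Hz, where even the in-band gain of a 20 Hz Butterworth is
below unity. With the default synthetic trough (latency 30 ms, width
parameter 25 ms) the pipeline retains >97 % of the model depth; the estimator
noise floor is therefore assessed against the noiseless-pipeline amplitude
(the estimand within the mERG band), with the systematic in-band loss bounded
separately. Recovery *percentages* are ratios of identically filtered
amplitudes and are insensitive to this loss.

## Spike pipeline

The spike band is a 200 Hz second-order Butterworth high-pass. Detection uses
a per-channel negative threshold at −k·σ̂ (default k = 4) with the robust
noise scale σ̂ = median(|v|)/0.6745, one event per refractory window (default
1 ms), timestamped at the trough; extracellular somatic spikes are
negative-going, so only downward crossings are considered.

Unit separation is a deliberately simple, fully documented sorter: ±1 ms
trough-aligned snippets are projected on 2 principal axes and k-means
clustered for k ≤ 3; k is chosen by silhouette score and accepted only above
0.5, with two guards — channels with fewer than 10 events pass through as one
unit, and clusterings containing a cluster smaller than 10 events are
rejected (singleton outliers such as edge-truncated or overlapping spikes
otherwise form spurious high-silhouette clusters). This sorter separates
well-isolated units of distinct amplitude; it is not a substitute for
template-matching or density-based sorting of overlapping units.

Light responses are summarized from a trial-averaged PSTH (default bin
50 ms, chosen to resolve onset latencies on the 100–300 ms scale):

* basal rate = spikes in the 1 s pre-stimulus window per trial-second;
* response criterion = basal mean + 3·SD of the basal bin rates (with a
  one-spike-per-bin floor so silent baselines do not yield a zero criterion),
  and a response component must hold the criterion for **two consecutive
  bins** — a genuine transient (decay ≈ 150 ms) always spans several 50 ms
  bins, whereas isolated supra-criterion bins are Poisson flukes of the
  baseline that would otherwise promote a substantial fraction of pure ON or
  OFF cells to ON-OFF;
* onset = left edge of the first qualifying run; peak rate and time-to-peak
  from the PSTH maximum;
* class = ON if qualifying activity occurs only during the stimulus, OFF if
  only in the 500 ms after offset, ON-OFF if both.

Cohort tabulation reports per-class counts and fractions over classified
cells plus mean ± SD metric summaries.

## Intrinsic membrane properties

From one current-step family per cell (default steps 1 s long, analysis
windows expressed as fractions of the step):

* **V_m** — mean pre-injection voltage, averaged across sweeps (≥ 200 ms of
  baseline required).
* **R_n** — least-squares slope of (I, steady-state ΔV) over hyperpolarizing
  sweeps plus the implicit (0, 0) point; steady state is the last 20 % of the
  step; mV/nA = MΩ.
* **τ** — single-exponential least-squares fit to the charging trajectory of
  the weakest hyperpolarizing step. The initial τ guess uses the 63 %
  crossing of a 2 ms-smoothed trajectory (a raw-noise blip would collapse the
  fit window), the fit window is max(5·τ₀, 50 ms), and two quality gates
  raise a fit error rather than return nonsense: τ standard error exceeding τ
  itself, or fit-residual SD exceeding half the total deflection.
* **sag** — trough minus steady-state voltage at the strongest
  hyperpolarizing step; negative when hyperpolarization-activated
  rectification (I_h) relaxes the membrane back toward rest; exactly 0 for a
  pure RC cell.
* **steady / max frequency** — max over sweeps of spike count / step
  duration; steady rate over the final 500 ms of the maximal-rate sweep.
* **FA** — 1 − f_last/f_first at the maximal-rate sweep, with f_first/f_last
  the reciprocal first/last inter-spike intervals; clipped to [0, 1] and
  flagged if the cell accelerates. Chosen because it is bounded, increases
  with adaptation strength, and is strictly monotone in the simulator's
  adaptation increment.
* **amplitude / SW** — up to 100 spikes aligned at their peaks and averaged;
  threshold = first point where dV/dt exceeds 10 mV/ms before the peak;
  amplitude = peak − threshold; SW = full width at half amplitude by linear
  interpolation. The reference table labels the amplitude column in pA; the
  extractor measures a voltage difference and labels it as such.

Burst detection returns maximal runs of consecutive inter-spike intervals
≤ 10 ms (configurable) with ≥ 2 spikes; first-spike latencies after light
onset and offset quantify the fast-ON/slower-OFF asymmetry of ON-OFF
transient cells, with missing components returned as undefined rather than 0.

## Statistics

Normality gate: Shapiro-Wilk plus Lilliefors-corrected Kolmogorov-Smirnov
(parameters estimated from the sample; a plain KS test against fitted
parameters would be anti-conservative); "reject" requires both p < 0.05.
Mann-Whitney U uses the exact null distribution when the smaller sample has
≤ 8 observations and the pooled sample is tie-free, otherwise the
tie-corrected, continuity-corrected normal approximation. Friedman's
chi-square is followed by pairwise Wilcoxon signed-rank tests with Holm
adjustment — the post-hoc pair (Dunn-style, Holm) is an explicit choice and
configurable. The species comparison of per-cell intrinsic parameters uses
the pooled-variance two-sided Student t (the pooled form, not Welch,
reproduces the reference V_m comparison p = 0.029 exactly). Group summaries
are mean ± SEM. Two-sided tests at α = 0.05 throughout.

## Synthetic generators

All generators take one integer seed; a single `numpy` generator stream per
call drives every draw, so identical seeds give identical traces and
different seeds decorrelate noise but not ground truth.

**mERG forward model.** The unbleached-pigment fraction u starts at `u0`,
collapses to `bleach_floor` (0.05) after any epoch with flux ≥ `bleach_flux`,
and relaxes in darkness toward `rec_ceiling` as
`u(Δt) = c + (u − c)·e^(−Δt/τ_rec)` (recovery only; pigment does not bleach
in darkness). `rec_ceiling` is 1 with an intact visual cycle and ~0.1
without. Each light step renders a negative gamma-like trough of depth
`a_depth·u(onset)` peaking `a_latency` after onset, plus a smaller positive
late component, plus white noise. Defaults: depth −77.2 µV, latency 30 ms,
width 25 ms, noise 5 µV, τ_rec = 240 s — with the default protocol (bleach,
test at +15 s, test at +5 min) the 5-minute recovery fraction is ~0.73 and
the 15-s post-bleach amplitude ~11 % of dark. A single-exponential recovery
cannot simultaneously match both observed stage ratios; the 5-minute recovery
fraction was prioritized. Only the amplitude–bleach-state coupling is
meaningful ground truth; the kernel shapes are phenomenological, and no
phototransduction cascade or spectral sensitivity is modelled.

**RGC spike trains.** rate(t) = base + on_gain·k(t − onset − on_latency) +
off_gain·k(t − offset − off_latency) with exponential kernel k (decay
150 ms); draws by thinning a homogeneous Poisson process at the envelope
maximum, then enforcing an absolute refractory period (2 ms), which gives the
analytic equilibrium rate r/(1 + r·t_ref) for constant r. Class ground truth
follows the gains (ON / OFF / ON-OFF / none). Defaults: base 10 Hz, gains
60 Hz, ON latency 50 ms, OFF latency 80 ms. Synthetic cohorts use 10
stimulus repeats, the field-standard repetition count for PSTH estimation.

**Membrane model.** Exponential-integrator (exact per step for held drive)
leaky integrate-and-fire: τ_m dV/dt = −(V − E_L) + R_in·I + s − a, with sag
variable s relaxing toward `sag_gain·max(E_L − V, 0)` with τ_sag = 120 ms,
and adaptation drive a incremented per spike (decay τ_adapt = 250 ms). Spikes
are rendered as 1 ms symmetric triangles from threshold to `spike_peak`
followed by reset, giving an analytic half-width of exactly 0.5 ms.
Measurement noise is additive white noise on the recorded trace (`noise_sd`,
mV) — deliberately not process noise, whose τ_m-correlated structure mimics
the charging exponential and is not what an amplifier noise floor looks like.
Defaults mirror the bovine reference means (E_L = −56.5 mV, R_in = 141 MΩ,
τ_m = 35.2 ms).

## What the validations show — and what they do not

Estimator validations run on synthetic data with known ground truth:
noiseless passive-parameter recovery is exact to float precision, recovery at
0.5 mV white noise stays within 10 %, the classification accuracy of the
three-class mixture exceeds 90 %, and the intact-visual-cycle protocol always
recovers more than the RPE-removed one. Passive-parameter recovery is
validated on cells without sag: with an active sag conductance the
steady-state deflection is no longer R_in·ΔI, so the Ohmic ground truth
itself is ill-defined; sag extraction is validated separately (exactly zero
for pure RC, monotone in the sag gain). These checks validate the
*estimators*, not the biology: real recordings add drift, electrode
artifacts, correlated network activity, overlapping spike waveforms and
cell-to-cell kernel variability that the generators deliberately omit.

## Reproducibility

`scripts/acceptance.py --seed N --out results.json` recomputes every headline
quantity at run time; all randomness derives from the one seed. Problem sizes
(100 amplitude sweeps, 50 cells per noise level, 4 protocol seeds, 60
classification cells) are the package's validation defaults. CLI runs write a
JSON manifest with the full config, package version and input digests.
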
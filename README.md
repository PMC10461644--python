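# retinaphys

Analysis toolkit for ex vivo retina electrophysiology, built around the three
recording modalities of MEA + patch-clamp retina studies — in particular the
choroid-attached preparation, in which the retinal pigment epithelium (RPE)
stays apposed to the photoreceptors so the visual cycle keeps regenerating
photopigment after bleaching.

It is written for electrophysiologists who record:

1. **micro-ERGs (mERG)** — low-frequency field potentials on MEA electrodes.
   The initial negative deflection after a light step (the **A-wave**,
   photoreceptor hyperpolarization) indexes the pool of unbleached
   photopigment, so comparing its amplitude dark-adapted, right after a
   photobleach, and after dark recovery quantifies whether the visual cycle is
   intact.
2. **RGC spike responses** — retinal ganglion cell units extracted from the
   same MEA traces, summarized by basal rate, peak rate, response onset,
   time-to-peak, and ON / OFF / ON-OFF classification.
3. **whole-cell current clamp** — per-cell intrinsic membrane properties from
   current-step families: resting potential V_m, input resistance R_n,
   membrane time constant τ, sag, steady and maximal firing rate, frequency
   adaptation index FA, spike amplitude, and spike half-width SW.

## Methods in brief

* mERG band: second-order Butterworth low-pass at 20 Hz (zero-phase by
  default), down-sample 25 kHz → 5 kHz; A-wave amplitude = (signed minimum in
  the 50 ms after light onset) − (mean voltage over the 1 s before onset);
  recovery % = 100 · mean(recovered) / mean(dark), per-electrode stages
  compared with a Friedman test plus Holm-adjusted signed-rank pairs.
* Spike band: 200 Hz Butterworth high-pass; detection at −4·σ̂ with
  σ̂ = median(|v|)/0.6745; PCA + k-means unit separation (silhouette-selected
  k); PSTH-based response metrics with an onset criterion of basal mean +
  3 SD of basal bin rates held for two consecutive 50 ms bins.
* Intrinsic suite: R_n from the hyperpolarizing I–V slope, τ from a
  single-exponential charging fit, sag = trough − steady state at the
  strongest hyperpolarizing step, FA = 1 − f_last/f_first at the maximal-rate
  sweep, spike shape from the peak-aligned average of up to 100 spikes.
* Statistics: Shapiro-Wilk + Lilliefors-KS normality gate, exact
  small-sample Mann-Whitney, Friedman with post-hoc pairs, pooled-variance
  two-sided Student t, mean ± SEM group summaries.
* Synthetic module: forward models with known ground truth for all three
  modalities (bleach-state-coupled mERG, thinning-based inhomogeneous-Poisson
  spike trains with refractoriness, exponential-integrator LIF membranes with
  sag and adaptation), so every estimator is validated against parameters it
  should recover.

Michelson contrast of a light step is `C = (L_max − L_min)/(L_max + L_min)`;
the protocol validator expects C in [0.8, 0.9].

A per-cell reference table of the nine intrinsic parameters for bovine
(n = 10) and mouse (n = 9) alpha RGCs ships with the package
(`retinaphys.load_rgc_profiles()`).

## Worked example

```python
import retinaphys as rp
from retinaphys import merg, stats
from retinaphys.synthetic import MERGModel, simulate_merg
from retinaphys.cli import default_bleach_protocol

model = MERGModel()                      # intact visual cycle (rec_ceiling=1)
epochs = default_bleach_protocol(model)  # dark test, bleach, +15 s, +5 min
rec, truth = simulate_merg(model, epochs, rate=25000, seed=1, n_channels=4)

band = merg.downsample(merg.butterworth_filter(rec, merg.FilterSpec()), 5000)
results = []
for stage, ep in zip(("dark", "post_bleach", "recovered"),
                     [e for e in epochs if e.flux < model.bleach_flux]):
    results.extend(merg.a_wave_amplitude(band, ep, stage=stage))
out = merg.bleach_recovery_analysis(results)
print({s: round(m, 1) for s, m in out["stage_means"].items()})
print(round(out["recovery_pct"], 1))
```

prints

```
{'dark': -65.1, 'post_bleach': -6.9, 'recovered': -47.4}
72.8
```

i.e. the A-wave collapses to ~11 % of its dark-adapted amplitude right after
the bleach and recovers to ~73 % of it within five minutes of darkness — the
signature of an intact visual cycle. Re-running with
`MERGModel(rec_ceiling=0.1)` (RPE removed) leaves recovery near 10 %.

The same pipelines are available from the shell:

```sh
retinaphys simulate --modality merg --out sim/ --seed 1
retinaphys merg --trace sim/trace.h5 --stimlog sim/stimlog.tsv --out out/
retinaphys report --out report/     # group summary of the reference table
```

Every run writes a JSON manifest (config echo, input digests) beside its
outputs.

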
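# smdwell

Single-molecule TIRF microscopy measures how long individual fluorophore-
labeled enzymes stay bound to their substrate: each binding event appears
as a diffraction-limited spot that persists for some number of camera
frames and then vanishes. `smdwell` turns such image stacks into
per-molecule **binding lifetimes** and decomposes their distribution into
kinetic populations. It was built for interfacial enzyme kinetics — for
example cellobiohydrolases (Cel7A) acting on cellulose fibrils, where a
majority population unbinds within seconds while a minority is effectively
immobilized — but applies to any surface-binding dwell-time experiment
with stationary molecules.

The pipeline:

1. **simulate** — synthetic movies and ground-truth event lists (fibril
   geometries, mixture-of-exponentials dwells, photobleaching, blinking,
   drift, shot noise) for validation and testing;
2. **localize** — sub-pixel spot detection and pixel-integrated 2D
   Gaussian fitting with iterative joint refitting of overlapping spots;
3. **drift** — lateral stage-drift estimation from the localizations
   themselves by block-wise super-resolution cross-correlation;
4. **linking** — greedy nearest-neighbour association of localizations
   into binding events with gap (blinking) tolerance, plus censoring of
   events touching the first or last frame;
5. **masking** — super-resolution summed images, automatic fibril
   segmentation (or a user-drawn mask), and on-fibril vs background event
   classification;
6. **dwell** — the statistical core: multi-exponential dwell-time fits;
7. **kinetics** — dissociation rates, intrinsic processivity and
   translation distances derived from fitted residence times.

## The model

Dwell times are compiled into a histogram with bins of one frame interval
(right-open, starting at one frame). The expected count in bin *i* under
an *m*-component exponential mixture (m = 1–3) is

    mu_i = sum_j N_j [G_j(t_i) − G_j(t_{i+1})] / [G_j(t_min) − G_j(t_max)]

with `G_j(t) = exp(−t/tau_j)`, so `N_j` counts observed events of
component *j* inside the histogram support and the event fractions are
`f_j = N_j / Σ N_k`. When events are censored by dropping any that touch
the first or last frame of a movie of length *T*, the surviving dwells
follow `exp(−t/tau)(1 − t/T)` instead, and passing `window_s=T` uses
`G_j(t) = exp(−t/tau_j)(1 − (t + tau_j)/T)` — without this, long time
constants are biased low by ~15–20%.

The fit minimizes the Poisson deviance

    D = 2 Σ_i [ y_i ln(y_i/mu_i) − (y_i − mu_i) ]

by differential evolution over `(log tau_j, N_j)` followed by a
Nelder–Mead polish; goodness of fit is judged by the calibrated reduced
deviance `D / E[D]` (≈1 for an adequate model at any bin occupancy), and
the number of components by a sequential deviance (likelihood-ratio) test
with guards against indistinct components. Components whose fitted time
constant matches a photobleach lifetime of the dye are flagged
**bleach-limited**: those molecules outlived their label, so tau is only
a lower bound and their pooled fraction is reported as "immobilized".

## Worked example

Simulate an intact-enzyme experiment (81% short-lived at 15 s, 19%
immobilized, Cy5 bleach lifetimes 195 s / 1100 s, 2500 frames at 1 s),
censor, and fit three components:

```python
import numpy as np
from smdwell import (SimulationTruth, PopulationSpec, BleachModel,
                     simulate_event_list, ExponentialMixtureModel, kinetics_report)

truth = SimulationTruth(
    populations=[PopulationSpec(0.81, 15.0), PopulationSpec(0.19, immobilized=True)],
    bleach=BleachModel.oxygen_scavenged(),
    arrival_rate_fibril=2.0, n_frames=2500, seed=0,
)
events = simulate_event_list(truth)
durations = np.array([
    e.n_frames_obs * truth.frame_interval_s for e in events
    if e.start_frame > 0 and e.start_frame + e.n_frames_obs - 1 < truth.n_frames - 1
])
model = ExponentialMixtureModel(durations, bleach=truth.bleach, window_s=2500.0)
result = model.fit(3, seed=0)
print(result.summary())
```

```
Exponential mixture dwell-time fit
======================================================
components:       3
events (binned):  4782
deviance:         1136.68
reduced deviance: 0.521  (dof=2180)
calibrated D/E[D]: 1.006
converged:        True   seed=0
------------------------------------------------------
comp    tau (s)  fraction       N_j  bleach-limited
   1       14.8     0.859    4110.0  no
   2        251     0.101     481.2  yes
   3   1.18e+03     0.040     190.8  yes
------------------------------------------------------
immobilized fraction: 0.141
```

The short-lived population is recovered at 14.8 s (truth 15 s) and the
two long components sit at the Cy5 bleach lifetimes, so they are flagged
bleach-limited and pooled as immobilized. The observed short fraction
(0.859) exceeds the generating 0.81 because immobilized events are more
likely to overlap the end of the movie and be censored away. Derived
kinetics for the short population:

```python
print(kinetics_report(float(result.taus[0])))
# koff_per_s=0.068, processivity_range=(30, 162), translation_range_nm=(30.0, 162.0)
```

i.e. a dissociation rate of ~0.07 s⁻¹ and, for a turnover number in the
range 2–11 s⁻¹ at ~1 nm per catalytic cycle, an intrinsic processivity of
~30–160 turnovers (nm) per binding.

A command-line interface mirrors the library
(`smdwell simulate|localize|drift|link|mask|fit|kinetics|run`); `smdwell
run config.yaml` executes the full movie-to-report pipeline and writes
every intermediate table plus a JSON report.

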
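# Methods

This note records the models, numerical choices, and open design
decisions behind `smdwell`, in the order data flows through the pipeline.

## Imaging model and coordinate conventions

A movie is an `(n_frames, height, width)` stack with a pixel pitch
(default 220 nm, typical of EMCCD TIRF at ~73× magnification) and a frame
interval (default 1 s). Pixels are indexed from the top-left; pixel `i`
spans `[i − 0.5, i + 0.5]` so integer coordinates are pixel centers.
Sub-pixel positions are continuous in these units; conversion to nm
happens only at reporting.

## Synthetic data generator

The generator emulates a sparse surface-binding experiment:

- **Geometry.** Fibrils are straight line segments 1–2 px wide rasterized
  into a boolean support mask, placed with a 2 px exclusion halo so they
  remain countable as separate connected components. Real fibrils are
  3–6 nm thick — far below one pixel — so the rasterized width is the
  detection support, not a physical diameter.
- **Arrivals.** Events arrive Poisson in time (uniform over frames) and
  uniform over the spatial support (fibril mask or its complement).
  Arrival rates are free parameters (defaults keep ≲200 concurrent
  emitters per field, the sparsity single-molecule tracking needs);
  published experiments do not constrain them.
- **Dwells.** Each event draws a population by its fraction; true dwell
  is exponential with that population's time constant, or infinite for an
  *immobilized* population. Photobleaching runs as a competing clock: the
  observed dwell is `min(true dwell, bleach draw)`, with the bleach draw
  from a mixture of exponentials (Cy5 under oxygen scavenging: 195 s and
  1100 s; unscavenged: 5 s and 20 s). The min rule is the standard
  photophysics composition; the mixture weights are not separately
  measurable from the published decay curves, so they default to equal
  and are always configurable and echoed in reports.
- **Discretization.** A molecule visible during any part of a frame is
  detectable in that frame, so an observed dwell of `t` seconds spans
  `ceil(t / Δt)` frames, minimum one.
- **Rendering.** Active emitters are pixel-integrated 2D Gaussians
  (error-function differences per axis) of width `psf_sigma_px` (default
  1.3 px) and expected brightness `photons_per_frame`; optional per-frame
  blinking, global linear drift, Poisson shot noise on signal plus
  uniform background, and additive Gaussian read noise. EMCCD
  excess-noise statistics are deliberately not modeled: dwell analysis
  depends on detection, not calibrated photometry. Emitters carried out
  of the field by drift are skipped and counted, not fatal.

What passing tests on this generator do **not** show about real data:
fibrils are straight and time-invariant, backgrounds are spatially flat,
molecules never slide along fibrils, and there is no out-of-focus or
camera-artifact structure. Conclusions about algorithmic correctness
(localization accuracy, linking, censoring arithmetic, fit recovery)
transfer; absolute detection thresholds will need retuning on real
movies.

## Localization

Per frame: a median-filter background (15 px window) is subtracted, the
residual is smoothed (σ = 1 px), and local maxima above `k_sigma` (default
5) times the robust noise SD (1.4826 × MAD, insensitive to the spots
themselves) become candidates. A 2 px border margin is excluded — the
reflect-padded filters inflate noise there and such spots cannot be fit
reliably. Candidates within one ROI (7 px) of each other are fit
*jointly*: a sum of pixel-integrated Gaussians with one shared constant
offset, least-squares via `scipy.optimize.least_squares`. Amplitudes are
unconstrained during optimization so that non-spots resolve to
non-positive photons and are rejected (`negative-amplitude`), along with
fits whose center leaves the ROI or that fail to converge. The PSF width
is fixed by default (1.3 px) — at the low excitation powers typical of
long-dwell imaging, freeing σ destabilizes faint fits — with a free-σ
option.

Subtraction rounds (default 2) implement high-density recovery: each
round detects peaks in the residual of the current model, adds them to
the candidate set, and refits **all** candidates jointly against the
original frame. Two emitters 3 px apart that merge into one fit in round
one are teased apart in round two once their residual dipole shows up.
Near-duplicate fits (< 1 px) keep only the brighter. The whole procedure
is deterministic.

## Drift correction

Stage drift is estimated from the localization table itself (no
fiducials): frames are grouped into blocks (default 250), each block is
rendered as a super-resolution histogram (zoom 5 → 44 nm bins, lightly
blurred), and every block is registered against block 0 — redundant, not
chained, so registration errors do not accumulate. Two robustness choices
matter on sparse data: the correlation peak for block *b* is searched
only within ±3 px of block *b−1*'s estimate (drift is continuous;
unrestricted correlation of histograms containing *different* molecule
sets can lock onto spurious peaks tens of px away), and the sub-pixel
refinement evaluates the cross-correlation on a 0.05-bin grid by
matrix-multiply DFT (3-point parabolic interpolation showed pixel-locking
bias up to ~0.1 px). Block shifts are interpolated linearly between block
centers and extended linearly at the ends; the trajectory is pinned to
zero at frame 0 and subtracted from the localizations. Correction happens
*before* linking, so a drifting molecule is not mistaken for a mobile
one.

Blocks must each hold ≥ 50 localizations or estimation refuses (the
registration would be noise). Tracking oscillatory drift requires blocks
much shorter than the oscillation period.

## Linking and censoring

Bound molecules are assumed stationary (sliding is not modeled; observed
translation in this regime is rare and below the 220 nm pixel), so
association is greedy nearest-neighbour: a localization joins the closest
open event within `radius_px` (default 1 px = one camera pixel) whose
last supporting frame is at most `1 + max_gap_frames` behind. The default
gap tolerance of 1 frame absorbs residual fluorophore blinking at 1 s
integration; both parameters are echoed in all outputs since the
published analyses do not state theirs. Candidate pairs are assigned in
order of distance (ties to the lowest event id); every localization
supports exactly one event (conservation is asserted in tests).

An event's duration is `(end_frame − start_frame + 1) × Δt` — always an
integer multiple of the frame interval. Events touching the first or
last frame are **censored**: their true duration is unobservable (a
molecule present in all 2500 frames of a standard stack has been bound
for at least 41.7 min). They are excluded from fitting but counted and
reported. This exclusion is itself a selection on dwell length, which the
fit model corrects for (below).

## Masks and region classification

All localizations are binned onto a zoom-5 grid (`floor(x·zoom)`); the
summed image traces fibrils. Automatic segmentation is Gaussian blur →
global threshold (Otsu by default) → removal of components below
`min_area_px` → dilation by 2 SR px; a user-drawn binary mask can replace
it to reproduce manual workflows. Events are classified by mean
position: on the mask → *fibril*; outside the mask dilated by a margin
(default 2 SR px) → *background*; in between → *unassigned*, excluded
from both region analyses so fibril-adjacent molecules cannot contaminate
the background class. How far from a fibril a molecule must be to count
as background is not knowable from published data; the buffer width is a
free parameter.

## Dwell-time model and fitting

Durations are histogrammed at one frame interval per bin (durations are
integer multiples of Δt, so finer binning is meaningless and coarser
discards resolution); bins are right-open starting at Δt. Durations at or
beyond `t_max` are reported as truncated, not binned.

The m-component mixture (m = 1–3) is parameterized by event counts `N_j`
and time constants `tau_j`, each component renormalized over the
histogram support so fractions `f_j = N_j/ΣN_k` describe the partitioning
of observed events. With a finite observation window *T* and first/last-
frame censoring, kept dwells follow `e^(−t/τ)(1 − t/T)` under uniform
arrivals; the bin integral has the closed form difference of
`G(t) = e^(−t/τ)(1 − (t + τ)/T)`. The window correction is optional
(`window_s=None` gives plain exponentials, appropriate for uncensored
survival data such as photobleach decays) but is essential for long
components: at τ = 99 s in a 2500 s window the uncorrected fit is biased
low by ~17%, outside any useful tolerance.

The cost is the Poisson deviance (correct likelihood for bin counts,
including empty bins). Optimization is differential evolution
(`rand1bin`, population 15 per parameter, dithered mutation 0.5–1.0,
crossover 0.7, tolerance 1e-8, ≤1000 generations, fixed seed) over
`(log τ_j, N_j)` — τ spans 1 s to 10× the histogram range, hence
log-space — followed by a Nelder–Mead polish from the DE optimum with the
search box enforced. Components are always reported sorted by τ.
Non-convergence flags the result rather than raising. Verified against an
exhaustive 400×400 grid search, the DE optimum matches to < 1e-3 in
deviance.

**Goodness of fit.** The classical reduced deviance D/dof is reported but
is *not* near 1 for adequate models here: with 1 s bins most of the
support has expected counts ≪ 1, where the per-bin deviance expectation
tends to 0. We therefore also compute the calibrated statistic
`D / E[D]`, with `E[D]` the expected deviance under the fitted model
(exact Poisson sum per bin for μ < 30, asymptotic `1 + 1/(6μ)` above).
This statistic is ≈ 1 for an adequate model at any bin occupancy and is
the one used to judge fits.

**Model selection.** Candidate component counts are each fit; fits with
indistinct components (adjacent τ ratio < 3, or any fraction < 1%) are
discarded as unidentifiable. Among the remainder, nested models are
compared by a sequential deviance test: the larger model is adopted only
if it lowers the deviance by more than the χ² critical value at α = 0.01
for its two extra parameters. A parsimony band rule on the reduced
deviance was tried first and rejected: because D/dof is uninformative on
sparse bins it systematically preferred underfitting models. All
candidate diagnostics are retained in the result.

**Bleach-limited classification.** A component is flagged bleach-limited
("immobilized") if its τ lies within 35% relative tolerance of any
photobleach lifetime, or beyond the longest one. The 35% operationalizes
a qualitative judgment — published fits treat ~187 s and ~1260 s
components as reflecting the 195 s / 1100 s dye lifetimes while a ~99 s
component counts as resolved — and is configurable. Flagged fractions are
pooled into an immobilized fraction; flagged τ values are lower bounds,
not dissociation times.

**Uncertainty.** Bootstrap percentile intervals: resample durations with
replacement, refit at the same m with a reduced DE budget (generations
capped at 150 — the refit starts from a resample of a solved problem),
default 200 replicates, seeded. Region comparisons (fibril vs background)
tabulate τ_j and f_j with these CIs side by side.

## Derived kinetics

For a dissociating population, `k_off = 1/τ` (reported to 2 significant
figures; 15 s → 0.067 s⁻¹). Intrinsic processivity is `k_cat × τ` at the
bounds of a user-supplied turnover-number range (default 2–11 s⁻¹,
spanning literature values for processive cellobiohydrolases), rounded to
whole turnovers; translation distance multiplies by the step per turnover
(default 1 nm, one cellobiose unit). Rounding conventions are chosen to
match how such values are conventionally printed.

## Pipeline and reproducibility

`run_pipeline` executes localize → drift → link → censor → mask →
classify → per-region fits → kinetics, writing every intermediate table,
the exact configuration used, and a conservation ledger (localizations
consumed, events linked = kept + censored, kept = fibril + background +
unassigned). Every stochastic step takes an explicit seed; rerunning a
config reproduces the report bit-for-bit. Regions with fewer than 50
events are reported unavailable rather than fit.

## Problem sizes used in validation

Recovery studies simulate ~5,000 censored events per replicate (arrival
rate 2 events/frame over a 2500-frame window) for the dwell-structure
targets and 10,000 draws for photobleach-survival fits, with medians over
10 seeded replicates in the acceptance script (3 in the faster test
suite). Image-level tests use 96–128 px fields and 120–150 frame movies,
which exercise every code path at interactive runtimes.

## Known limitations

- Censored events are excluded, not likelihood-integrated; the window
  correction removes the selection bias for the kept events, but a full
  censored-survival likelihood (e.g. Kaplan–Meier-weighted or
  right-censored MLE) would use more of the data. Documented extension.
- The immobilized population's observed dwell is a bleach *mixture*; a
  single fitted component can only approximate it, and under censoring
  its fitted τ is not interpretable beyond the bleach-limited flag.
- Fractions describe *observed* (post-censoring) events. With a 2500 s
  window, an immobilized population's observed fraction is ~3–4
  percentage points below its arrival fraction; short-lived fractions are
  correspondingly inflated.
- Greedy linking can mis-associate in crowded fields (concurrent
  emitters within ~2 px); localization recall degrades similarly. The
  intended operating regime is sparse.
- No mobile-molecule or sliding-trajectory analysis; no two-color
  colocalization; no axial drift.
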
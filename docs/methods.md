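# Methods

## The kinetic model

Nucleosome gaping is modelled as a continuous-time Markov chain over
three FRET states, high / mid / low, with the *mid-centered* connectivity
(high ↔ mid ↔ low, no direct high ↔ low exchange).  The published
observables do not include a rate matrix, only per-state mean dwell times
τ and relative populations π, so the generator is calibrated from those:

- spoke states (high, low): total exit rate `k_s = 1/τ_s`, all of it into
  mid;
- hub (mid): branch rates `q_mid→s = f_s / τ_mid` with the branching
  fraction solved from stationary flux balance,
  `f_s = (π_s/π_mid)·(τ_mid/τ_s)`.

With the measured ED2.8 numbers this gives `f_high ≈ 0.583`,
`f_low ≈ 0.402`, summing to 0.986 rather than 1 — a measure of how
self-consistent the dwell times and populations are under the
mid-centered scheme.  We keep the branch rates un-normalised, which makes
the stationary distribution of the calibrated generator match the
supplied populations *exactly* (the spoke exit rates stay exactly
`1/τ`); the cost is that the hub's implied mean dwell is `τ_mid / Σf`
(419 → 425 s, 1.5 % longer).  The alternative — normalising the
branching — preserves the hub dwell but misses the populations by ~0.2
percentage points.  Since the downstream recovery checks target the
high-state dwell and the mid-state population, exactness was assigned to
those two quantities.  A deviation of `Σf` from 1 beyond 0.05 triggers a
warning; `full` connectivity is available and validated by its achieved
stationary residual.

Why mid-centered: the molecule resides in mid 84.7 % of the time and
visits high and low only transiently, and the printed dwell/population
table is numerically self-consistent under this scheme.  Whether direct
high↔low transitions occur is not decidable from the available
observables; the configuration option exists but is not the default.

## The synthetic-data generator

`simulate_cohort` emulates the real measurement: ~1000 molecules recorded
for 50 min at 0.5 s per frame (50 ms frames are used for snapshot
histograms).  Per molecule, a Gillespie realisation of the calibrated
generator (initial state drawn from the stationary distribution) is
rendered into two camera channels:

```
I_D = S(1−E)/γ + bg_D
I_A = S·E + l(I_D − bg_D) + bg_A
```

with `S = 220` a.u. total corrected intensity, `l = 0.12`, `γ = 1.7`,
backgrounds 10 a.u. per channel, and per-channel Gaussian noise of
constant sd 12 a.u. (≈ shot noise at this count level; Poisson emission
and photon-by-photon simulation are out of scope).  γ is modelled as a
donor-channel detection scaling, which makes the standard correction
formula invert the emission exactly: noiseless round trips are exact to
machine precision, and this round trip is tested.  The true FRET of a
frame is the exact time-weighted average of the state efficiencies
within the frame window, so transition frames take intermediate values
as they do on a real camera.

Photobleaching: each fluorophore dies at an exponential time with mean
1.5× the trace duration (most traces survive most of the movie, but
minute-scale mid dwells are frequently censored — the reason the
published analysis fits lifetimes only for the short-dwelled high
state).  After acceptor death the molecule emits at E = 0 (donor rises);
after donor death both channels emit background only.  A configurable
fraction of molecules are static low-FRET free DNA (E ≈ 0.10); it
defaults to 0 for kinetic recovery because dwell statistics are computed
on molecules showing three-state dynamics, the free-DNA subpopulation
being a separate histogram peak.

Seeding: one cohort seed is expanded into per-molecule substreams with
`SeedSequence(entropy=seed, spawn_key=(i,))`, so identical configs are
bit-identical and enlarging a cohort does not reshuffle existing
molecules.

Salt dependence is a log-linear scaling of named states' exit rates,
`k(c) = k_ref · (c/c_ref)^α`: only the direction of the real effect is
known (high-state dwells lengthen with NaCl), so monotonic one-parameter
scaling is the minimal rule.

What the simulator does *not* emulate: dye blinking, spectral crosstalk
beyond a constant leakage, baseline drift, stage drift, multi-step
bleaching, heterogeneous per-molecule intensities, κ² dynamics.  Passing
recovery tests therefore demonstrates correctness of the estimators
under the stated noise model, not robustness to every artefact of real
TIRF data.

## Trace correction

Photobleach detection is a single change point per channel: the split
minimising the two-segment piecewise-constant SSE, accepted only when
the level *drop* exceeds 4× a robust noise scale (1.4826·MAD of first
differences / √2).  The donor's own bleach is searched after the
acceptor's step (where the donor has risen); if nothing is found there
the whole donor channel is searched, which catches the donor-first case
in which both channels drop simultaneously.  Backgrounds are medians of
the region after the *last* detected bleach — after the donor is dark
both channels are at baseline, whereas the region after an
acceptor-only bleach still carries donor leakage and is deliberately
not used.  Molecules without a usable baseline fall back to a
configured default background, treated as an instrument calibration
(in practice: measured from empty areas of the field of view).
Correction order is background → leakage → gamma; this is the order
under which the generator's emission inverts exactly.  Frames at or
after the first bleach are excluded from analysis; a trace whose
corrected total intensity is non-positive on >20 % of pre-bleach frames
is flagged degenerate and excluded from kinetics.

## Segmentation and dwell statistics

Default method: median-filter the efficiency series (window 5 frames),
cut at the midpoints between adjacent state means (0.4925, 0.3895), then
iteratively merge runs shorter than a 12-frame dwell floor (6 s at 0.5
s/frame) into the flanking state with the closer mean, shortest runs
first.  The window and floor were calibrated by ground-truth recovery on
simulated cohorts: at the realistic per-frame efficiency noise
(σ_E ≈ 0.055, state separation ≈ 0.105, i.e. ~2σ), noise excursions of
up to ~5 s survive a median filter, so a floor much below that
fragments 100-s dwells into ~10-s pieces (estimated mean dwell low by
>10×), while a floor far above it truncates the dwell distribution and
biases the exponential mean up by roughly the floor itself.  Six
seconds sits in the window where both biases are a few per cent of the
minute-scale dwells of interest — and remains 7× below the shortest
mean dwell (42 s).  Frame-label accuracy on calibrated simulations is
>99 %.  A 3-state Viterbi decoder (fixed means, shared variance, sticky
transitions; via hmmlearn) is available as the `hmm` method and gives
equivalent recovery.

Dwells carry explicit censoring flags: the first dwell of a trace is
left-censored, the last (ended by bleach or movie end) right-censored.
`mean_dwell` is total in-state time (censored exposure included) divided
by observed exits — the right-censored exponential MLE and exactly the
published estimator.  Empirical dwell CDFs use complete dwells only;
the lifetime fit minimises least squares of `1 − exp(−t/τ)` against the
ECDF at midpoint plotting positions, with a seeded 1000-resample
bootstrap SE (the published error model for its ± values is unstated;
the bootstrap makes no distributional assumption beyond the resample).
The censoring-aware MLE with profile SE `τ/√exits` is reported
alongside; the two estimators are *not* forced to agree (the published
high-state numbers 100.25 s and 99–106 s differ between them too).
Condition comparisons report Δτ, occupancy shift and a two-sample
Kolmogorov–Smirnov test on complete dwells, declaring a shift to longer
dwells when Δτ > 0 and p < 0.05; fewer than 20 complete dwells in
either arm yields an "underpowered" flag instead of a verdict.

## Histograms

Snapshot protocol: one count per molecule, the mean efficiency over a
500 ms window (10 frames of 50 ms) whose start is uniform over the
pre-bleach region (seeded), normalised to total counts.  Per-state
protocol: one count per (molecule, state) — the molecule's mean
efficiency over frames assigned to that state — each state's histogram
scaled to its occupancy so the three masses sum to 1 (a per-dwell
contribution unit is available as an option).  Bin width 0.02 (the
source presentation does not state its binning).  Peaks are located by a
weighted 1-D Gaussian-mixture EM on bin centers (written in-house
because standard mixture fitters do not accept binned weights), with a
local-maxima fallback on fit failure.

## Distances and mode classification

`R = R0((1−E)/E)^(1/6)` with R0 = 5.9 nm (Cy3/Cy5, κ² = 2/3).  Absolute
distances are approximate — dye linkers add an unknown extension of
order 2.2 nm, carried as an annotation only — so gaping amplitude is
reported as *differences* between state distances, which cancel the
constant offset: 0.4 nm (high↔mid), 0.5 nm (mid↔low), 0.9 nm
(high↔low), inside the 0.5–1 nm band expected for gaping.  Reported
distances are rounded to 0.1 nm; full precision is kept internally.
No attempt is made to assign any FRET state to the crystallographic
structure, which is not identifiable from these data.

The mode classifier encodes hard boolean predicates over multi-probe
salt-response observations (upstream and downstream probes mandatory):
breathing requires ms-scale kinetics with salt-induced FRET decrease;
sliding and tightening/loosening require opposite signs at the upstream
vs downstream probes; gaping requires the same non-null sign at every
probe with minutes-scale kinetics.  All modes whose requirements hold
are returned; probabilistic evidence weighing is out of scope.

## Numerical choices and degenerate inputs

- Stationary distributions solve `πQ = 0, Σπ = 1` by least squares after
  an irreducibility check (strongly connected off-diagonal support).
- An all-zero generator simulates as a single static segment; a reducible
  non-trivial generator is an error.
- Efficiencies are stored clipped to [−0.2, 1.2]; kinetics uses unclipped
  values; zero-total frames yield NaN and are imputed with the trace
  median before filtering.
- Zero-noise change-point detection accepts any positive drop (MAD = 0).
- Ties in the short-run merge go to the earlier-scanned flank; merging is
  order-stable (shortest first) and idempotent on its own output.
- `curve_fit` for the lifetime starts at the sample mean; bootstrap
  resamples that fail to converge are dropped from the SE (NaN-ignored).

## Problem sizes

Recovery checks run at the study scale — 1000 molecules × 50 min × 0.5 s
frames (6 × 10⁶ frames) — which completes in well under a minute;
property tests use 10⁵-second paths and 10⁴-draw Monte Carlo samples,
sizes at which three-standard-error bands are decisive.

## Known limitations

- Threshold segmentation assumes the three state means are known; it
  does not estimate state number or means (the three-state model is
  taken as given).
- The censored-MLE mean dwell is unbiased only under exponential dwells;
  multi-exponential dwell models are out of scope.
- Acceptor direct excitation and multi-step bleaching are not corrected.
- The free-DNA subpopulation is modelled as perfectly static; real free
  DNA shows slow baseline wander.
- Lifetime recovery from a single cohort of ~250 dwells has an inherent
  sampling sd of ~8 % of τ; single-sample estimates at this size
  scatter accordingly.
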
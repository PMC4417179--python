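# gapekin

Single-molecule FRET analysis of slow nucleosome **gaping** — the
spontaneous, minutes-scale motion in which the two superhelical turns of
nucleosomal DNA separate along the axis normal to the DNA plane, like a
clam shell opening.

`gapekin` is for single-molecule biophysicists who record two-colour
(donor/acceptor) TIRF intensity time traces of surface-immobilised
nucleosomes and want to quantify slow three-state conformational
switching: trace correction, state segmentation, censoring-aware
dwell-time kinetics, FRET histograms, Förster distance conversion and
structural-mode discrimination.  Because raw traces of this kind are
rarely deposited, the package ships a first-class simulator that
generates cohorts with the full statistical structure of the experiment
(three-state Markov kinetics, leakage, gamma imbalance, noise,
photobleaching, free-DNA contamination), with ground truth retained so
every analysis stage is testable end to end.

## The model

A nucleosome switches between three FRET states — high (E = 0.545),
middle (E = 0.440) and low (E = 0.339) — following a continuous-time
Markov chain in which the high and low states exchange only with the
middle state (*mid-centered* scheme).  The generator is calibrated from
measured observables by flux balance:

- each state's total exit rate is `1/τ_state` (τ = mean dwell time),
- the branching of mid exits into high vs low is solved from
  `π_s / π_mid = f_s · τ_s / τ_mid` (π = relative population).

Raw channel intensities are corrected by background subtraction
(baseline taken after photobleaching of both fluorophores), donor
leakage `l = 0.12` and gamma factor `γ = 1.7`:

```
A' = I_A − l·I_D        E = A' / (A' + γ·I_D)
```

Mean dwell times use the right-censored exponential maximum-likelihood
estimator (total dwell time ÷ number of observed exits); the high-state
lifetime is additionally fit as `1 − exp(−t/τ)` to the empirical dwell
CDF with a seeded bootstrap standard error.  FRET converts to
donor–acceptor distance via the Förster relation
`R = R0·((1−E)/E)^(1/6)` with `R0 = 5.9 nm` for the Cy3/Cy5 pair.

## Worked example

Simulate a cohort at the calibrated kinetics (1000 molecules, 50 min at
0.5 s/frame), run the full pipeline, and summarise:

```python
import gapekin as g
from gapekin.trace_correction import correct_trace
from gapekin.state_kinetics import SegmentationModel, segment_states, summarize_kinetics

cfg = g.paper_calibrated_config(n_molecules=1000, duration=3000.0, seed=1)
cohort = g.simulate_cohort(cfg)
bg = (cfg.emission.background_donor, cfg.emission.background_acceptor)
model = SegmentationModel()
fret, tables = [], []
for tr in cohort.traces:
    ft = correct_trace(tr, default_background=bg)
    if not ft.degenerate:
        fret.append(ft)
        tables.append(segment_states(ft, model))
dwells = [d for t in tables for d in t]
summary = summarize_kinetics(dwells, fit_states=("high",), seed=1)
for state in ("high", "mid", "low"):
    k = summary.states[state]
    line = (f"{state:>4}: mean dwell {k.mean_dwell_s:6.1f} s   "
            f"occupancy {100 * k.occupancy:5.2f} %   n_dwells {k.n_dwells}")
    if k.lifetime:
        line += f"   CDF-fit lifetime {k.lifetime.tau_s:.0f} +/- {k.lifetime.se_s:.0f} s"
    print(line)
```

This prints:

```
high: mean dwell  102.2 s   occupancy 12.08 %   n_dwells 2132   CDF-fit lifetime 95 +/- 2 s
 mid: mean dwell  445.6 s   occupancy 84.47 %   n_dwells 4096
 low: mean dwell   46.7 s   occupancy  3.45 %   n_dwells 1294
```

The pipeline recovers the generating kinetics (high-state mean dwell
100.25 s, mid occupancy 84.71 %) to within a few per cent; the mid
dwell reads high because minute-long mid dwells are frequently
photobleach-censored.  Per-state histogram peaks and their distances:

```
state peak E: {'mid': 0.448, 'high': 0.548, 'low': 0.344}
distances nm: {'mid': 6.1, 'high': 5.7, 'low': 6.6}
extreme-state separation: 0.86 nm
```

The ~0.9 nm high↔low separation sits inside the 0.5–1 nm amplitude
expected for gaping; the mode classifier
(`gapekin.classify_mode`) confirms that a salt-induced FRET *increase of
the same sign at upstream, central and downstream probes* on the
minutes scale is consistent only with gaping, not with breathing,
sliding or tightening/loosening.

A command-line interface mirrors the library
(`gapekin simulate | correct | kinetics | hist | distance | classify | run`);
`examples/paper_cohort.yaml` is a complete pipeline configuration for
the calibrated cohort.

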
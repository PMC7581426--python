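# cfpc — climbing-fiber / Purkinje-cell calcium analysis

`cfpc` analyzes two-photon calcium recordings of cerebellar climbing-fiber (CF)
axonal varicosities and Purkinje-cell (PC) dendrites, and ships a ground-truth
synthetic generator so every estimator can be validated by parameter recovery.

Climbing fibers fire brief ~400 Hz bursts of 1–9 spikes; each burst evokes a
calcium transient whose amplitude grows with the spike count and saturates
around seven spikes. The package turns slow, noisy fluorescence into discrete
events with amplitudes in SD units, and from those events measures:

- **event statistics** — per-ROI event frequency and amplitude distributions
  (`signal_processing`);
- **burst-size inference** — a saturating calibration curve
  `a(n) = a_max (1 − e^(−n/κ))` fitted to calibration points, and spike-count
  estimation from amplitude mixtures (`burst`);
- **population synchrony** — trace correlation matrices, merging of duplicated
  ROIs (same axon imaged twice), and the decay of synchrony with mediolateral
  distance (`synchrony`);
- **CF–PC pairing** — geometric classification of CF/PC ROI combinations
  (paired < 1 µm boundary gap, neighboring ≤ 30 µm, distant beyond), per-category
  trace correlation, and the presynaptic→postsynaptic "translation gain"
  regression of PC on CF event amplitudes (`pairing`);
- **stimulus & motion** — air-puff-aligned amplitude grouping with a from-scratch
  one-way ANOVA + Tukey HSD, forepaw twitch onset/peak latencies at 64 Hz, and
  the amplitude–motion null regression (`stimulus`);
- **simulation** — Poisson CF event trains with distance-dependent population
  synchrony, burst-size-dependent amplitudes, AR(1) indicator kinetics, paired
  PC channels with a configurable gain and analytically calibrated noise, puff
  sessions, and motion traces, all with exported ground truth (`simulate`).

## Worked example

Simulate a 16-varicosity, 3-minute resting-state session, detect events, and
measure the population event frequency:

```python
from cfpc import (SimParams, DeconvParams, simulate_cf_population, zscore,
                  deconvolve, detect_events, first_peak_sample, event_frequency)

params = SimParams(seed=0, n_cf=16, duration=180.0)
trace, rois, truth = simulate_cf_population(params)   # 2311 ground-truth events

dp = DeconvParams()                                   # tau 0.4 s, 0.5 SD floor
z = zscore(trace)
events = first_peak_sample(detect_events(z, deconvolve(z, dp), dp))
freq = event_frequency(events, params.duration, roi_ids=trace.roi_ids)
print(f"{len(events)} events, {freq.attrs['mean_hz']:.3f} Hz "
      f"+/- {freq.attrs['sem_hz']:.3f} SEM")
# -> 2227 events, 0.773 Hz +/- 0.015 SEM   (configured rate 0.85 Hz; the 0.5 s
#    first-peak rule and same-frame event merging remove a few percent)
```

Synchrony versus mediolateral distance on the same session:

```python
from cfpc import correlation_matrix, merge_correlated_rois, synchrony_vs_distance

merged, merged_rois = merge_correlated_rois(z, rois)
pairs, fit = synchrony_vs_distance(correlation_matrix(merged), merged_rois)
print(fit.summary())
# -> Synchrony vs mediolateral distance: n = 120 pairs,
#    slope = -5.253e-05 /um, intercept = 0.086, R^2 = 0.004
```

The same stages are available from the command line:

```bash
cfpc simulate --seed 0 --n-cf 16 --duration 180 --out-dir session
cfpc process  --traces session/cf_traces.h5 --out-dir processed
cfpc synchrony --traces processed/zscored.h5 --rois session/cf_rois.csv
cfpc run --seed 0 --out-dir full_run     # simulate -> ... -> stimulus/motion
```

Every command writes a YAML config snapshot next to its outputs; a config plus
a seed reproduces every output byte for byte.

## Testing

```bash
python -m pytest -q tests/
```

The suite covers exact oracles (scipy NNLS for the deconvolution, scipy/
statsmodels for ANOVA and Tukey HSD, brute-force transitive closure for ROI
merging), property-based tests, and seeded parameter-recovery panels. One
acceptance test (`TestCriterion1FrequencyRecovery`) asserts a 2-SEM band that
the documented resolution limit does not meet; it is left honestly red rather
than widened — see `docs/methods.md`, "Known limits".

## Layout

- `src/cfpc/` — library (`simulate`, `signal_processing`, `burst`, `synchrony`,
  `pairing`, `stimulus`, `containers`, `io`, `pipeline`, `recovery`, `cli`)
- `scripts/acceptance.py` — from-scratch recovery panel runner
- `docs/methods.md` — model definitions, calibration derivations, estimator
  choices, and known limits
- `tests/` — pytest suite
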
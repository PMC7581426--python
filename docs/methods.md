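# Methods

This note defines the generative model behind `cfpc.simulate`, derives the
calibrations the package relies on, and records the estimator design choices
and their known limits. Everything here is self-contained: the quantities are
derived from the model, and the recovery panels in `cfpc.recovery` check them
empirically.

## 1. Generative model

### 1.1 Event trains and population synchrony

Each climbing-fiber (CF) varicosity fires a Poisson train of burst events at
rate `rate_cf` (default 0.85 Hz). Synchrony across the population is generated
by a shared-event construction: population events occur at rate
`rate_cf / p̄(x)`, and ROI `i` at mediolateral position `x_i` joins a population
event centered at `x_0` with probability

    p(i) = sync_p0 · exp(−|x_i − x_0| / sync_lambda),

(defaults `sync_p0 = 0.5`, `sync_lambda = 150 µm` over a 208 µm field), with a
per-ROI independent top-up train so every ROI's marginal rate is exactly
`rate_cf` regardless of its position. This yields pairwise event synchrony that
decays with mediolateral distance while keeping the single-ROI statistics
Poisson at the configured rate.

### 1.2 Burst sizes and amplitudes

Each event carries a burst spike count `n` drawn from a geometric(1/2)
distribution truncated to {1..7} (counts 8–9 are allowed by the schema but have
zero default mass). The transient amplitude follows the saturating transfer

    a(n) = a_max · (1 − exp(−n / κ)),      a_max = 4,  κ = 2,

so `a(7)/a_max ≈ 0.97`: seven spikes effectively saturate the response,
matching the physiological regime where amplitude encodes burst size up to a
ceiling.

### 1.3 Trace rendering

Amplitudes drive an AR(1) indicator model at `fs = 32` Hz with decay constant
`τ = 0.4 s` (`g = exp(−1/(fs·τ)) ≈ 0.9249`). An event at continuous time `t0`
contributes `a · exp(−(t_k − t0)/τ)` to every frame `t_k ≥ t0`, so sub-frame
timing produces partial first-frame decay rather than timing quantization
artifacts. White noise of SD `noise_sd = 0.3` is added per frame.

### 1.4 Amplitude-scale design (Campbell's theorem)

The defaults were chosen analytically so that z-scoring is approximately
unit-gain, i.e. detected amplitudes live on the generator's amplitude scale.
For a shot-noise process (Poisson events, exponential kernel), Campbell's
theorem gives the stationary signal variance

    V = rate · E[a²] · τ / 2.

With the default burst distribution, E[a] ≈ 2.23 and E[a²] ≈ 5.58, so
V ≈ 0.85 · 5.58 · 0.2 ≈ 0.949; adding noise variance 0.09 gives a trace SD of
√1.039 ≈ 1.02. A z-scored trace therefore divides by ≈ 1, the mean event
amplitude is ≈ 2.2 SD, and the mean standing (DC) level of the transient tails
is `rate · E[a] · τ ≈ 0.76 SD` — a number that matters for the amplitude read
(section 2.3).

### 1.5 Paired Purkinje-cell channel

Each of `n_pc` PC dendrite ROIs is placed within 1 µm of its CF partner and
receives the *same* realized CF events scaled by the translation gain
`pc_gain = 0.61`, plus independent white noise σ. Three calibrations for σ are
provided:

- **variance-matched** (default, `pc_noise_sd=None`):
  σ² = var(CF trace) − gain²·V, which makes the CF and PC channels' SD units
  commensurate, so amplitudes compared across z-scored channels share a scale.
- **target per-pair R²** (`pc_noise_for_target_r2`): the closed form
  σ² = gain² · var(a) · (1 − R²)/R², which sets the fraction of per-event PC
  amplitude variance explained by the CF amplitude.
- **target trace correlation** (`pc_noise_for_target_correlation`): solves

      r = gain · V / (sd_cf · sd_pc),    sd_pc = √(gain²·V + σ²),

  for σ at a requested Pearson correlation between the measured CF and PC
  traces (this form accounts for the CF channel's own measurement noise).

### 1.6 Stimulus sessions and motion

Air puffs (30 ms, 5 s inter-trial, pressures P1 = 20 psi / P2 = 50 psi) evoke
CF events with latency N(60, 20) ms clipped to (5, 290) ms; the evoked burst
size distribution shifts upward with pressure, with P2 stochastically dominant
over P1 (validated at simulation time). Forepaw speed is rendered at 64 Hz as a
squared-sine rise from onset to peak and a squared-cosine decay (80 ms) on a
rectified-noise baseline; per-trial onset/peak latencies are N(23.2, 2.9) ms
and N(57.6, 5.8) ms, peak speeds N(25, 8) mm/s.

## 2. Estimators

### 2.1 Deconvolution with a joint baseline

Event extraction uses a nonnegative sparse AR(1) deconvolution (an online
pool-adjacent-violators scheme, verified in tests against a scipy NNLS oracle
to 1e−6). Because z-scored traces are mean-centered, the quiescent level sits
*below* zero (at −mean/SD), which a nonnegative model cannot represent; a
per-ROI constant baseline is therefore estimated jointly: initialized at the
20th percentile and refined by alternating deconvolution and mean-residual
updates (3 rounds suffice; on noiseless traces the procedure is exact).

### 2.2 Event detection and the amplitude scale

Deconvolved activity is lightly smoothed (Gaussian, σ = 25 ms), candidate
events are local maxima, and amplitudes are read in SD units. The per-ROI
scale from deconvolved activity to SD amplitude is fitted by least squares
between activity peaks and their forward-window z-trace peaks, then refitted
on the candidates surviving the 0.5 SD amplitude floor.

### 2.3 Carryover-corrected peak read

A naive "max of the z-trace after the event" read is biased: at 0.85 Hz the
standing level of earlier transients' decay tails averages ≈ 0.76 SD
(section 1.4), inflating the fitted scale by ~1.4×. The read is therefore
local baseline-to-peak: the predicted carryover of pre-event modeled activity,
`g^(t−k+1) · c[k−1]`, is subtracted before taking the forward maximum. After
this correction the detected-vs-true amplitude regression has slope ≈ 1.05
(invariant band 0.9–1.1 in the tests) and per-spike-count mean amplitudes match
truth within ~3%.

### 2.4 First-peak sampling

Closely spaced events contaminate each other's amplitudes additively, so
amplitude analyses retain only the first event of any 0.5 s span (greedy
earliest-first selection; idempotent, minimum gap guaranteed, property-tested).

### 2.5 ROI merging and synchrony

Trace correlations ≥ 0.85 between ROIs within 20 µm mediolaterally mark
duplicate ROIs on the same axon; merging takes the transitive closure
(connected components, tested against a brute-force closure oracle) and
averages the member traces. Synchrony versus distance is an OLS fit of
pairwise correlation on mediolateral distance.

### 2.6 CF–PC pairing

Boundary gap = centroid distance − (r_CF + r_PC), floored at 0. Gaps < 1 µm
qualify as putative synaptic pairs; because all overlapping combinations floor
to gap 0, qualifying combinations are assigned **one-to-one greedily by
increasing centroid distance**, so each CF and each PC joins at most one pair
(a per-CF argmin over tied gaps can otherwise claim one PC twice). Remaining
qualifiers fall back to neighboring (≤ 30 µm); beyond that, distant.

For the translation-gain regression, the PC amplitude at a CF event is the
maximum of the PC z-trace within ±5 frames of the event; per-pair OLS of PC on
CF amplitudes (free intercept) is averaged across pairs.

### 2.7 Group statistics

The one-way ANOVA is computed from sums of squares; Tukey HSD p-values come
from the studentized-range distribution with the Tukey–Kramer unbalanced-size
correction (both verified against scipy `f_oneway` and statsmodels
`pairwise_tukeyhsd` in the tests). Bonferroni-corrected Welch t-tests are
available as an alternative.

### 2.8 Motion latencies

A twitch is located as the first post-puff crossing of baseline mean + 3 SD
(0.5 s pre-puff baseline); trials without a crossing within 0.5 s are flagged
`no_motion`. At 64 Hz, raw reads are biased relative to the true twitch timing:
a linearly interpolated threshold crossing sits on the convex early rise
(≈ −2.7 ms) and a parabolic peak fit to the asymmetric rise/decay waveform
lands late (≈ +5.5 ms). The default estimator therefore refines both latencies
by least-squares fitting the single-twitch waveform model (free onset, peak,
amplitude, decay) to the post-puff segment; this read is unbiased to ≤ 0.2 ms
on 100-trial panels. The raw crossing/parabola read remains available via
`refine="none"`.

## 3. Known limits

- **Temporal resolution (frequency deficit).** Two true events landing in the
  same or adjacent 32 Hz frame produce one smoothed-activity candidate. At
  0.85 Hz the probability is ≈ 1 − exp(−rate · 1.5/fs) ≈ 4%, so detected
  population frequency runs ~4–5% low (measured 0.810 Hz at a configured
  0.85 Hz over 20 seeds). This is an information limit of the recording, not an
  estimator defect; the corresponding acceptance test asserts the strict 2-SEM
  band and is left red with this explanation rather than widened.
- **Regression dilution in the gain estimate.** Detected CF amplitudes carry
  measurement noise (variance ≈ 0.19 SD² against a signal variance ≈ 0.52 SD²),
  attenuating the OLS slope of PC on *detected* CF amplitudes by ≈ 0.73 under
  the variance-matched PC noise default (measured slope ≈ 0.46 at a configured
  gain 0.61). Under the target-R² closed-form calibration the measured slope is
  ≈ 0.665 with per-pair R² ≈ 0.45. Both behaviors are inherent to per-event
  amplitude reads with errors in the predictor; an errors-in-variables
  correction is deliberately out of scope.
- **Window-max PC read.** Even with a noiseless PC channel, the ±5-frame
  maximum picks up standing decay tails of neighboring transients, so per-pair
  R² plateaus near 0.4–0.5; this bounds how sharply the gain regression can
  resolve single events at these rates.
- **Null R² replication.** For 2,926 independent amplitude/speed pairs the
  exact null distribution gives P(R² < 0.001) = P(χ²₁ < 2.93) ≈ 0.91 per run,
  so a ≥ 95% replication frequency over seeds is not attainable by a correct
  null; the test asserts ≥ 19/20 seeds and the median R² ≈ 1/(n−2).
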
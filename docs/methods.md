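# Methods

This note records the models, conventions, parameter choices and numerical
decisions behind `ipsckit`, and what the synthetic-data validation does and
does not establish about real recordings.

## Signal conventions

Currents are in pA with the raw amplifier sign: at −70 mV in high-chloride
internal solution, a GABA_A IPSC is an inward, negative-going current. All
*reported* amplitudes and charges are positive magnitudes, so transmission
successes carry positive charge and the baseline charge null is centred on
zero; outward-sign excursions therefore yield negative reported charge.
Times are in ms from the sweep start; each sweep stores its stimulus onset
(`stim_time`) and, when a presynaptic spike occurred, the AP peak time.
Windows are half-open `[start, end)` and converted to 0-based sample indices
by rounding `t·fs/1000`. The default sampling rate is 20 kHz.

## Trial-level measurements

**Fast charge.** `Q = −∫ (I(t) − Ī_baseline) dt` over `[AP+1, AP+6)` ms,
where `Ī_baseline` is the mean current of the 10 ms immediately preceding
the integration window. Integration is by the trapezoid rule on the native
grid; 1 pA·ms = 0.001 pC. The measure is linear in the trace and invariant
to DC offsets. The baseline null is built by applying the identical
measurement at anchor times drawn uniformly within the pre-stimulus region
(≥ 16 ms required); its mean is zero and it is symmetric for pure noise.

**Peak and synaptic delay.** The IPSC peak is located on a 0.25-ms-boxcar
smoothed copy of the sign-inverted, baseline-zeroed trace (the amplitude is
read off the unsmoothed trace at that index); the synaptic delay is the
peak-to-peak time from the AP. Trials whose peak does not exceed twice the
pre-stimulus noise SD are flagged undetermined.

**AP detection (loose patch).** The paper-style recordings annotate the
presynaptic AP from a cell-attached channel; the acquisition method for that
channel is not standardized, so detection here is a derivative-threshold
rule: band-pass 100–2000 Hz, differentiate, and accept the extremum in the
search window when it exceeds `k = 5` times the pre-stimulus derivative SD;
the reported time is the trace extremum within ±0.5 ms of the crossing.
At these defaults the false-positive rate on pure-noise sweeps is below 1%
(measured 0/400 in the validation battery) and detection jitter at SNR 10
is within ±0.1 ms.

## Classification

**Connectivity.** Two-sample Kolmogorov–Smirnov test of the post-AP charge
sample against the baseline null sample, `α = 0.05`. A pair is *connected*
when the test rejects **and** the post-AP mean exceeds the baseline mean;
the directional guard prevents left-shifted (outward) artefacts from being
called connections. Note the guard makes the *connected-flag* false-positive
rate ≈ α/2 under the null; the calibration suite therefore measures the
type-I error of the KS test itself (the p-value is always reported for
audit).

**Failure rate.** Failures carry no synaptic current, and their charge
distribution is symmetric about zero. Hence `n_fail = 2 × #{Q < 0}`
(capped at n with a warning), the failure/success boundary is the
`n_fail`-th smallest charge, and trials at the boundary count as failures
(the conservative choice). The estimator is equivariant under
sign-preserving shifts and unbiased when successes are well separated;
calibration at `p_fail ∈ {0.1, 0.3, 0.5}`, n = 200 trials, 500 replicates
shows mean absolute bias ≈ 0.001. On full traces a small positive bias on
failure-trial charges arises from the spillover tail present in failure
trials — physically real, and the reason the estimate is described as
conservative.

**Phasic vs. delayed.** The sliding difference
`D(t) = mean(I over [t−10.3, t−0.3)) − mean(I over [t, t+0.5))` (raw sign;
an IPSC onset makes D positive) is computed per trace. The pair's
fast-component rise time is the argmax of |D| on the mean success trace
within `[AP, AP+6)` ms. Each success is classified phasic when the maximum
of D within ±0.5 ms of that rise time exceeds the baseline mean + 2 SD.
Two implementation decisions matter here:

1. the baseline reference is the *windowed maximum* of D over segments of
   the same length in the pre-stimulus data of the individual trials —
   thresholding a max against pointwise statistics would inflate the
   false-phasic rate several-fold;
2. a pair is flagged "no fast component" (all successes delayed) when the
   maximum of D inside the monosynaptic window `[AP, AP+3)` ms — where a
   fast-rising IPSC must appear given the ~1.5 ms synaptic delay and
   sub-ms rise — stays below that threshold.

At peak SNR 8 with 25% delayed prevalence the classifier agrees with ground
truth on ≈ 98% of 1000 labeled events; errors are almost exclusively
delayed events misread as phasic.

## Exponential decomposition

Fits act on averaged, baseline-zeroed, sign-inverted traces and start at the
empirical peak (decay-only; the rise is excluded). The model is
`A1·e^{−t/τ1} + A2·e^{−t/τ2} + C` (mono-exponential: one term), where the
constant `C` absorbs the quasi-flat spillover pedestal under the fit window;
`C` does not enter the fitted charge `Q = (A1τ1 + A2τ2)/1000` pC.
Initialization is deterministic — τ1 from the 10–90% decay time, τ2 from a
log-linear regression of the tail (after pedestal subtraction), amplitudes
by linear least squares given the τs — followed by bounded trust-region
least squares, so fits are reproducible bit-for-bit on identical input.
Degenerate outcomes (τs within 10%, or one amplitude < 10⁻³ of the other)
are refit as mono-exponential and flagged. Delayed-trace fits refuse when
fewer than 5 delayed events entered the average. The weighted decay time
constant is reported from the fitted charge and the *measured* peak,
`τ_w = 1000·Q/I` ms.

**Slow component.** Two modes, reported side by side: `tail36` integrates
the baseline-zeroed current from 36 ms after the peak (when the fast
component has fully decayed) to the horizon (2 s where available); `cumsum`
fits `C(t) = C0 + Q_slow(1 − e^{−(t−t0)/τ_slow})` to the cumulative charge
with `t0` fixed at peak + 50 ms, falling back to `tail36` below a 1 s
horizon. Long integrations are zeroed on the full pre-stimulus region — a
0.05 pA baseline error integrates to 0.1 pC over 2 s, so a short zeroing
window would dominate the error budget.

**What "recovery" means.** With a finite rise time, decay-from-peak
parameters are functionals of the waveform, not the generative amplitudes:
for the default phasic shape the fit's A1 sits ≈ 35% below the generative
A1 and τ2 ≈ 13% above, *systematically and noiselessly* (the spillover tail
under the window contributes to the τ2 inflation; published fits of this
style embed the same mapping). Parameter recovery is therefore quantified
against the *noiseless-twin estimand*: the generator draws trial structure
and recording noise from independent RNG streams, so the identical pair can
be regenerated with `noise_sd = 0` and the identical measurement applied.
Over 100 pairs at study SNR the median |relative error| is ≤ 2% for
τ1/τ2/Q, ≈ 5% for τ_delayed and ≈ 7% for τ_slow. τ_slow and the generative
τ are additionally in direct agreement (bias < 1%).

## Synthetic data

`simulate_pair` composes, per trial: 3-kHz-low-passed Gaussian noise
(default SD 2.5 pA); with probability `p_ap` (0.62) a presynaptic AP at
flash + 3 ms; given an AP, a transmission failure with `p_fail` (0.16);
given success, a delayed event with `p_delayed` (0.26), else phasic. Phasic
events are `(1 − e^{−t/0.3})·(40·e^{−t/2} + 15·e^{−t/16.5})` pA (negative
sign); delayed events are mono-exponential (10 pA, τ = 10 ms) with a slow
3 ms rise and +0.5 ms onset shift — the slow onset is the class's defining
feature, chosen so the event carries little current inside the fast-rise
test window and peaks ≈ 5 ms after the AP. Event onsets are placed so the
*peak-to-peak* AP→IPSC delay averages 1.5 ms (SD 0.15; +1 ms under the
gap-junction confound). Trial-to-trial amplitude variability is lognormal
multiplicative (CV 0.3; the distributional form is our choice — no
published form exists). The spillover tail (τ = 359 ms) rises with a 15 ms
time constant (extrasynaptic receptors activate as transmitter accumulates
in the glomerulus; an instantaneous tail would leak into the 5-ms charge
window and the slide statistic) and carries 0.6 pC on successes, 1/3 of
that on postsynaptic failures, ≈ 0.18 of it on AP trials of unconnected
pairs, and nothing on AP failures. Sweeps default to 2 s at 20 kHz with the
stimulus at 50 ms.

`simulate_timecourse` builds a continuous 10 Hz train (default 17 min,
first 3 min baseline, 5 min drug) with a compound eIPSC template (peak
100 pA, τ1 = 3.48 ms, τ2 = 36.5 ms, slow fraction 0.5). Amplitude undergoes
multiplicative exponential rundown calibrated so the loss at 10 min equals
`rundown_rate` (default 0.20). Glycine competition is phenomenological:
after drug onset the amplitude and the slow fraction approach
`amplitude_scale` (0.79) and `a2_fraction_scale` (0.82) with first-order
kinetics (τ = 1.5 min), without washout recovery. The two scales were set
once, in closed form, so that the measured t2/t1 charge ratio under the
default rundown equals the 0.62 calibration value and the slow-fraction
ratio matches 0.40/0.49; simulation reproduces both within noise.

**What the generator does not emulate** — and what passing tests therefore
do not show: 1/f and line noise, series-resistance and holding drift,
stimulation artefacts, vesicle-pool depletion within trains, bath-perfusion
wash-in hydraulics, spontaneous synaptic activity, and any biophysical
model of vesicular GABA/glycine competition (the glycine effect is a scale,
not a loading model). Calibration results transfer to real data only to the
extent that recording noise is approximately Gaussian and stationary within
a pair.

## Population statistics

Mann–Whitney (unpaired) and Wilcoxon signed-rank (paired) comparisons and
Spearman correlation (p from the t-transform with n−2 df; the regression
slope is reported when p < 0.05) delegate to scipy. The Conover
squared-ranks test ranks |x−x̄| and |y−ȳ| jointly, squares the ranks, sums
them in one group, and uses the tie-corrected normal approximation
(`method="permutation"` provides an exact-style alternative for small n;
the two agree within 0.03 in p). The two-cluster 1-D K-means is exact: the
optimal 2-partition of scalars is a contiguous split of the sorted sample,
so scanning all n−1 splits (via prefix sums) is a proof, not a heuristic —
verified against full partition enumeration. "Dispersion explained" is
1 − WSS/TSS. The bootstrap bimodality test draws `n_draws` values (default:
the observed sample size) with replacement from the reference distribution,
computes each draw's exact inertia, and reports
`p = (#{inertia_boot ≤ inertia_obs} + 1)/(n_reps + 1)` one-sided, with
`n_reps = 10 000` by default. Empirical type-I errors at α = 0.05 over 2000
null replicates: Conover ≈ 0.052–0.063, Mann–Whitney ≈ 0.046,
Spearman ≈ 0.051; bootstrap self-draw rejection ≈ 0.03.

## Epochs and time courses

QeIPSC is the charge of the average of 100 consecutive eIPSCs (one 10-s bin
at 10 Hz), integrated from the stimulus to the end of the inter-stimulus
window after zeroing on the pre-stimulus segment; the series is normalized
by the mean over the first 3 min. Epoch summaries average 1000 consecutive
sweeps: t1 = last 1000 sweeps of baseline, t2 = last 1000 sweeps of the
drug application, t3 = the final 1000 sweeps, starting no earlier than
7 min after the drug ends (all configurable). Per epoch: charge, peak,
Q/I, A2/(A1+A2) via the bi-exponential fit, and the 36-ms slow charge
(from peak+36 ms to the window end). Rundown is *not* corrected;
interleaved no-drug controls are the comparison, and condition contrasts
report `(mean_A − mean_B)/mean_A` with a Mann–Whitney p-value.

## Validation battery sizes

The test suite (`tests/test_acceptance.py`) and `scripts/acceptance.py` use:
100 (suite) / 60 (script) synthetic pairs × 128 trials for parameter
recovery; 500 replicates × n = 200 per failure-rate level; 1000 null +
300 shifted pairs for the connectivity calibration; 1000 labeled events at
SNR 8 for the event classifier; 2000 replicates per rank-test calibration;
200 random instances (n ≤ 12) against brute-force K-means; 60 seeded runs
at 10 000 bootstrap replicates (detection) and 500 outer runs at 2000
(self-draw calibration); 100 (suite) / 60 (script) replicates × 80 trials
of 1.2 s sweeps for the spillover ordering; one 17-min and one 10.5-min
simulated train for the pharmacology calibration. These sizes give the
calibration bands a comfortable margin while keeping the full battery to a
few minutes.

## Known limitations

- The AP(+) compound fit mixes phasic and delayed events and sits on the
  spillover pedestal; its τ1/τ2 are waveform functionals (see above), so
  cross-study comparisons should use the same fit windows.
- The failure-rate estimator assumes a symmetric failure null; slow
  spillover in failure trials shifts it slightly positive, making the
  estimate conservative (biased low) on strongly spillover-coupled pairs.
- The delayed/phasic boundary degenerates at very low noise: any
  measurable early current exceeds a 2-SD threshold computed from a clean
  baseline. The rule is calibrated for realistic noise floors.
- `cumsum` slow fits need ≥ 1 s of horizon; shorter sweeps silently fall
  back to tail integration (with a warning), which underestimates Q_slow
  by the truncated tail fraction.
- The HDF5 archive stores samples as float32; round trips are bit-exact at
  float32 precision.
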
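# ipsckit

Trial-level analysis of GABAergic inhibitory postsynaptic currents (IPSCs)
recorded in cerebellar granule cells (GrCs) during paired recordings with
single Golgi cells (GoCs), plus the pharmacology time-course analysis of
electrically evoked IPSC trains. The package targets electrophysiologists
who need a reproducible, tested pipeline for:

- **per-trial charge metrics** — the 5-ms time integral of the current
  starting 1 ms after the presynaptic spike, baseline-zeroed on the
  preceding 10 ms (reported in pC, successes positive);
- **connectivity classification** — two-sample Kolmogorov–Smirnov test of
  post-AP charges against baseline-sampled charges;
- **transmission failure rate** — exploiting the symmetry of the failure
  charge null: `n_fail = 2 × #{Q < 0}`, a conservative quantal estimate;
- **phasic vs. delayed IPSC classification** — a sliding difference between
  a 10 ms and a 0.5 ms window (separated by 0.3 ms, the rise time of a fast
  IPSC), thresholded at baseline + 2 SD in a ±0.5 ms jitter window around
  the pair's fast-component rise time;
- **exponential decay decomposition** — bi-exponential fits of averaged
  currents, `Q_AP(+) = (A1·τ1 + A2·τ2)/1000`, the fit-free weighted decay
  time constant `τ_w = Q/I`, mono-exponential fits of delayed events, and
  the slow spillover component `Q_slow`, `τ_slow` from the cumulative
  charge `C(t) = C0 + Q_slow·(1 − e^{−(t−t0)/τ_slow})`;
- **pharmacology time courses** — QeIPSC per 10-s bin (charge of the
  average of 100 consecutive eIPSCs at 10 Hz), baseline normalization,
  t1/t2/t3 epoch ratios and condition contrasts;
- **population statistics** — Mann–Whitney / Wilcoxon, Spearman with a
  t-statistic p-value, the Conover squared-ranks test of equal variance, an
  *exact* 1-D two-cluster K-means, and a bootstrap inertia test of
  failure-rate bimodality.

A synthetic sweep generator (`ipsckit.synthio`) produces voltage-clamp
recordings with complete ground truth — quantal failures, bi-exponential
phasic IPSCs (τ1 ≈ 2 ms, τ2 ≈ 16.5 ms), slow-onset delayed IPSCs
(τ ≈ 10 ms), a spillover tail (τ ≈ 359 ms), gap-junction latency confounds,
10 Hz rundown, and glycine-competition scaling — so every stage of the
pipeline is validated against known truth.

## Worked example

Simulate one GlyT2(+) pair (128 optogenetic trials, 62% spike success, 16%
transmission failure), classify it, and summarize:

```python
import numpy as np
from ipsckit import synthio
from ipsckit.trial_classifier import classify_pair
from ipsckit.kinetics import pair_summary

cfg = synthio.SynthPairConfig(n_trials=128, seed=42)
pair, truth = synthio.simulate_pair(cfg, pair_id="demo", phenotype="GlyT2_pos")
cls = classify_pair(pair, rng=0)
row = pair_summary(pair, cls)
```

which prints (formatted):

```
connected      : True (KS p = 3.84e-48)
p_fail         : 0.135   (ground truth 0.16)
I_AP(+)        : 23.6 pA
Q_AP(+)        : 0.188 pC
TAU1 / TAU2    : 2.38 / 18.06 ms
weighted tau   : 7.96 ms
TAU_delayed    : 9.7 ms, Q_delayed 0.032 pC
Q_slow / tau   : 0.50 pC / 390 ms
synaptic delay : 1.55 ms
```

The pair is classified connected with overwhelming evidence; the failure
rate estimate (0.135) sits near the programmed 0.16; the fitted decay
constants bracket the generative values (τ2 is slightly inflated by the
spillover pedestal under the fit window — an inherent property of
decay-from-peak fitting, see `docs/methods.md`); and the spillover fit
recovers the programmed 0.49 pC of success-trial slow charge carried with
τ_slow ≈ 359 ms.

The same stages are available from a shell:

```sh
ipsckit simulate --seed 1 --out run1      # synthetic study archive + truth
ipsckit classify run1/archive.h5          # connectivity, failures, classes
ipsckit fit run1/archive.h5 --out run1    # per-pair summary CSV
ipsckit timecourse --condition glycine    # pharmacology epoch ratios
ipsckit report --seed 1 --out run1        # full pipeline + manifest
```

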
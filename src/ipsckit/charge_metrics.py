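"""Per-trial charge, peak, delay, and slow-charge measurements.

The fast trial charge is the 5-ms time integral of the current starting 1 ms
after the presynaptic spike, after zeroing the mean current of the preceding
10 ms.  Charges are reported as positive magnitudes for inward IPSCs
(1 pA*ms = 0.001 pC); outward-sign excursions therefore yield negative
reported charge, which the failure-rate estimator exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace_model import SweepRecord, TimeWindow, ms_to_idx

PA_MS_TO_PC = 1e-3

# paper-defined windows, ms
CHARGE_OFFSET = 1.0      # integration starts this long after the AP peak
CHARGE_LEN = 5.0         # integration length
BASELINE_LEN = 10.0      # zeroing window, immediately before integration start
TAIL36_OFFSET = 36.0     # slow charge starts this long after the IPSC peak


@dataclass
class TrialMetrics:
    """Measurements for one trial (see module docstring for conventions)."""

    trial: int
    q_fast: float            # pC, reported positive
    peak_amp: float          # pA, positive magnitude
    peak_time: float         # ms, sweep coordinates
    delay: float             # ms, AP peak -> IPSC peak
    q_slow_trial: float      # pC
    ap_success: bool | None = None
    ipsc_success: bool | None = None
    event_class: str = "undetermined"


def _windowed_integral(samples: np.ndarray, fs: float, t0: float, t1: float) -> float:
    """Trapezoid integral of ``samples`` over ``[t0, t1)`` ms, in pA*ms."""
    i0, i1 = ms_to_idx(t0, fs), ms_to_idx(t1, fs)
    if i1 == samples.size:      # window ending exactly at the trace end
        i1 -= 1
    if i0 < 0 or i1 + 1 > samples.size:
        raise ValueError("integration window out of range")
    dt = 1000.0 / fs
    return float(np.trapezoid(samples[i0:i1 + 1], dx=dt))


def trial_charge(sweep: SweepRecord, ap_time: float) -> float:
    """Fast trial charge in pC (reported positive for inward IPSCs).

    ``ap_time`` is in sweep coordinates (ms from sweep start).
    """
    fs = sweep.sampling_rate
    t_start = ap_time + CHARGE_OFFSET
    if t_start - BASELINE_LEN < 0:
        raise ValueError("need 10 ms of trace before the integration window")
    if ms_to_idx(t_start + CHARGE_LEN, fs) + 1 > sweep.n_samples:
        raise ValueError("integration window extends past the sweep")
    i0 = ms_to_idx(t_start - BASELINE_LEN, fs)
    i1 = ms_to_idx(t_start, fs)
    baseline = float(np.mean(sweep.samples[i0:i1]))
    integral = _windowed_integral(sweep.samples - baseline, fs, t_start,
                                  t_start + CHARGE_LEN)
    return -integral * PA_MS_TO_PC


def baseline_charge_distribution(sweeps: list[SweepRecord], n_draws: int,
                                 rng: np.random.Generator | int | None = None
                                 ) -> np.ndarray:
    """Null charge distribution sampled from the pre-stimulus baseline.

    Anchor times play the role of the AP peak and are drawn uniformly such
    that the full measurement (10 ms zeroing + 1 ms offset + 5 ms integral)
    fits before the stimulus.  Requires >= 16 ms of pre-stimulus baseline.
    """
    rng = np.random.default_rng(rng)
    if not sweeps:
        raise ValueError("no sweeps given")
    lo = BASELINE_LEN - CHARGE_OFFSET          # anchor + 1 - 10 >= 0
    draws = np.empty(n_draws)
    hi_by_sweep = [s.stim_time - (CHARGE_OFFSET + CHARGE_LEN) for s in sweeps]
    if min(hi_by_sweep) <= lo:
        raise ValueError("sweeps need >= 16 ms of pre-stimulus baseline")
    idx = rng.integers(0, len(sweeps), size=n_draws)
    for j, i in enumerate(idx):
        anchor = rng.uniform(lo, hi_by_sweep[i])
        draws[j] = trial_charge(sweeps[i], anchor)
    return draws


def peak_and_delay(sweep: SweepRecord, ap_time: float,
                   search: TimeWindow | None = None, smooth_ms: float = 0.25,
                   noise_guard_sd: float = 2.0
                   ) -> tuple[float, float, float, bool]:
    """IPSC peak amplitude, peak time, and synaptic delay for one trial.

    The peak is located on a lightly boxcar-smoothed copy of the
    sign-inverted, baseline-zeroed current (the amplitude is read from the
    unsmoothed trace at that index); the synaptic delay is the peak-to-peak
    time between the AP and the IPSC.  Returns
    ``(peak_amp, peak_time, delay, determined)`` where ``determined`` is
    False when the peak does not exceed ``noise_guard_sd`` times the
    pre-stimulus noise SD.
    """
    fs = sweep.sampling_rate
    if search is None:
        search = TimeWindow(ap_time, ap_time + 10.0)
    i0 = ms_to_idx(ap_time - BASELINE_LEN, fs)
    i1 = ms_to_idx(ap_time, fs)
    if i0 < 0:
        raise ValueError("need 10 ms of trace before the AP for baseline zeroing")
    baseline = float(np.mean(sweep.samples[i0:i1]))
    inverted = -(sweep.samples - baseline)
    n_box = max(1, ms_to_idx(smooth_ms, fs))
    smoothed = np.convolve(inverted, np.ones(n_box) / n_box, mode="same")
    sl = search.to_slice(fs)
    if sl.start >= sl.stop or sl.stop > sweep.n_samples:
        raise ValueError("empty or out-of-range search window")
    i_peak = sl.start + int(np.argmax(smoothed[sl]))
    peak_amp = float(inverted[i_peak])
    peak_time = i_peak * 1000.0 / fs
    delay = peak_time - ap_time
    noise_sd = float(np.std(inverted[:i1])) if i1 > 1 else 0.0
    determined = peak_amp > noise_guard_sd * noise_sd
    return peak_amp, peak_time, delay, determined


def slow_charge(trace: np.ndarray, sampling_rate: float, peak_time: float,
                horizon: TimeWindow | None = None,
                baseline_window: TimeWindow | None = None,
                start_offset: float = TAIL36_OFFSET) -> float:
    """Slow (spillover) charge by direct tail integration, in pC.

    Integrates the baseline-zeroed, sign-inverted current from
    ``peak_time + start_offset`` to the end of ``horizon`` (default: end of
    trace, at most 2 s after the peak).  ``trace`` is typically an averaged
    sweep; ``baseline_window`` defaults to the 10 ms preceding the AP window,
    i.e. ``[peak_time - 12, peak_time - 2)`` ms, but a longer pre-stimulus
    window gives a steadier zero on long horizons.
    """
    trace = np.asarray(trace, dtype=float)
    fs = sampling_rate
    duration = trace.size * 1000.0 / fs
    if horizon is None:
        horizon = TimeWindow(peak_time + start_offset,
                             min(duration, peak_time + 2000.0))
    if horizon.end > duration + 1e-9:
        raise ValueError("horizon extends past the trace")
    if baseline_window is None:
        baseline_window = TimeWindow(max(0.0, peak_time - 12.0), peak_time - 2.0)
    bsl = baseline_window.to_slice(fs)
    baseline = float(np.mean(trace[bsl]))
    t0 = max(horizon.start, peak_time + start_offset)
    integral = _windowed_integral(trace - baseline, fs, t0, horizon.end)
    return -integral * PA_MS_TO_PC
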
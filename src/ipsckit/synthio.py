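"""Synthetic voltage-clamp data with full ground truth.

The generator emulates the statistical structure of GoC-GrC recordings that
the analysis pipeline assumes:

* Gaussian recording noise, low-pass filtered at 3 kHz;
* quantal successes and failures of transmission following a presynaptic AP;
* fast phasic IPSCs with bi-exponential decay (tau1 ~ 2 ms, tau2 ~ 16.5 ms);
* delayed IPSCs lacking the fast component (mono-exponential, tau ~ 10 ms);
* a slow spillover tail (tau_slow ~ 359 ms) whose amplitude depends on the
  trial class -- full on transmission successes, a configurable fraction
  (default 1/3) on postsynaptic failures, small on unconnected AP trials;
* an optional gap-junction latency confound (+1 ms);
* 10 Hz-train rundown and glycine-competition scaling of amplitude and of
  the slow decay fraction for the pharmacology time-course experiments.

Failure trials contain pure noise in the measurement window, so the trial
charge distribution of failures is symmetric about zero by construction --
the assumption the failure-rate estimator exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal

from .trace_model import (DEFAULT_SAMPLING_RATE, PairRecording, SweepRecord,
                          TrialLabels, ms_to_idx)

NOISE_FILTER_HZ = 3000.0


# ---------------------------------------------------------------------------
# configurations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhasicParams:
    """Bi-exponential phasic IPSC shape (amplitudes in pA, times in ms)."""

    a1: float = 40.0
    tau1: float = 2.0
    a2: float = 15.0
    tau2: float = 16.5
    rise_tau: float = 0.3

    def __post_init__(self) -> None:
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("time constants must be positive")
        if not self.tau2 > self.tau1:
            raise ValueError("tau2 must exceed tau1")

    @property
    def charge_pc(self) -> float:
        """Analytic charge magnitude with instantaneous rise, pC."""
        return (self.a1 * self.tau1 + self.a2 * self.tau2) / 1000.0


@dataclass(frozen=True)
class DelayedParams:
    """Mono-exponential delayed IPSC (no fast component, slow onset)."""

    a: float = 10.0
    tau: float = 10.0
    onset_shift: float = 0.5
    # slow onset is the defining feature of the class (no fast-rising
    # component): with rise_tau 3 ms the event carries little current inside
    # the fast-rise test window and peaks ~5 ms after the AP
    rise_tau: float = 3.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass(frozen=True)
class SpilloverParams:
    """Slow spillover tail shared across trial classes of a pair."""

    q_slow: float = 0.6          # pC carried on a transmission success
    tau_slow: float = 359.0      # ms
    failure_fraction: float = 1.0 / 3.0   # AP+/IPSC- trials carry this fraction
    unconnected_fraction: float = 0.18    # AP+ trials of unconnected pairs

    def __post_init__(self) -> None:
        if self.tau_slow <= 0:
            raise ValueError("tau_slow must be positive")


@dataclass
class SynthPairConfig:
    """Ground-truth parameters for one simulated GoC-GrC pair.

    Defaults follow adult GoC-GrC physiology: 62% spike success at
    juxta-threshold optogenetic stimulation, 16% postsynaptic failure rate,
    ~26% delayed-event prevalence, 1.5 ms synaptic delay.
    """

    connected: bool = True
    n_trials: int = 64
    p_ap: float = 0.62
    p_fail: float = 0.16
    p_delayed: float = 0.26
    phasic_params: PhasicParams = field(default_factory=PhasicParams)
    delayed_params: DelayedParams = field(default_factory=DelayedParams)
    spillover_params: SpilloverParams = field(default_factory=SpilloverParams)
    delay_mean: float = 1.5     # ms, AP peak -> IPSC onset
    delay_sd: float = 0.15
    gap_junction: bool = False  # adds ~1 ms of latency
    noise_sd: float = 2.5       # pA after the 3 kHz low-pass
    amplitude_cv: float = 0.3   # lognormal trial-to-trial multiplicative CV
    seed: int = 0
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    sweep_ms: float = 2000.0
    stim_time: float = 50.0     # ms from sweep start
    ap_latency: float = 3.0     # ms, flash -> AP peak

    def __post_init__(self) -> None:
        for name in ("p_ap", "p_fail", "p_delayed"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def phenotype_guess(self) -> str:
        return "unknown"


@dataclass
class GroundTruth:
    """What the generator actually did, trial by trial."""

    trials: pd.DataFrame     # ap_emitted, ipsc_emitted, event_class,
    #                          event_amplitude (pA), event_onset (ms, sweep coords)
    config: SynthPairConfig

    @property
    def p_fail_true(self) -> float:
        return self.config.p_fail

    @property
    def n_failures(self) -> int:
        df = self.trials
        return int((df.ap_emitted & ~df.ipsc_emitted).sum())


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------


def phasic_waveform(t: np.ndarray, params: PhasicParams) -> np.ndarray:
    """Bi-exponential IPSC waveform on time grid ``t`` (ms), raw (negative) sign.

    ``w(t) = -(1 - exp(-t/rise_tau)) * (a1 exp(-t/tau1) + a2 exp(-t/tau2))``
    for t >= 0, zero before.  With ``rise_tau -> 0`` the analytic charge
    magnitude is ``a1*tau1 + a2*tau2`` (pA*ms).
    """
    t = np.asarray(t, dtype=float)
    w = np.zeros_like(t)
    m = t >= 0
    tm = t[m]
    rise = 1.0 if params.rise_tau <= 0 else -np.expm1(-tm / params.rise_tau)
    w[m] = -rise * (params.a1 * np.exp(-tm / params.tau1)
                    + params.a2 * np.exp(-tm / params.tau2))
    return w


def delayed_waveform(t: np.ndarray, params: DelayedParams) -> np.ndarray:
    """Mono-exponential delayed IPSC with a slow rise, raw (negative) sign."""
    t = np.asarray(t, dtype=float)
    w = np.zeros_like(t)
    ts = t - params.onset_shift
    m = ts >= 0
    tm = ts[m]
    rise = 1.0 if params.rise_tau <= 0 else -np.expm1(-tm / params.rise_tau)
    w[m] = -rise * params.a * np.exp(-tm / params.tau)
    return w


def spillover_waveform(t: np.ndarray, q_slow_pc: float, tau_slow: float,
                       rise_tau: float = 15.0) -> np.ndarray:
    """Slow spillover tail carrying ``q_slow_pc`` pC, raw (negative) sign.

    High-affinity extrasynaptic receptors activate over tens of ms as the
    transmitter accumulates in the glomerulus, so the tail rises with
    ``rise_tau`` (15 ms default) rather than stepping on instantaneously;
    the amplitude is normalized so the total charge stays ``q_slow_pc``.
    """
    t = np.asarray(t, dtype=float)
    w = np.zeros_like(t)
    m = t >= 0
    if rise_tau > 0:
        amp = 1000.0 * q_slow_pc * (rise_tau + tau_slow) / tau_slow ** 2
        w[m] = (-amp * -np.expm1(-t[m] / rise_tau)) * np.exp(-t[m] / tau_slow)
    else:
        w[m] = -(1000.0 * q_slow_pc / tau_slow) * np.exp(-t[m] / tau_slow)
    return w


def waveform_peak_lag(params: PhasicParams, resolution_ms: float = 0.01) -> float:
    """Time from waveform onset to its (negative) peak, ms."""
    t = np.arange(0.0, 20.0, resolution_ms)
    return float(t[np.argmin(phasic_waveform(t, params))])


def filtered_noise(n: int, sd: float, rng: np.random.Generator,
                   sampling_rate: float = DEFAULT_SAMPLING_RATE) -> np.ndarray:
    """White Gaussian noise low-passed at 3 kHz and rescaled to SD ``sd``."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    white = rng.normal(0.0, 1.0, size=n)
    nyq = sampling_rate / 2.0
    if NOISE_FILTER_HZ < nyq:
        sos = signal.butter(4, NOISE_FILTER_HZ / nyq, output="sos")
        white = signal.sosfiltfilt(sos, white)
    s = white.std()
    return white * (sd / s) if s > 0 else white


def cell_attached_sweep(ap_time: float, sampling_rate: float = DEFAULT_SAMPLING_RATE,
                        duration_ms: float = 50.0, stim_time: float = 10.0,
                        snr: float = 10.0, noise_sd: float = 1.0,
                        rng: np.random.Generator | int | None = None,
                        spike: bool = True) -> SweepRecord:
    """Loose-patch sweep with a biphasic extracellular spike for AP detection.

    The spike template is the derivative of a Gaussian (width 0.3 ms) whose
    positive extremum, taken as the AP peak, sits at ``ap_time`` (sweep
    coordinates).  ``snr`` is the template extremum over ``noise_sd``.
    """
    rng = np.random.default_rng(rng)
    n = ms_to_idx(duration_ms, sampling_rate)
    trace = filtered_noise(n, noise_sd, rng, sampling_rate)
    if spike:
        t = np.arange(n) * 1000.0 / sampling_rate
        width = 0.3
        x = (t - ap_time) / width
        template = -x * np.exp(-0.5 * x * x)      # positive peak at ap_time - width
        template[template < 0] *= 0.5             # dominant capacitive lobe
        template = np.roll(template, ms_to_idx(width, sampling_rate))
        ref_sd = noise_sd if noise_sd > 0 else 1.0
        template *= snr * ref_sd / np.max(np.abs(template))
        trace = trace + template
    return SweepRecord(samples=trace, sampling_rate=sampling_rate,
                       stim_time=stim_time,
                       ap_time=ap_time if spike else None)


# ---------------------------------------------------------------------------
# pair simulation
# ---------------------------------------------------------------------------


def simulate_pair(config: SynthPairConfig, pair_id: str = "synth",
                  phenotype: str = "unknown") -> tuple[PairRecording, GroundTruth]:
    """Simulate one pair recording with per-trial ground truth.

    Composition rule per trial: noise + (if an AP was emitted and
    transmission did not fail) a phasic or delayed event timed so that the
    peak-to-peak AP -> IPSC delay averages ``delay_mean`` (+1 ms with a gap
    junction), plus a spillover tail whose amplitude depends on the trial
    class (see module docstring).
    """
    cfg = config
    # independent streams for trial structure and recording noise, so that a
    # noiseless twin (same seed, noise_sd=0) shares the exact trial sequence
    ss = np.random.SeedSequence(cfg.seed)
    rng, rng_noise = (np.random.default_rng(c) for c in ss.spawn(2))
    fs = cfg.sampling_rate
    n_samp = ms_to_idx(cfg.sweep_ms, fs)
    t_grid = np.arange(n_samp) * 1000.0 / fs
    peak_lag = waveform_peak_lag(cfg.phasic_params)

    if cfg.amplitude_cv > 0:
        sigma2 = np.log1p(cfg.amplitude_cv ** 2)
        mu = -0.5 * sigma2
    rows, sweeps = [], []
    sp = cfg.spillover_params
    for k in range(cfg.n_trials):
        ap = bool(rng.random() < cfg.p_ap)
        ap_time = cfg.stim_time + cfg.ap_latency if ap else None
        ipsc = False
        event_class = "failure" if ap else "undetermined"
        amp = 0.0
        onset = np.nan
        trace = filtered_noise(n_samp, cfg.noise_sd, rng_noise, fs)
        if ap:
            delay = rng.normal(cfg.delay_mean, cfg.delay_sd)
            if cfg.gap_junction:
                delay += 1.0
            onset = ap_time + max(delay - peak_lag, 0.05)
            scale = (float(rng.lognormal(mu, np.sqrt(sigma2)))
                     if cfg.amplitude_cv > 0 else 1.0)
            te = t_grid - onset
            if cfg.connected:
                ipsc = bool(rng.random() >= cfg.p_fail)
                if ipsc:
                    delayed = bool(rng.random() < cfg.p_delayed)
                    event_class = "delayed" if delayed else "phasic"
                    wav = (delayed_waveform(te, cfg.delayed_params) if delayed
                           else phasic_waveform(te, cfg.phasic_params))
                    amp = scale * float(-wav.min())
                    trace += scale * wav
                    trace += scale * spillover_waveform(te, sp.q_slow, sp.tau_slow)
                else:
                    trace += spillover_waveform(te, sp.failure_fraction * sp.q_slow,
                                                sp.tau_slow)
            else:
                trace += spillover_waveform(te, sp.unconnected_fraction * sp.q_slow,
                                            sp.tau_slow)
        sweeps.append(SweepRecord(
            samples=trace, sampling_rate=fs, stim_time=cfg.stim_time,
            ap_time=ap_time,
            labels=TrialLabels(ap_success=ap, ipsc_success=ipsc if ap else None)))
        rows.append(dict(trial=k, ap_emitted=ap, ipsc_emitted=ipsc,
                         event_class=event_class, event_amplitude=amp,
                         event_onset=onset))
    pair = PairRecording(pair_id=pair_id, phenotype=phenotype,
                         protocol="optogenetic_0p37Hz", sweeps=sweeps,
                         connected=cfg.connected)
    truth = GroundTruth(trials=pd.DataFrame(rows), config=cfg)
    return pair, truth


def simulate_charge_set(p_fail: float, n: int, separation_sd: float = 5.0,
                        noise_sd_pc: float = 0.05,
                        rng: np.random.Generator | int | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Trial charges for failure-rate estimator calibration.

    Failures are drawn symmetric about zero (N(0, noise_sd_pc)); successes sit
    ``separation_sd`` noise SDs above.  Returns ``(charges, is_failure)``.
    """
    rng = np.random.default_rng(rng)
    fail = rng.random(n) < p_fail
    charges = np.where(fail, rng.normal(0.0, noise_sd_pc, n),
                       rng.normal(separation_sd * noise_sd_pc, noise_sd_pc, n))
    return charges, fail


# ---------------------------------------------------------------------------
# pharmacology time-course simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GlycineEffect:
    """Phenomenological glycine-competition effect on evoked IPSCs.

    ``amplitude_scale`` is the steady-state multiplicative factor on the
    evoked amplitude; ``a2_fraction_scale`` scales the relative weight of the
    slow decay component A2/(A1+A2); both approach their plateau with
    first-order kinetics (``onset_tau`` min) after drug onset.  The defaults
    are calibrated in closed form so that, combined with the 20%/10 min
    rundown, the measured charge ratio t2/t1 is 0.62 and the slow-fraction
    ratio matches 0.40/0.49.
    """

    amplitude_scale: float = 0.79
    a2_fraction_scale: float = 0.82
    onset_tau: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 < self.amplitude_scale <= 1.0:
            raise ValueError("amplitude_scale must be in (0, 1]")
        if not 0.0 < self.a2_fraction_scale <= 1.0:
            raise ValueError("a2_fraction_scale must be in (0, 1]")


@dataclass(frozen=True)
class TimecourseKinetics:
    """Compound eIPSC shape for 10 Hz train experiments (ms, pA)."""

    peak: float = 100.0
    tau1: float = 3.48
    tau2: float = 36.5
    a2_fraction: float = 0.5
    rise_tau: float = 0.3
    onset_delay: float = 1.5   # ms after the stimulus


@dataclass
class SynthTimecourseConfig:
    """One pharmacology time-course experiment (10 Hz electrical train)."""

    duration_min: float = 17.0
    stim_rate: float = 10.0
    baseline_min: float = 3.0
    drug_onset_min: float = 3.0
    drug_duration_min: float = 5.0
    rundown_rate: float = 0.20      # fractional loss of amplitude per 10 min
    glycine_effect: GlycineEffect = field(default_factory=GlycineEffect)
    apply_drug: bool = True
    kinetics: TimecourseKinetics = field(default_factory=TimecourseKinetics)
    noise_sd: float = 2.5
    amplitude_cv: float = 0.1       # sweep-to-sweep multiplicative CV
    seed: int = 0
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    first_stim_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.drug_onset_min < self.baseline_min - 1e-9:
            raise ValueError("drug onset must not precede the end of the baseline")
        if not 0.0 <= self.rundown_rate < 1.0:
            raise ValueError("rundown_rate must be in [0, 1)")


@dataclass
class TimecourseTruth:
    """Per-sweep ground truth of the time-course generator."""

    sweep_times_min: np.ndarray
    amp_factor: np.ndarray       # rundown x glycine amplitude factor (noiseless)
    a2_fraction: np.ndarray      # effective slow fraction per sweep
    config: SynthTimecourseConfig

    def expected_charge_ratio(self, t_num: np.ndarray, t_den: np.ndarray) -> float:
        """Noiseless charge ratio between two sets of sweep indices."""
        k = self.config.kinetics

        def charge(sel: np.ndarray) -> float:
            c1 = k.tau1 ** 2 / (k.rise_tau + k.tau1)
            c2 = k.tau2 ** 2 / (k.rise_tau + k.tau2)
            f2 = self.a2_fraction[sel]
            return float(np.mean(self.amp_factor[sel] * ((1 - f2) * c1 + f2 * c2)))

        return charge(np.asarray(t_num)) / charge(np.asarray(t_den))


def simulate_timecourse(config: SynthTimecourseConfig
                        ) -> tuple[np.ndarray, np.ndarray, TimecourseTruth]:
    """Continuous 10 Hz-train recording; returns (trace, stim_times_ms, truth).

    The evoked amplitude undergoes multiplicative exponential rundown
    (calibrated so the fractional loss at 10 min equals ``rundown_rate``) and,
    after drug onset, first-order glycine scaling of the amplitude and of the
    slow-component fraction.
    """
    cfg = config
    fs = cfg.sampling_rate
    k = cfg.kinetics
    isi_ms = 1000.0 / cfg.stim_rate
    n_sweeps = int(round(cfg.duration_min * 60.0 * cfg.stim_rate))
    if n_sweeps < 1:
        raise ValueError("duration too short for a single stimulus")
    stim_times = cfg.first_stim_ms + isi_ms * np.arange(n_sweeps)
    total_ms = stim_times[-1] + 2 * isi_ms
    n_total = ms_to_idx(total_ms, fs)
    ss = np.random.SeedSequence(cfg.seed)
    rng, rng_noise = (np.random.default_rng(c) for c in ss.spawn(2))
    trace = filtered_noise(n_total, cfg.noise_sd, rng_noise, fs)

    # per-sweep modulation factors
    t_min = stim_times / 60000.0
    if cfg.rundown_rate > 0:
        run = (1.0 - cfg.rundown_rate) ** (t_min / 10.0)
    else:
        run = np.ones(n_sweeps)
    gly = np.ones(n_sweeps)
    f2 = np.full(n_sweeps, k.a2_fraction)
    if cfg.apply_drug:
        g = cfg.glycine_effect
        dt = t_min - cfg.drug_onset_min
        on = dt > 0
        rise = -np.expm1(-np.clip(dt, 0, None) / g.onset_tau)
        # effects persist after the drug window ends (no washout recovery,
        # matching the absence of recovery after 7 min of washing)
        gly[on] = 1.0 - (1.0 - g.amplitude_scale) * rise[on]
        f2[on] = k.a2_fraction * (1.0 - (1.0 - g.a2_fraction_scale) * rise[on])
    cv = cfg.amplitude_cv
    if cv > 0:
        sigma2 = np.log1p(cv ** 2)
        trial_noise = rng.lognormal(-0.5 * sigma2, np.sqrt(sigma2), n_sweeps)
    else:
        trial_noise = np.ones(n_sweeps)
    amp = run * gly * trial_noise

    # event templates over two inter-stimulus intervals (tail carry-over)
    n_ev = ms_to_idx(2 * isi_ms, fs)
    te = np.arange(n_ev) * 1000.0 / fs - k.onset_delay
    m = te >= 0
    rise_f = np.zeros(n_ev)
    rise_f[m] = -np.expm1(-te[m] / k.rise_tau) if k.rise_tau > 0 else 1.0
    w1 = np.zeros(n_ev)
    w2 = np.zeros(n_ev)
    w1[m] = -rise_f[m] * np.exp(-te[m] / k.tau1)
    w2[m] = -rise_f[m] * np.exp(-te[m] / k.tau2)
    c1 = amp * (1.0 - f2) * k.peak
    c2 = amp * f2 * k.peak
    for j in range(n_sweeps):
        i0 = ms_to_idx(stim_times[j], fs)
        i1 = min(i0 + n_ev, n_total)
        trace[i0:i1] += c1[j] * w1[:i1 - i0] + c2[j] * w2[:i1 - i0]

    truth = TimecourseTruth(sweep_times_min=t_min, amp_factor=run * gly,
                            a2_fraction=f2, config=cfg)
    return trace, stim_times, truth


def ground_truth_frame(truth: GroundTruth) -> pd.DataFrame:
    """Flat per-trial ground-truth table (for the CSV written next to archives)."""
    df = truth.trials.copy()
    for key, val in (("p_fail_true", truth.config.p_fail),
                     ("q_slow_true", truth.config.spillover_params.q_slow),
                     ("tau_slow_true", truth.config.spillover_params.tau_slow)):
        df[key] = val
    return df
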
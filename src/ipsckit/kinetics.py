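"""Exponential decomposition of averaged IPSCs.

Decay-only fits starting at the empirical peak of the averaged,
baseline-zeroed, sign-inverted current:

* phasic / AP(+) mean traces: ``A1 exp(-t/tau1) + A2 exp(-t/tau2)``,
  with the fitted charge ``Q = (A1 tau1 + A2 tau2) / 1000`` pC and the
  slow-fraction ``A2 / (A1 + A2)``;
* delayed mean traces: a single exponential ``A exp(-t/tau)``;
* the spillover component: either a mono-exponential saturation fit to the
  cumulative charge (``cumsum`` mode) or direct tail integration from
  36 ms after the peak (``tail36`` mode).

Fits are deterministic: the initialization is fixed (tau1 from the 10-90%
decay time, tau2 from a log-linear regression of the tail, amplitudes by
linear least squares given the taus) and the refinement uses bounded
least squares.  The weighted decay time constant is the fit-free
charge-to-peak ratio Q/I, reported in ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .charge_metrics import peak_and_delay, slow_charge
from .trace_model import SweepRecord, TimeWindow, ms_to_idx

MIN_DELAYED_EVENTS = 5


@dataclass
class DecayFit:
    """Exponential decay fit of an averaged IPSC (amplitudes pA, taus ms).

    ``offset`` is a constant term absorbing any slow pedestal under the fit
    window (e.g. the spillover tail); it does not enter the fitted charge.
    """

    a1: float = np.nan
    tau1: float = np.nan
    a2: float = 0.0
    tau2: float = np.nan
    offset: float = 0.0
    rss: float = np.nan
    converged: bool = False
    model: str = "biexp"              # 'biexp' | 'monoexp'
    refit_mono: bool = False          # biexp collapsed (taus within 10%)
    flag: str = ""

    @property
    def a2_fraction(self) -> float:
        tot = self.a1 + self.a2
        return self.a2 / tot if tot > 0 else np.nan

    @property
    def q_fit(self) -> float:
        """Analytic charge of the fitted decay, pC."""
        if self.model == "monoexp":
            return self.a1 * self.tau1 / 1000.0
        return (self.a1 * self.tau1 + self.a2 * self.tau2) / 1000.0

    def weighted_tau(self, peak: float) -> float:
        return weighted_tau(self.q_fit, peak)


@dataclass
class SlowComponent:
    """Slow spillover charge and kinetics for one trial class of a pair."""

    q_slow: float                 # pC
    tau_slow: float               # ms (NaN in tail36 mode)
    fit_window: TimeWindow | None
    context: str = "AP+"          # 'AP+' | 'AP+IPSC-' | 'AP-'
    mode: str = "cumsum"
    converged: bool = False


def weighted_tau(q_pc: float, peak_pa: float) -> float:
    """Charge-to-peak ratio 1000*Q/I in ms (fit-free decay summary)."""
    if peak_pa <= 0:
        raise ValueError("peak must be positive")
    return 1000.0 * q_pc / peak_pa


def _prepare_decay(trace: np.ndarray, sampling_rate: float, t_start: float,
                   t_end: float) -> tuple[np.ndarray, np.ndarray]:
    """Decay segment (t in ms from the peak, y sign-inverted pA)."""
    trace = np.asarray(trace, dtype=float)
    i0, i1 = ms_to_idx(t_start, sampling_rate), ms_to_idx(t_end, sampling_rate)
    if i0 < 0 or i1 > trace.size or i1 - i0 < 10:
        raise ValueError("invalid fit window")
    y = -trace[i0:i1]
    t = np.arange(y.size) * 1000.0 / sampling_rate
    return t, y


def _decay_time_10_90(t: np.ndarray, y: np.ndarray) -> float:
    """Time from 90% to 10% of the initial value (tau1 seed)."""
    y0 = y[0] if y[0] > 0 else max(y.max(), 1e-9)
    try:
        t90 = t[np.nonzero(y <= 0.9 * y0)[0][0]]
        t10 = t[np.nonzero(y <= 0.1 * y0)[0][0]]
        dt = t10 - t90
    except IndexError:
        dt = 0.0
    return dt / np.log(9.0) if dt > 0 else max(t[-1] / 20.0, t[1])


def _tail_loglinear_tau(t: np.ndarray, y: np.ndarray) -> float:
    """tau2 seed from a log-linear regression of the positive tail."""
    n = y.size
    tail = slice(n // 2, n)
    tt, yy = t[tail], y[tail]
    pos = yy > 0
    if pos.sum() < 5:
        return max(t[-1] / 3.0, 1.0)
    slope = np.polyfit(tt[pos], np.log(yy[pos]), 1)[0]
    return -1.0 / slope if slope < 0 else max(t[-1] / 3.0, 1.0)


def _amps_given_taus(t: np.ndarray, y: np.ndarray,
                     taus: tuple[float, ...]) -> np.ndarray:
    basis = np.column_stack([np.exp(-t / tau) for tau in taus])
    amps, *_ = np.linalg.lstsq(basis, y, rcond=None)
    return amps


def fit_biexponential(mean_trace: np.ndarray, sampling_rate: float,
                      t_start: float, t_end: float) -> DecayFit:
    """Bi-exponential decay fit from the peak of an averaged trace.

    ``mean_trace`` is the raw-sign (negative-going), baseline-zeroed average;
    ``t_start`` is the peak time.  If the two fitted time constants end up
    within 10% of each other the trace is refit as a mono-exponential and the
    ``refit_mono`` flag is raised.
    """
    t, y = _prepare_decay(mean_trace, sampling_rate, t_start, t_end)
    c_0 = float(np.mean(y[-max(5, y.size // 20):]))      # pedestal seed
    yc = np.clip(y - c_0, 0.0, None)
    tau1_0 = _decay_time_10_90(t, yc)
    tau2_0 = max(_tail_loglinear_tau(t, yc), 2.5 * tau1_0)
    a_0 = _amps_given_taus(t, yc, (tau1_0, tau2_0))
    a_0 = np.clip(a_0, 1e-6, None)
    x0 = np.array([a_0[0], tau1_0, a_0[1], tau2_0, c_0])

    def resid(x):
        return x[0] * np.exp(-t / x[1]) + x[2] * np.exp(-t / x[3]) + x[4] - y

    try:
        sol = least_squares(resid, x0,
                            bounds=([0, 1e-3, 0, 1e-3, -np.inf],
                                    [np.inf] * 5), method="trf")
    except Exception:
        return DecayFit(converged=False, flag="fit_error")
    if not sol.success:
        return DecayFit(converged=False, flag="no_convergence")
    a1, tau1, a2, tau2, c = sol.x
    if tau1 > tau2:                      # order by speed
        a1, tau1, a2, tau2 = a2, tau2, a1, tau1
    degenerate_taus = tau2 > 0 and abs(tau2 - tau1) / tau2 < 0.10
    vanished_amp = min(a1, a2) < 1e-3 * max(a1, a2)
    if degenerate_taus or vanished_amp:
        mono = fit_monoexponential(mean_trace, sampling_rate, t_start, t_end)
        mono.refit_mono = True
        mono.flag = "taus_degenerate" if degenerate_taus else "one_component"
        return mono
    return DecayFit(a1=float(a1), tau1=float(tau1), a2=float(a2),
                    tau2=float(tau2), offset=float(c),
                    rss=float(np.sum(sol.fun ** 2)),
                    converged=True, model="biexp")


def fit_monoexponential(mean_trace: np.ndarray, sampling_rate: float,
                        t_start: float, t_end: float,
                        n_events: int | None = None) -> DecayFit:
    """Mono-exponential decay fit (delayed IPSCs).

    ``n_events`` (when given) is the number of events entering the average;
    pairs with fewer than 5 delayed IPSCs cannot be fit reliably and the
    operation refuses with a flag.
    """
    if n_events is not None and n_events < MIN_DELAYED_EVENTS:
        return DecayFit(converged=False, model="monoexp", flag="too_few_events")
    t, y = _prepare_decay(mean_trace, sampling_rate, t_start, t_end)
    c_0 = float(np.mean(y[-max(5, y.size // 20):]))
    yc = np.clip(y - c_0, 0.0, None)
    tau_0 = max(_decay_time_10_90(t, yc), 1e-2)
    a_0 = max(float(_amps_given_taus(t, yc, (tau_0,))[0]), 1e-6)

    def resid(x):
        return x[0] * np.exp(-t / x[1]) + x[2] - y

    try:
        sol = least_squares(resid, np.array([a_0, tau_0, c_0]),
                            bounds=([0, 1e-3, -np.inf], [np.inf] * 3),
                            method="trf")
    except Exception:
        return DecayFit(converged=False, model="monoexp", flag="fit_error")
    if not sol.success:
        return DecayFit(converged=False, model="monoexp", flag="no_convergence")
    return DecayFit(a1=float(sol.x[0]), tau1=float(sol.x[1]), a2=0.0,
                    tau2=np.nan, offset=float(sol.x[2]),
                    rss=float(np.sum(sol.fun ** 2)),
                    converged=True, model="monoexp")


def fit_slow_component(mean_trace: np.ndarray, sampling_rate: float,
                       peak_time: float, mode: str = "cumsum",
                       context: str = "AP+",
                       baseline_window: TimeWindow | None = None,
                       horizon_ms: float | None = None) -> SlowComponent:
    """Spillover charge of an averaged trace.

    ``cumsum`` mode fits ``C(t) = C0 + Q_slow (1 - exp(-(t - t0)/tau_slow))``
    to the cumulative charge from 50 ms after the peak (t0 fixed there) out to
    ``min(2 s, trace end)``; it falls back to ``tail36`` (direct integration
    from peak + 36 ms) with a warning when less than 1 s of horizon is
    available.  ``peak_time`` is in trace coordinates (ms).
    """
    trace = np.asarray(mean_trace, dtype=float)
    fs = sampling_rate
    duration = trace.size * 1000.0 / fs
    if horizon_ms is None:
        horizon_ms = min(duration, peak_time + 2000.0)
    if horizon_ms > duration + 1e-9:
        raise ValueError("horizon extends past the trace")
    if mode == "cumsum" and horizon_ms - peak_time < 1000.0:
        warnings.warn("horizon under 1 s: falling back to tail36 integration",
                      stacklevel=2)
        mode = "tail36"
    if mode == "tail36":
        q = slow_charge(trace, fs, peak_time,
                        horizon=TimeWindow(peak_time + 36.0, horizon_ms),
                        baseline_window=baseline_window)
        return SlowComponent(q_slow=q, tau_slow=np.nan,
                             fit_window=TimeWindow(peak_time + 36.0, horizon_ms),
                             context=context, mode="tail36", converged=True)
    if mode != "cumsum":
        raise ValueError(f"unknown mode {mode!r}")
    if baseline_window is None:
        baseline_window = TimeWindow(max(0.0, peak_time - 12.0), peak_time - 2.0)
    baseline = float(np.mean(trace[baseline_window.to_slice(fs)]))
    inverted = -(trace - baseline)
    t0 = peak_time + 50.0
    i0, i1 = ms_to_idx(t0, fs), ms_to_idx(horizon_ms, fs)
    dt = 1000.0 / fs
    cum = np.cumsum(inverted[i0:i1]) * dt / 1000.0     # pC
    t = np.arange(cum.size) * dt                        # ms from t0
    q0 = max(cum[-1] - cum[0], 1e-6)
    x0 = np.array([cum[0], q0, 300.0])

    def resid(x):
        return x[0] + x[1] * -np.expm1(-t / x[2]) - cum

    try:
        sol = least_squares(resid, x0,
                            bounds=([-np.inf, 0, 10.0], [np.inf, np.inf, 1e5]),
                            method="trf")
    except Exception:
        return SlowComponent(q_slow=np.nan, tau_slow=np.nan, fit_window=None,
                             context=context, mode="cumsum", converged=False)
    return SlowComponent(q_slow=float(sol.x[1]), tau_slow=float(sol.x[2]),
                         fit_window=TimeWindow(t0, horizon_ms), context=context,
                         mode="cumsum", converged=bool(sol.success))


# ---------------------------------------------------------------------------
# pair summary
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS = ["pair_id", "phenotype", "connected", "I_AP_pos", "Q_AP_pos",
                   "TAU1", "TAU2", "a2_fraction", "weighted_tau", "I_phasic",
                   "TAU2_phasic", "Q2_phasic", "Q_delayed", "TAU_delayed",
                   "Q_delayed_over_I_phasic", "Q_slow", "tau_slow",
                   "Q_slow_tail36", "p_fail", "delay_ms", "n_trials", "notes"]


def _mean_trace(pair, trial_ids) -> np.ndarray:
    return np.mean([pair.sweeps[k].samples for k in trial_ids], axis=0)


def _zeroed(trace: np.ndarray, fs: float, ap_time: float) -> np.ndarray:
    i0, i1 = ms_to_idx(ap_time - 10.0, fs), ms_to_idx(ap_time, fs)
    return trace - float(np.mean(trace[max(i0, 0):i1]))


def pair_summary(pair, classification, fit_end_ms: float = 120.0) -> pd.Series:
    """One summary row per pair, aggregating all kinetic and quantal metrics.

    AP(+) averages include postsynaptic failures but exclude presynaptic
    stimulation failures.  Fields that cannot be computed (missing classes,
    unconnected pair, too few delayed events) are NaN with a note.
    """
    notes: list[str] = []
    row = {c: np.nan for c in SUMMARY_COLUMNS}
    row.update(pair_id=pair.pair_id, phenotype=pair.phenotype,
               connected=pair.connected, n_trials=pair.n_trials, notes="")
    cls = classification
    row["p_fail"] = cls.failures.p_fail if cls.failures is not None else np.nan
    ap_ids = cls.ap_trial_ids
    if ap_ids.size == 0:
        row["notes"] = "no AP trials"
        return pd.Series(row)
    fs = pair.sampling_rate
    ap_time = float(np.mean([pair.sweeps[k].ap_time for k in ap_ids]))
    mean_ap = _zeroed(_mean_trace(pair, ap_ids), fs, ap_time)
    mean_sweep = SweepRecord(samples=mean_ap, sampling_rate=fs,
                             stim_time=pair.sweeps[ap_ids[0]].stim_time)
    peak, peak_t, delay, det = peak_and_delay(mean_sweep, ap_time)
    row["I_AP_pos"], row["delay_ms"] = peak, delay
    if not pair.connected:
        row["notes"] = "unconnected"
        return pd.Series(row)
    if not det:
        notes.append("AP+ peak below noise")
    t_end = min(peak_t + fit_end_ms, pair.sweeps[0].duration_ms)
    fit = fit_biexponential(mean_ap, fs, peak_t, t_end)
    if fit.converged and fit.model == "biexp":
        row.update(TAU1=fit.tau1, TAU2=fit.tau2, a2_fraction=fit.a2_fraction,
                   Q_AP_pos=fit.q_fit, weighted_tau=fit.weighted_tau(peak))
    else:
        notes.append(f"AP+ fit: {fit.flag or 'failed'}")

    classes = cls.event_classes
    phasic_ids = [k for k in ap_ids if classes.get(int(k)) == "phasic"]
    delayed_ids = [k for k in ap_ids if classes.get(int(k)) == "delayed"]
    fail_ids = [k for k in ap_ids if classes.get(int(k)) == "failure"]
    if phasic_ids:
        mean_ph = _zeroed(_mean_trace(pair, phasic_ids), fs, ap_time)
        ph_sweep = SweepRecord(samples=mean_ph, sampling_rate=fs,
                               stim_time=mean_sweep.stim_time)
        i_ph, pt_ph, _, _ = peak_and_delay(ph_sweep, ap_time)
        row["I_phasic"] = i_ph
        fph = fit_biexponential(mean_ph, fs, pt_ph,
                                min(pt_ph + fit_end_ms, pair.sweeps[0].duration_ms))
        if fph.converged and fph.model == "biexp":
            row["TAU2_phasic"] = fph.tau2
            row["Q2_phasic"] = fph.a2 * fph.tau2 / 1000.0
        else:
            notes.append("phasic fit failed")
    if delayed_ids:
        mean_de = _zeroed(_mean_trace(pair, delayed_ids), fs, ap_time)
        de_sweep = SweepRecord(samples=mean_de, sampling_rate=fs,
                               stim_time=mean_sweep.stim_time)
        _, pt_de, _, _ = peak_and_delay(de_sweep, ap_time)
        fde = fit_monoexponential(mean_de, fs, pt_de,
                                  min(pt_de + 80.0, pair.sweeps[0].duration_ms),
                                  n_events=len(delayed_ids))
        if fde.converged:
            row["TAU_delayed"] = fde.tau1
            row["Q_delayed"] = fde.q_fit
            if np.isfinite(row["I_phasic"]) and row["I_phasic"] > 0:
                row["Q_delayed_over_I_phasic"] = weighted_tau(fde.q_fit,
                                                              row["I_phasic"])
        else:
            notes.append(f"delayed fit: {fde.flag or 'failed'}")

    horizon = pair.sweeps[0].duration_ms
    # the full pre-stimulus region gives the steadiest zero for the long
    # integrations (a small baseline error integrates into pC over 2 s)
    stim = pair.sweeps[ap_ids[0]].stim_time
    slow_bsl = TimeWindow(0.0, max(stim - 1.0, 2.0))
    slow = fit_slow_component(mean_ap, fs, peak_t, mode="cumsum",
                              horizon_ms=horizon, baseline_window=slow_bsl)
    if slow.converged:
        row["Q_slow"], row["tau_slow"] = slow.q_slow, slow.tau_slow
    tail = fit_slow_component(mean_ap, fs, peak_t, mode="tail36",
                              horizon_ms=horizon, baseline_window=slow_bsl)
    row["Q_slow_tail36"] = tail.q_slow
    row["notes"] = "; ".join(notes)
    return pd.Series(row)
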
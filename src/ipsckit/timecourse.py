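"""Pharmacology time-course analysis of 10 Hz electrically evoked IPSC trains.

The strength of GABAergic transmission is monitored as the charge of the
average of 100 consecutive eIPSCs (QeIPSC, one value per 10 s bin at 10 Hz),
normalized by the mean over the first 3 min of baseline.  Epoch summaries
average 1000 consecutive sweeps before (t1), at the end of the drug
application (t2) and after 7 min of washout (t3), and report the charge,
peak, charge-to-peak ratio, slow-fraction A2/(A1+A2) and 36-ms slow charge
per epoch, plus the t2/t1 and t3/t1 ratios.  Rundown is not corrected;
interleaved no-drug controls are the comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .charge_metrics import PA_MS_TO_PC, slow_charge
from .kinetics import fit_biexponential, weighted_tau
from .trace_model import SweepRecord, TimeWindow, ms_to_idx
from . import popstats

SWEEPS_PER_BIN = 100       # 10 s at 10 Hz
SWEEPS_PER_EPOCH = 1000    # 100 s at 10 Hz


@dataclass
class TimecourseSeries:
    """QeIPSC / IeIPSC over time for one cell."""

    time_min: np.ndarray        # bin centers
    q_eipsc: np.ndarray         # pC per bin
    i_eipsc: np.ndarray         # pA per bin
    normalized_q: np.ndarray
    condition: str = "control"
    baseline_min: float = 3.0

    def normalize(self, baseline_min: float | None = None) -> "TimecourseSeries":
        """(Re)normalize by the mean charge over the baseline window.

        Idempotent: normalizing an already-normalized series is a no-op up to
        floating point, because the stored normalized values are recomputed
        from ``q_eipsc`` each time.
        """
        if baseline_min is None:
            baseline_min = self.baseline_min
        sel = self.time_min < baseline_min
        if not sel.any():
            raise ValueError("no bins inside the baseline window")
        self.normalized_q = self.q_eipsc / float(np.mean(self.q_eipsc[sel]))
        self.baseline_min = baseline_min
        return self


@dataclass
class EpochSummary:
    """t1/t2/t3 epoch means and the ratios the pharmacology analysis reports."""

    epochs: pd.DataFrame        # index t1/t2/t3: charge, peak, q_over_i,
    #                             a2_fraction, slow_charge_36ms
    t2_over_t1: float
    t3_over_t1: float
    q_over_i_t2_over_t1: float
    condition: str = "control"


def _bin_average(sweeps: list[SweepRecord], lo: int, hi: int) -> np.ndarray:
    return np.mean([s.samples for s in sweeps[lo:hi]], axis=0)


def _eipsc_metrics(avg: np.ndarray, fs: float, stim_time: float
                   ) -> tuple[float, float, float]:
    """(charge pC, peak pA, peak_time ms) of an averaged eIPSC."""
    i_stim = ms_to_idx(stim_time, fs)
    baseline = float(np.mean(avg[:i_stim])) if i_stim > 0 else 0.0
    inverted = -(avg - baseline)
    dt = 1000.0 / fs
    q = float(np.trapezoid(inverted[i_stim:], dx=dt)) * PA_MS_TO_PC
    i_peak = i_stim + int(np.argmax(inverted[i_stim:]))
    return q, float(inverted[i_peak]), i_peak * dt


def qeipsc_series(sweeps: list[SweepRecord], condition: str = "control",
                  baseline_min: float = 3.0,
                  sweeps_per_bin: int = SWEEPS_PER_BIN) -> TimecourseSeries:
    """Per-10-s-bin charge and peak of the averaged eIPSC.

    ``sweeps`` are stimulus-locked segments (10 Hz protocol).  An incomplete
    final bin is dropped with a warning.
    """
    if not sweeps:
        raise ValueError("no sweeps")
    fs = sweeps[0].sampling_rate
    stim_time = sweeps[0].stim_time
    n_bins, rem = divmod(len(sweeps), sweeps_per_bin)
    if rem:
        warnings.warn(f"dropping incomplete final bin of {rem} sweeps",
                      stacklevel=2)
    if n_bins == 0:
        raise ValueError("fewer sweeps than one bin")
    q = np.empty(n_bins)
    pk = np.empty(n_bins)
    for b in range(n_bins):
        avg = _bin_average(sweeps, b * sweeps_per_bin, (b + 1) * sweeps_per_bin)
        q[b], pk[b], _ = _eipsc_metrics(avg, fs, stim_time)
    # bin length in minutes at the native stimulation rate (sweep spacing is
    # the sweep duration at 10 Hz segmentation)
    bin_min = sweeps_per_bin * sweeps[0].duration_ms / 60000.0
    time_min = (np.arange(n_bins) + 0.5) * bin_min
    series = TimecourseSeries(time_min=time_min, q_eipsc=q, i_eipsc=pk,
                              normalized_q=np.ones_like(q), condition=condition,
                              baseline_min=baseline_min)
    return series.normalize()


def default_epochs(n_sweeps: int, baseline_min: float = 3.0,
                   drug_end_min: float = 8.0, wash_min: float = 7.0,
                   stim_rate: float = 10.0) -> dict[str, tuple[int, int]]:
    """Default t1/t2/t3 sweep-index windows (1000 consecutive sweeps each).

    t1: last 1000 sweeps of the baseline; t2: last 1000 sweeps of the drug
    application; t3: the final 1000 sweeps, starting no earlier than 7 min
    after the end of the drug.
    """
    per_min = int(round(stim_rate * 60))
    t1_end = int(baseline_min * per_min)
    t2_end = int(drug_end_min * per_min)
    t3_start = max(int((drug_end_min + wash_min) * per_min),
                   n_sweeps - SWEEPS_PER_EPOCH)
    windows = {"t1": (t1_end - SWEEPS_PER_EPOCH, t1_end),
               "t2": (t2_end - SWEEPS_PER_EPOCH, t2_end),
               "t3": (t3_start, min(t3_start + SWEEPS_PER_EPOCH, n_sweeps))}
    for name, (lo, hi) in windows.items():
        if lo < 0 or hi > n_sweeps or hi - lo < 1:
            raise ValueError(f"epoch {name} does not fit into {n_sweeps} sweeps")
    return windows


def epoch_summary(sweeps: list[SweepRecord],
                  windows: dict[str, tuple[int, int]] | None = None,
                  condition: str = "control",
                  fit_end_ms: float | None = None) -> EpochSummary:
    """t1/t2/t3 summaries from 1000-sweep epoch averages."""
    if windows is None:
        windows = default_epochs(len(sweeps))
    spans = sorted(windows.values())
    for (a, b), (c, d) in zip(spans, spans[1:]):
        if c < b:
            raise ValueError("epochs must not overlap")
    fs = sweeps[0].sampling_rate
    stim_time = sweeps[0].stim_time
    rows = {}
    for name, (lo, hi) in windows.items():
        avg = _bin_average(sweeps, lo, hi)
        q, pk, pk_t = _eipsc_metrics(avg, fs, stim_time)
        i_stim = ms_to_idx(stim_time, fs)
        baseline = float(np.mean(avg[:i_stim])) if i_stim else 0.0
        zeroed = avg - baseline
        end = fit_end_ms if fit_end_ms is not None else sweeps[0].duration_ms
        fit = fit_biexponential(zeroed, fs, pk_t, end)
        a2f = fit.a2_fraction if fit.converged and fit.model == "biexp" else np.nan
        q36 = slow_charge(avg, fs, pk_t, horizon=TimeWindow(pk_t + 36.0, end),
                          baseline_window=TimeWindow(0.0, stim_time))
        rows[name] = dict(charge=q, peak=pk, q_over_i=weighted_tau(q, pk),
                          a2_fraction=a2f, slow_charge_36ms=q36)
    df = pd.DataFrame(rows).T
    return EpochSummary(
        epochs=df,
        t2_over_t1=float(df.loc["t2", "charge"] / df.loc["t1", "charge"]),
        t3_over_t1=float(df.loc["t3", "charge"] / df.loc["t1", "charge"]),
        q_over_i_t2_over_t1=float(df.loc["t2", "q_over_i"]
                                  / df.loc["t1", "q_over_i"]),
        condition=condition)


def percent_reduction(ratio: float) -> float:
    """A t2/t1 ratio of 0.83 is a 17% reduction."""
    return 100.0 * (1.0 - ratio)


def condition_contrast(group_a: np.ndarray, group_b: np.ndarray,
                       label_a: str = "control", label_b: str = "glycine"
                       ) -> dict:
    """Relative difference of mean epoch ratios between two condition groups.

    Returns ``(mean_A - mean_B) / mean_A`` in percent (how much larger the
    reduction is in group B than in group A) with a Mann-Whitney p-value.
    Each input is the per-cell ratio (e.g. t2/t1) for one condition.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 cells per condition group")
    contrast = 100.0 * (a.mean() - b.mean()) / a.mean()
    stat = popstats.group_compare(a, b, paired=False)
    return {"group_a": label_a, "group_b": label_b,
            "mean_a": float(a.mean()), "mean_b": float(b.mean()),
            "contrast_pct": float(contrast),
            "mw_statistic": stat.statistic, "p_value": stat.p_value,
            "n_a": a.size, "n_b": b.size}
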
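"""Core data types, sweep archive I/O, segmentation and presynaptic AP detection.

Conventions used throughout the package
---------------------------------------
* Currents are in pA with the raw amplifier sign: in our high-chloride,
  -70 mV recording configuration an IPSC is an inward, *negative*-going
  current.  All *reported* IPSC amplitudes and charges are positive
  magnitudes (sign-inverted), so that transmission successes carry positive
  charge and the baseline charge null is centred on zero.
* Times are in ms, referenced to the stimulus onset of each sweep
  (``stim_time``); windows are half-open ``[start, end)``; sample indices are
  0-based and obtained by rounding ``t_ms * fs / 1000`` to the nearest sample.
* The default sampling rate is 20 kHz.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

DEFAULT_SAMPLING_RATE = 20_000.0

PHENOTYPES = ("GlyT2_pos", "GlyT2_neg", "unknown")
PROTOCOLS = ("optogenetic_0p37Hz", "electrical_10Hz")
EVENT_CLASSES = ("undetermined", "phasic", "delayed", "failure")

# integer codes used in the archive's optional labels dataset
_TRI_CODE = {None: -1, False: 0, True: 1}
_TRI_DECODE = {-1: None, 0: False, 1: True}
_CLASS_CODE = {c: i for i, c in enumerate(EVENT_CLASSES)}
_CLASS_DECODE = {i: c for c, i in _CLASS_CODE.items()}


class ArchiveFormatError(ValueError):
    """Raised when a sweep archive does not conform to the documented layout."""


def ms_to_idx(t_ms: float, sampling_rate: float) -> int:
    """Convert a time in ms to the nearest 0-based sample index."""
    return int(round(t_ms * sampling_rate / 1000.0))


@dataclass(frozen=True)
class TimeWindow:
    """Half-open time window ``[start, end)`` in ms."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"TimeWindow requires end > start, got [{self.start}, {self.end})")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def to_slice(self, sampling_rate: float, t0: float = 0.0) -> slice:
        """Sample slice for this window on a grid whose time origin is ``t0`` ms."""
        return slice(ms_to_idx(self.start - t0, sampling_rate),
                     ms_to_idx(self.end - t0, sampling_rate))


@dataclass
class TrialLabels:
    """Per-trial classification labels.

    ``None`` means undetermined (not yet classified or not classifiable).
    """

    ap_success: bool | None = None
    ipsc_success: bool | None = None
    event_class: str = "undetermined"

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event_class {self.event_class!r}")

    def encode(self) -> tuple[int, int, int]:
        return (_TRI_CODE[self.ap_success], _TRI_CODE[self.ipsc_success],
                _CLASS_CODE[self.event_class])

    @classmethod
    def decode(cls, codes: Sequence[int]) -> "TrialLabels":
        return cls(ap_success=_TRI_DECODE[int(codes[0])],
                   ipsc_success=_TRI_DECODE[int(codes[1])],
                   event_class=_CLASS_DECODE[int(codes[2])])


@dataclass
class SweepRecord:
    """One stimulus-locked voltage-clamp current trace.

    Parameters
    ----------
    samples : ndarray
        Current in pA, raw amplifier sign (inward IPSC negative).
    sampling_rate : float
        Hz.
    stim_time : float
        Stimulus onset in ms from the start of the sweep.
    ap_time : float or None
        Time of the presynaptic action potential peak in ms, or ``None`` if
        the stimulation failed to evoke a spike (AP failure trial).
    labels : TrialLabels
    """

    samples: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    stim_time: float = 0.0
    ap_time: float | None = None
    labels: TrialLabels = field(default_factory=TrialLabels)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be 1-D")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if not 0.0 <= self.stim_time < self.duration_ms:
            raise ValueError("stim_time must lie within the sweep")
        if self.ap_time is not None and self.ap_time < self.stim_time:
            raise ValueError("ap_time must not precede stim_time")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_ms(self) -> float:
        return self.samples.size * 1000.0 / self.sampling_rate

    @property
    def time_ms(self) -> np.ndarray:
        """Time base in ms from sweep start (not stimulus-referenced)."""
        return np.arange(self.n_samples) * 1000.0 / self.sampling_rate


@dataclass
class PairRecording:
    """All sweeps recorded from one GoC-GrC pair.

    ``phenotype`` is the presynaptic Golgi cell's neurochemical identity
    (GlyT2_pos: mixed GABA/glycine; GlyT2_neg: pure GABAergic).  ``connected``
    is ``None`` until connectivity has been classified.
    """

    pair_id: str
    phenotype: str = "unknown"
    protocol: str = "optogenetic_0p37Hz"
    sweeps: list[SweepRecord] = field(default_factory=list)
    connected: bool | None = None

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        rates = {s.sampling_rate for s in self.sweeps}
        if len(rates) > 1:
            raise ValueError("all sweeps of a pair must share one sampling rate")

    @property
    def n_trials(self) -> int:
        return len(self.sweeps)

    @property
    def sampling_rate(self) -> float:
        if not self.sweeps:
            raise ValueError("pair has no sweeps")
        return self.sweeps[0].sampling_rate


# ---------------------------------------------------------------------------
# Archive I/O
#
# HDF5 layout:
#   /pairs/<pair_id>/sweeps     2-D float32 dataset, trials x samples, pA
#       attrs: sampling_rate_hz, phenotype, protocol, stim_time_ms
#              connected (-1 undetermined / 0 / 1)
#   /pairs/<pair_id>/ap_times   1-D float64, ms; NaN = AP failure
#   /pairs/<pair_id>/labels     optional 2-D int8, trials x 3
#       columns: ap_success, ipsc_success (-1/0/1), event_class code
# ---------------------------------------------------------------------------


def write_pair_archive(pairs: Sequence[PairRecording], path: str | Path,
                       overwrite: bool = False) -> None:
    """Write pair recordings to an HDF5 archive (see module layout notes)."""
    if not pairs:
        raise ValueError("cannot write an empty pair list")
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    with h5py.File(path, "w") as f:
        root = f.create_group("pairs")
        for pair in pairs:
            g = root.create_group(pair.pair_id)
            data = np.stack([s.samples for s in pair.sweeps]).astype(np.float32)
            ds = g.create_dataset("sweeps", data=data)
            ds.attrs["sampling_rate_hz"] = pair.sampling_rate
            ds.attrs["phenotype"] = pair.phenotype
            ds.attrs["protocol"] = pair.protocol
            ds.attrs["stim_time_ms"] = pair.sweeps[0].stim_time
            ds.attrs["connected"] = _TRI_CODE[pair.connected]
            ap = np.array([np.nan if s.ap_time is None else s.ap_time
                           for s in pair.sweeps])
            g.create_dataset("ap_times", data=ap)
            codes = np.array([s.labels.encode() for s in pair.sweeps], dtype=np.int8)
            g.create_dataset("labels", data=codes)


def read_pair_archive(path: str | Path) -> list[PairRecording]:
    """Read an HDF5 pair archive written by :func:`write_pair_archive`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pairs: list[PairRecording] = []
    with h5py.File(path, "r") as f:
        if "pairs" not in f:
            raise ArchiveFormatError("archive lacks a /pairs group")
        for pair_id, g in f["pairs"].items():
            ds = g["sweeps"]
            if "sampling_rate_hz" not in ds.attrs:
                raise ArchiveFormatError(
                    f"pair {pair_id!r}: missing sampling_rate_hz attribute")
            fs = float(ds.attrs["sampling_rate_hz"])
            if "phenotype" in ds.attrs:
                phenotype = str(ds.attrs["phenotype"])
            else:
                phenotype = "unknown"
                logger.warning("pair %s: no phenotype attribute, using 'unknown'",
                               pair_id)
            protocol = str(ds.attrs.get("protocol", "optogenetic_0p37Hz"))
            stim_time = float(ds.attrs.get("stim_time_ms", 0.0))
            connected = _TRI_DECODE[int(ds.attrs.get("connected", -1))]
            data = np.asarray(ds, dtype=float)
            if data.ndim != 2:
                raise ArchiveFormatError(f"pair {pair_id!r}: sweeps must be 2-D")
            ap = np.asarray(g["ap_times"]) if "ap_times" in g else \
                np.full(data.shape[0], np.nan)
            if ap.shape[0] != data.shape[0]:
                raise ArchiveFormatError(f"pair {pair_id!r}: ap_times length mismatch")
            if "labels" in g:
                labels = [TrialLabels.decode(row) for row in np.asarray(g["labels"])]
            else:
                labels = [TrialLabels() for _ in range(data.shape[0])]
            sweeps = [SweepRecord(samples=row, sampling_rate=fs, stim_time=stim_time,
                                  ap_time=None if np.isnan(a) else float(a),
                                  labels=lab)
                      for row, a, lab in zip(data, ap, labels)]
            pairs.append(PairRecording(pair_id=pair_id, phenotype=phenotype,
                                       protocol=protocol, sweeps=sweeps,
                                       connected=connected))
    return pairs


def write_pair_csv(pair: PairRecording, path: str | Path) -> None:
    """CSV fallback: one file per pair, long format (trial, time_ms, current_pA)."""
    import pandas as pd

    frames = []
    for k, s in enumerate(pair.sweeps):
        frames.append(pd.DataFrame({"trial": k, "time_ms": s.time_ms,
                                    "current_pA": s.samples}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_pair_csv(path: str | Path, sampling_rate: float,
                  stim_time: float = 0.0, pair_id: str | None = None) -> PairRecording:
    """Read the long-format CSV fallback into a :class:`PairRecording`.

    Sampling rate and stimulus time are not stored in the CSV and must be
    supplied by the caller.
    """
    import pandas as pd

    df = pd.read_csv(path)
    sweeps = []
    for _, sub in df.groupby("trial", sort=True):
        sweeps.append(SweepRecord(samples=sub["current_pA"].to_numpy(),
                                  sampling_rate=sampling_rate,
                                  stim_time=stim_time))
    lengths = {s.n_samples for s in sweeps}
    if len(lengths) > 1:
        raise ArchiveFormatError("inconsistent sweep lengths within pair CSV")
    return PairRecording(pair_id=pair_id or Path(path).stem, sweeps=sweeps)


# ---------------------------------------------------------------------------
# Segmentation and AP detection
# ---------------------------------------------------------------------------


def segment_train(continuous: np.ndarray, sampling_rate: float,
                  stim_times: Sequence[float], window: TimeWindow) -> list[SweepRecord]:
    """Cut a continuous recording into stimulus-locked sweeps.

    ``window`` is expressed relative to each stimulus (e.g. ``[-10, 90)`` ms
    at 10 Hz).  Each returned sweep has ``stim_time = -window.start`` so that
    downstream code sees a common time base.
    """
    continuous = np.asarray(continuous, dtype=float)
    stim_times = np.asarray(stim_times, dtype=float)
    if stim_times.size == 0:
        raise ValueError("no stimulus times given")
    if np.any(np.diff(stim_times) <= 0):
        raise ValueError("stim_times must be sorted ascending")
    if stim_times.size > 1 and window.duration > np.min(np.diff(stim_times)) + 1e-9:
        raise ValueError("window longer than the inter-stimulus interval")
    n_win = ms_to_idx(window.duration, sampling_rate)
    sweeps = []
    for t in stim_times:
        i0 = ms_to_idx(t + window.start, sampling_rate)
        if i0 < 0 or i0 + n_win > continuous.size:
            raise ValueError(f"window around stimulus at {t} ms exceeds the recording")
        sweeps.append(SweepRecord(samples=continuous[i0:i0 + n_win].copy(),
                                  sampling_rate=sampling_rate,
                                  stim_time=-window.start))
    return sweeps


def detect_ap_time(sweep: SweepRecord, search: TimeWindow, k: float = 5.0,
                   band: tuple[float, float] = (100.0, 2000.0)) -> float | None:
    """Detect the presynaptic AP in a loose cell-attached sweep.

    The trace is band-pass filtered, differentiated, and the extremum of the
    derivative inside ``search`` is compared against ``k`` times the SD of the
    pre-stimulus derivative.  ``search`` is given relative to the stimulus
    onset; the returned extremum time is in sweep coordinates (ms from sweep
    start, directly storable as ``ap_time``).  Returns ``None`` if no sample
    crosses the threshold (AP failure trial).
    """
    if search.duration < 1.0:
        raise ValueError("search window must be at least 1 ms long")
    if search.start < 0 or search.end > sweep.duration_ms - sweep.stim_time + 1e-9:
        raise ValueError("search window must lie within the sweep")
    fs = sweep.sampling_rate
    nyq = fs / 2.0
    lo = min(band[0], 0.45 * nyq)
    hi = min(band[1], 0.9 * nyq)
    sos = signal.butter(2, [lo / nyq, hi / nyq], btype="band", output="sos")
    filtered = signal.sosfiltfilt(sos, sweep.samples)
    deriv = np.gradient(filtered) * fs / 1000.0  # pA / ms
    # noise floor from the pre-stimulus derivative (excluding the final ms
    # so filter edge bleed from the stimulus artefact cannot inflate it)
    i_stim = ms_to_idx(sweep.stim_time - 1.0, fs)
    if i_stim < 10:
        raise ValueError("not enough pre-stimulus baseline for AP detection")
    sd = float(np.std(deriv[:i_stim]))
    sl = search.to_slice(fs, t0=-sweep.stim_time)
    seg = deriv[sl]
    if seg.size == 0:
        raise ValueError("empty search window")
    i_ext = int(np.argmax(np.abs(seg)))
    if np.abs(seg[i_ext]) <= k * sd:
        return None
    # the derivative extremum marks the steepest slope; the AP peak is the
    # extremum of the band-passed trace within +-0.5 ms of the crossing
    i_cross = sl.start + i_ext
    half = ms_to_idx(0.5, fs)
    lo = max(i_cross - half, 0)
    hi = min(i_cross + half + 1, filtered.size)
    i_peak = lo + int(np.argmax(np.abs(filtered[lo:hi])))
    return i_peak * 1000.0 / fs
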
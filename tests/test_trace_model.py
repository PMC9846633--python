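"""Archive round trips, train segmentation, and presynaptic AP detection."""

import h5py
import numpy as np
import pytest
from scipy import stats

from ipsckit import synthio
from ipsckit.trace_model import (ArchiveFormatError, PairRecording, SweepRecord,
                                 TimeWindow, TrialLabels, detect_ap_time,
                                 read_pair_archive, segment_train,
                                 write_pair_archive)


def _make_pairs(rng, n_pairs=3, n_sweeps=6, n_samples=400):
    pairs = []
    for i in range(n_pairs):
        sweeps = [SweepRecord(
            samples=rng.normal(0, 2, n_samples).astype(np.float32),
            sampling_rate=20000.0, stim_time=5.0,
            ap_time=8.0 if k % 2 == 0 else None,
            labels=TrialLabels(ap_success=(k % 2 == 0), event_class="phasic"
                               if k % 2 == 0 else "undetermined"))
            for k in range(n_sweeps)]
        pairs.append(PairRecording(pair_id=f"p{i}", phenotype="GlyT2_pos",
                                   sweeps=sweeps, connected=True))
    return pairs


class TestArchiveRoundTrip:
    def test_field_by_field_identity(self, tmp_path, rng):
        pairs = _make_pairs(rng)
        path = tmp_path / "arc.h5"
        write_pair_archive(pairs, path)
        back = read_pair_archive(path)
        assert len(back) == len(pairs)
        for a, b in zip(pairs, sorted(back, key=lambda p: p.pair_id)):
            assert a.pair_id == b.pair_id
            assert a.phenotype == b.phenotype
            assert a.protocol == b.protocol
            assert a.connected == b.connected
            for sa, sb in zip(a.sweeps, b.sweeps):
                np.testing.assert_array_equal(sa.samples, sb.samples)
                assert sa.sampling_rate == sb.sampling_rate
                assert sa.ap_time == sb.ap_time
                assert sa.labels == sb.labels

    def test_counts_preserved(self, tmp_path, rng):
        pair, _ = synthio.simulate_pair(
            synthio.SynthPairConfig(n_trials=64, sweep_ms=100.0, stim_time=30.0,
                                    seed=1))
        write_pair_archive([pair], tmp_path / "one.h5")
        back = read_pair_archive(tmp_path / "one.h5")
        assert len(back) == 1 and back[0].n_trials == 64
        assert back[0].sampling_rate == 20000.0

    def test_empty_list_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_pair_archive([], tmp_path / "x.h5")

    def test_overwrite_guard(self, tmp_path, rng):
        pairs = _make_pairs(rng, n_pairs=1)
        path = tmp_path / "arc.h5"
        write_pair_archive(pairs, path)
        with pytest.raises(FileExistsError):
            write_pair_archive(pairs, path)
        write_pair_archive(pairs, path, overwrite=True)

    def test_missing_phenotype_defaults_to_unknown(self, tmp_path, rng):
        pairs = _make_pairs(rng, n_pairs=1)
        path = tmp_path / "arc.h5"
        write_pair_archive(pairs, path)
        with h5py.File(path, "a") as f:
            del f["pairs/p0/sweeps"].attrs["phenotype"]
        assert read_pair_archive(path)[0].phenotype == "unknown"

    def test_missing_sampling_rate_is_format_error(self, tmp_path, rng):
        pairs = _make_pairs(rng, n_pairs=1)
        path = tmp_path / "arc.h5"
        write_pair_archive(pairs, path)
        with h5py.File(path, "a") as f:
            del f["pairs/p0/sweeps"].attrs["sampling_rate_hz"]
        with pytest.raises(ArchiveFormatError):
            read_pair_archive(path)


class TestSegmentTrain:
    def test_sweep_count_10hz(self):
        fs = 20000.0
        trace = np.zeros(int(10.5 * fs))          # 10.5 s
        stim = 100.0 + 100.0 * np.arange(100)     # 10 s at 10 Hz
        sweeps = segment_train(trace, fs, stim, TimeWindow(-10.0, 90.0))
        assert len(sweeps) == 100
        assert all(s.n_samples == 2000 for s in sweeps)
        assert all(s.stim_time == 10.0 for s in sweeps)

    def test_constant_zero_input(self):
        fs = 20000.0
        sweeps = segment_train(np.zeros(int(fs)), fs, [200.0, 400.0],
                               TimeWindow(0.0, 100.0))
        assert all(np.all(s.samples == 0) for s in sweeps)

    def test_no_gap_no_overlap(self):
        """Contiguous windows tile the recording sample-exactly."""
        fs = 20000.0
        trace = np.arange(int(fs), dtype=float)
        stim = 100.0 * np.arange(1, 8)
        sweeps = segment_train(trace, fs, stim, TimeWindow(0.0, 100.0))
        joined = np.concatenate([s.samples for s in sweeps])
        i0 = int(stim[0] * fs / 1000)
        np.testing.assert_array_equal(joined, trace[i0:i0 + joined.size])

    def test_window_exceeding_isi_rejected(self):
        with pytest.raises(ValueError):
            segment_train(np.zeros(20000), 20000.0, [100.0, 150.0],
                          TimeWindow(0.0, 100.0))

    def test_segmented_events_at_fixed_latency(self):
        """Each segmented sweep holds exactly one event at the known latency."""
        cfg = synthio.SynthTimecourseConfig(duration_min=0.5, noise_sd=0.0,
                                            amplitude_cv=0.0, rundown_rate=0.0,
                                            apply_drug=False, seed=0)
        trace, stim, _ = synthio.simulate_timecourse(cfg)
        sweeps = segment_train(trace, cfg.sampling_rate, stim,
                               TimeWindow(-10.0, 90.0))
        mins = np.array([np.argmin(s.samples) for s in sweeps])
        assert np.all(mins == mins[0])            # same latency everywhere
        t_peak = mins[0] / cfg.sampling_rate * 1000.0 - 10.0
        assert 1.5 < t_peak < 4.0                 # onset delay + rise to peak


class TestDetectApTime:
    def test_detects_spike_within_tolerance(self):
        hits = []
        for seed in range(20):
            sw = synthio.cell_attached_sweep(ap_time=13.0, snr=10.0, rng=seed)
            t = detect_ap_time(sw, TimeWindow(0.0, 10.0))
            assert t is not None
            hits.append(t)
        assert np.all(np.abs(np.array(hits) - 13.0) <= 0.1)

    def test_pure_noise_is_ap_failure(self):
        for seed in range(30):
            sw = synthio.cell_attached_sweep(ap_time=13.0, snr=10.0, rng=seed,
                                             spike=False)
            assert detect_ap_time(sw, TimeWindow(0.0, 10.0)) is None

    def test_detection_rate_tracks_spike_rate(self, rng):
        """Detected AP rate on 62%-spiking sweeps within the binomial 95% CI."""
        p_true, n = 0.62, 100
        detected = 0
        for k in range(n):
            spike = rng.random() < p_true
            sw = synthio.cell_attached_sweep(ap_time=13.0, snr=10.0,
                                             rng=int(rng.integers(2 ** 31)),
                                             spike=spike)
            detected += detect_ap_time(sw, TimeWindow(0.0, 10.0)) is not None
        lo, hi = stats.binom.interval(0.95, n, p_true)
        assert lo <= detected <= hi

    def test_false_positive_rate_on_pure_noise(self):
        """At the default threshold, noise sweeps trigger <= 1% detections."""
        fp = sum(detect_ap_time(
            synthio.cell_attached_sweep(ap_time=13.0, rng=seed + 5000,
                                        spike=False),
            TimeWindow(0.0, 10.0)) is not None for seed in range(200))
        assert fp / 200 <= 0.01

    def test_short_search_window_rejected(self):
        sw = synthio.cell_attached_sweep(ap_time=13.0)
        with pytest.raises(ValueError):
            detect_ap_time(sw, TimeWindow(2.0, 2.5))


def test_sweep_invariants():
    with pytest.raises(ValueError):
        SweepRecord(samples=np.zeros(100), sampling_rate=-1.0)
    with pytest.raises(ValueError):
        SweepRecord(samples=np.zeros(100), stim_time=500.0)
    with pytest.raises(ValueError):
        SweepRecord(samples=np.zeros(100), stim_time=2.0, ap_time=1.0)
    with pytest.raises(ValueError):
        TimeWindow(5.0, 5.0)
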
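"""EEG filtering, spike/train detection, and rule-based classification."""

import numpy as np
import pytest

from epiphys import eeg, io, synth

FS = 500.0


class TestPreprocess:
    def test_60hz_line_noise_attenuated(self):
        t = np.arange(int(60 * FS)) / FS
        rec = io.EEGRecord(signal=100.0 * np.sin(2 * np.pi * 60.0 * t),
                           sampling_rate=FS)
        out = eeg.preprocess(rec)
        mid = out[int(10 * FS):int(50 * FS)]
        assert np.abs(mid).max() < 5.0  # < 5% of input amplitude

    def test_dc_offset_removed(self):
        rng = np.random.default_rng(0)
        rec = io.EEGRecord(signal=300.0 + rng.normal(0, 10, int(60 * FS)),
                           sampling_rate=FS)
        out = eeg.preprocess(rec)
        assert abs(out.mean()) < 1.0

    def test_10hz_passband_preserved(self):
        t = np.arange(int(60 * FS)) / FS
        rec = io.EEGRecord(signal=100.0 * np.sin(2 * np.pi * 10.0 * t),
                           sampling_rate=FS)
        out = eeg.preprocess(rec)
        mid = out[int(10 * FS):int(50 * FS)]
        assert np.abs(mid).max() == pytest.approx(100.0, rel=0.02)

    def test_low_rate_rejected(self):
        rec = io.EEGRecord(signal=np.zeros(1000), sampling_rate=100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            eeg.preprocess(rec)


class TestRollingRms:
    def test_constant_trace(self):
        out = eeg.rolling_rms(np.full(int(120 * FS), -3.0), FS)
        np.testing.assert_allclose(out, 3.0, atol=1e-12)

    def test_gaussian_noise_converges_to_sigma(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1.0, int(180 * FS))
        out = eeg.rolling_rms(x, FS)
        assert out[int(120 * FS):].mean() == pytest.approx(1.0, abs=0.02)

    def test_variance_step_rises_monotonically(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 1.0, int(120 * FS)),
                            rng.normal(0, 10.0, int(60 * FS))])
        out = eeg.rolling_rms(x, FS)
        after = out[int(120 * FS):int(150 * FS)]
        # RMS after the variance step climbs (allow tiny sample wobble)
        assert after[-1] > after[0]
        assert np.min(np.diff(after[::250])) > -0.05

    def test_same_length_and_expanding_start(self):
        x = np.ones(1000)
        out = eeg.rolling_rms(x, FS)
        assert out.size == 1000
        assert out[0] == 1.0


class TestDetectSpikes:
    def test_background_noise_alone_silent(self):
        rec, _ = synth.gen_eeg(seed=3, duration_s=600)
        f = eeg.preprocess(rec)
        spikes = eeg.detect_spikes_eeg(f, eeg.rolling_rms(f, FS), FS)
        assert len(spikes) == 0

    def test_inserted_spikes_found_at_times(self):
        times = [100.0, 200.0, 300.0]
        rec, _ = synth.gen_eeg(seed=4, duration_s=400,
                               train_schedule=[{"start_s": t, "n_spikes": 1}
                                               for t in times])
        f = eeg.preprocess(rec)
        spikes = eeg.detect_spikes_eeg(f, eeg.rolling_rms(f, FS), FS)
        assert len(spikes) == 3
        for s, t in zip(spikes, times):
            assert s.time_s == pytest.approx(t + 0.02, abs=0.05)
            assert s.amplitude_uV > 200.0

    def test_low_amplitude_spikes_below_floor_ignored(self):
        rec, _ = synth.gen_eeg(seed=5, duration_s=300,
                               spike_amplitude_uV=150.0,
                               train_schedule=[{"start_s": 100.0}])
        f = eeg.preprocess(rec)
        spikes = eeg.detect_spikes_eeg(f, eeg.rolling_rms(f, FS), FS)
        assert len(spikes) == 0

    def test_raising_floor_never_increases_counts(self):
        rec, _ = synth.gen_eeg(seed=6, duration_s=300,
                               train_schedule=[{"start_s": 60.0},
                                               {"start_s": 200.0}])
        f = eeg.preprocess(rec)
        rms = eeg.rolling_rms(f, FS)
        counts = [len(eeg.detect_spikes_eeg(f, rms, FS,
                                            amplitude_floor_uV=floor))
                  for floor in (200.0, 300.0, 450.0)]
        assert counts[0] >= counts[1] >= counts[2]


def oracle_trains(times, lo=0.05, hi=0.6, min_spikes=5, min_dur=3.0):
    """Brute force: absorb sub-lo complexes, then every maximal segment of
    consecutive ISIs within the band, filtered by size and span."""
    times = np.sort(np.asarray(times, dtype=float))
    if times.size == 0:
        return []
    merged = [times[0]]
    for t in times[1:]:
        if t - merged[-1] >= lo:
            merged.append(t)
    times = np.asarray(merged)
    isi_ok = [(b - a <= hi) for a, b in zip(times, times[1:])]
    segments = []
    start = 0
    for i, ok in enumerate(isi_ok + [False]):
        if not ok:
            segments.append((start, i))
            start = i + 1
    out = []
    for s, e in segments:
        seg = times[s:e + 1]
        if seg.size >= min_spikes and seg[-1] - seg[0] >= min_dur:
            out.append(seg)
    return out


class TestDetectTrains:
    def test_ten_spikes_at_04s_isi(self):
        trains = eeg.detect_trains(np.arange(10) * 0.4 + 5.0)
        assert len(trains) == 1
        assert trains[0].n_spikes == 10
        assert trains[0].duration_s == pytest.approx(3.6)

    def test_short_duration_rejected(self):
        # 6 spikes at 0.4 s span 2.0 s < 3 s
        assert eeg.detect_trains(np.arange(6) * 0.4) == []

    def test_out_of_band_isi_breaks_chain(self):
        times = np.concatenate([np.arange(10) * 0.4,
                                [10.0 + 0.4 * k for k in range(10)]])
        trains = eeg.detect_trains(times)
        assert len(trains) == 2

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_enumeration_oracle_on_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(0, 21)
        times = np.sort(rng.uniform(0, 30, n).round(3))
        got = eeg.detect_trains(times)
        want = oracle_trains(times)
        assert len(got) == len(want)
        for g, w in zip(got, want):
            np.testing.assert_allclose(g.spike_times_s, w)


class TestClassification:
    def _detect(self, rec):
        f = eeg.preprocess(rec)
        spikes = eeg.detect_spikes_eeg(f, eeg.rolling_rms(f, FS), FS)
        trains = eeg.detect_trains(spikes)
        return f, spikes, trains

    def test_train_without_annotation_is_run_of_spikes(self):
        rec, _ = synth.gen_eeg(seed=7, duration_s=400,
                               train_schedule=[{"start_s": 120.0}])
        f, spikes, trains = self._detect(rec)
        events = eeg.classify_events(trains, spikes,
                                     rec.behavior_annotations, f, FS)
        assert [e.label for e in events] == ["run_of_spikes"]

    def test_convulsive_annotation_makes_seizure(self):
        rec, _ = synth.gen_eeg(seed=8, duration_s=400,
                               train_schedule=[{"start_s": 120.0,
                                                "behavior": "convulsive"}])
        f, spikes, trains = self._detect(rec)
        events = eeg.classify_events(trains, spikes,
                                     rec.behavior_annotations, f, FS)
        assert [e.label for e in events] == ["seizure"]

    def test_narrow_isolated_spike_with_spasm_is_myoclonic(self):
        rec, _ = synth.gen_eeg(seed=9, duration_s=400,
                               myoclonic_times_s=[150.0])
        f, spikes, trains = self._detect(rec)
        events = eeg.classify_events(trains, spikes,
                                     rec.behavior_annotations, f, FS)
        assert [e.label for e in events] == ["myoclonic"]
        assert events[0].evidence["width_ms"] < 200.0

    def test_fatal_scenario_classified(self):
        rec, _ = synth.gen_eeg(seed=10, duration_s=900, fatal_scenario=True,
                               fatal_train_start_s=400.0)
        f, spikes, trains = self._detect(rec)
        events = eeg.classify_events(trains, spikes,
                                     rec.behavior_annotations, f, FS)
        assert [e.label for e in events] == ["fatal_seizure"]
        assert events[0].evidence["post_event_suppression"]

    def test_labels_partition_events(self):
        rec, _ = synth.gen_eeg(
            seed=11, duration_s=1200,
            train_schedule=[{"start_s": 100.0, "behavior": "convulsive"},
                            {"start_s": 400.0}],
            myoclonic_times_s=[700.0], fatal_scenario=True,
            fatal_train_start_s=900.0)
        f, spikes, trains = self._detect(rec)
        events = eeg.classify_events(trains, spikes,
                                     rec.behavior_annotations, f, FS)
        assert sorted(e.label for e in events) == [
            "fatal_seizure", "myoclonic", "run_of_spikes", "seizure"]


class TestRaster:
    def test_empty_events_header_only(self):
        df = eeg.export_raster([])
        assert list(df.columns) == ["animal_id", "label", "onset_s",
                                    "duration_s"]
        assert df.empty

    def test_grouped_by_animal(self):
        events = {
            "m2": [eeg.ClassifiedEvent(10.0, 5.0, "seizure")],
            "m1": [eeg.ClassifiedEvent(1.0, 3.0, "run_of_spikes"),
                   eeg.ClassifiedEvent(20.0, 0.1, "myoclonic")],
        }
        df = eeg.export_raster(events)
        assert len(df) == 3
        assert list(df["animal_id"]) == ["m1", "m1", "m2"]

    def test_round_trip_through_event_table(self, tmp_path):
        events = [eeg.ClassifiedEvent(10.0, 5.0, "seizure"),
                  eeg.ClassifiedEvent(100.0, 14.5, "run_of_spikes")]
        df = eeg.export_raster(events)
        io.write_event_table(df.rename(columns={}), tmp_path / "raster.csv")
        back = io.read_event_table(tmp_path / "raster.csv")
        assert list(back["label"]) == ["seizure", "run_of_spikes"]
        np.testing.assert_allclose(back["onset_s"], [10.0, 100.0])
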
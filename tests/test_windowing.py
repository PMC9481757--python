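"""Segmentation geometry, labeling intervals, balancing and hygiene."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from preictal.io import SeizureEvent
from preictal.windowing import (
    OVERLAP_GRID,
    TrialConfig,
    WindowSpec,
    build_balanced_trainset,
    build_testset,
    interictal_intervals,
    preictal_interval,
    segment_interval,
)

from conftest import make_recording

SPEC = WindowSpec()


class TestTrialConfig:
    def test_trial_presets(self):
        t1, t2 = TrialConfig.trial(1), TrialConfig.trial(2)
        assert (t1.sph_min, t1.sop_min) == (5.0, 25.0)
        assert (t2.sph_min, t2.sop_min) == (10.0, 20.0)

    @pytest.mark.parametrize("sph,sop", [(-1, 25), (5, 0), (10, 25)])
    def test_invalid_trials(self, sph, sop):
        with pytest.raises(ValueError):
            TrialConfig(sph_min=sph, sop_min=sop)


class TestPreictalInterval:
    def test_trial1_window(self):
        span = preictal_interval(SeizureEvent(3600.0, 3660.0), TrialConfig.trial(1))
        assert span == (1800.0, 3300.0)

    def test_trial2_window(self):
        span = preictal_interval(SeizureEvent(3600.0, 3660.0), TrialConfig.trial(2))
        assert span == (1800.0, 3000.0)

    def test_insufficient_preonset_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            span = preictal_interval(SeizureEvent(1200.0, 1260.0),
                                     TrialConfig.trial(1))
        assert span is None
        assert "skipped" in caplog.text


class TestInterictalIntervals:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_per_second_scan(self, seed):
        """Interval arithmetic equals a brute-force per-second label scan.

        Integer onsets/margins make the half-open boundaries exact: the
        exclusion zone of each seizure is [onset - 30 min - margin,
        offset + margin).
        """
        rng = np.random.default_rng(seed)
        duration = 4 * 3600
        rec = make_recording(20.0, seed=seed)
        rec.data = np.repeat(rec.data, duration // 20, axis=1)  # cheap long rec
        onsets = np.sort(rng.integers(0, duration - 120,
                                      size=rng.integers(0, 4)))
        events = [SeizureEvent(float(o), float(o + 60), rec.recording_id)
                  for i, o in enumerate(onsets)
                  if all(o - p >= 2000 for p in onsets[:i])]
        margin_min = 10
        got = interictal_intervals(events, rec, margin_min)
        scan = np.ones(duration, bool)
        for e in events:
            lo = max(0, int(e.onset) - 1800 - margin_min * 60)
            hi = min(duration, int(e.offset) + margin_min * 60)
            scan[lo:hi] = False
        mask = np.zeros(duration, bool)
        for lo, hi in got:
            mask[int(lo):int(hi)] = True
        assert np.array_equal(mask, scan)

    def test_no_events_whole_recording(self):
        rec = make_recording(30.0)
        assert interictal_intervals([], rec) == [(0.0, 30.0)]

    def test_intervals_sorted_disjoint(self):
        rec = make_recording(60.0)
        rec.data = np.repeat(rec.data, 600, axis=1)  # 10 hours
        events = [SeizureEvent(7200.0, 7260.0, rec.recording_id),
                  SeizureEvent(21600.0, 21660.0, rec.recording_id)]
        got = interictal_intervals(events, rec, margin_min=60.0)
        assert got == sorted(got)
        for (a, b), (c, d) in zip(got, got[1:]):
            assert b < c


class TestSegmentInterval:
    def test_25_minutes_gives_300_windows(self):
        rec = make_recording(1500.0)
        assert len(segment_interval(rec, (0.0, 1500.0), SPEC, 0.0)) == 300

    def test_20_minutes_gives_240_windows(self):
        rec = make_recording(1200.0)
        assert len(segment_interval(rec, (0.0, 1200.0), SPEC, 0.0)) == 240

    def test_60s_half_overlap_gives_23_windows(self):
        rec = make_recording(60.0)
        segs = segment_interval(rec, (0.0, 60.0), SPEC, 0.5)
        assert len(segs) == 23
        assert [s.t_start for s in segs] == [2.5 * i for i in range(23)]

    def test_interval_shorter_than_window_is_empty(self):
        rec = make_recording(10.0)
        assert segment_interval(rec, (0.0, 4.0), SPEC, 0.0) == []

    def test_window_is_16x1280(self):
        rec = make_recording(30.0)
        seg = segment_interval(rec, (0.0, 30.0), SPEC, 0.0)[0]
        assert seg.x.shape == (16, 1280)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(duration=st.integers(5, 200),
           overlap=st.sampled_from(OVERLAP_GRID))
    def test_count_matches_enumeration(self, duration, overlap):
        """count == floor((D - win) / (win*(1-o))) + 1, by direct enumeration."""
        rec = make_recording(float(duration), seed=0)
        got = segment_interval(rec, (0.0, float(duration)), SPEC, overlap)
        win, fs = 1280, 256
        stride = int(round(win * (1 - overlap)))
        expected, s = 0, 0
        while s + win <= duration * fs:
            expected += 1
            s += stride
        assert len(got) == expected
        assert all(g.x.shape == (16, 1280) for g in got)
        # no window crosses the interval boundary
        assert all(g.t_start + 5.0 <= duration + 1e-9 for g in got)


def _one_patient_pairs(seed=0, preictal_trial=None, interictal_s=1500.0):
    """A seizure recording plus a seizure-free recording for one patient."""
    seiz = make_recording(2400.0, seed=seed, recording_id="p0_s0")
    events = [SeizureEvent(1860.0, 1920.0, "p0_s0")]
    inter = make_recording(interictal_s, seed=seed + 1, recording_id="p0_i0")
    return [(seiz, events), (inter, [])]


class TestBalancedTrainset:
    def test_exact_balance_and_determinism(self):
        pairs = _one_patient_pairs()
        a = build_balanced_trainset(pairs, TrialConfig.trial(1), SPEC, seed=5,
                                    max_per_class=60)
        b = build_balanced_trainset(pairs, TrialConfig.trial(1), SPEC, seed=5,
                                    max_per_class=60)
        assert a.count("preictal") == a.count("interictal") == 60
        assert a.manifest().equals(b.manifest())

    def test_different_seed_changes_subsample(self):
        pairs = _one_patient_pairs()
        a = build_balanced_trainset(pairs, TrialConfig.trial(1), SPEC, seed=1,
                                    max_per_class=60)
        b = build_balanced_trainset(pairs, TrialConfig.trial(1), SPEC, seed=2,
                                    max_per_class=60)
        assert not a.manifest().equals(b.manifest())

    def test_overlap_escalates_for_short_preictal(self):
        # SPH=5/SOP=10 gives a 10-minute preictal span: 120 non-overlap
        # windows. Target 200 forces the 0.5-overlap level (239 windows,
        # enumerated independently in the geometry tests).
        trial = TrialConfig(sph_min=5.0, sop_min=10.0)
        pairs = _one_patient_pairs()
        ts = build_balanced_trainset(pairs, trial, SPEC, seed=0,
                                     max_per_class=200)
        assert ts.count("preictal") == ts.count("interictal") == 200
        pre = [s for s in ts.segments if s.label == "preictal"]
        assert all(s.from_overlap for s in pre)
        starts = sorted(s.t_start for s in pre)
        smallest_gap = min(np.diff(starts))
        assert smallest_gap == pytest.approx(2.5)  # stride of the 0.5 level

    def test_no_preictal_data_raises(self):
        inter = make_recording(600.0, recording_id="p0_i0")
        with pytest.raises(ValueError, match="preictal"):
            build_balanced_trainset([(inter, [])], TrialConfig.trial(1), SPEC,
                                    seed=0)

    def test_preictal_and_interictal_spans_disjoint(self):
        pairs = _one_patient_pairs()
        ts = build_balanced_trainset(pairs, TrialConfig.trial(1), SPEC, seed=0,
                                     max_per_class=40, margin_min=0.5)
        spans = {}
        for s in ts.segments:
            spans.setdefault(s.label, []).append((s.recording_id, s.t_start))
        pre = {(r, t) for r, t in spans["preictal"]}
        for r, t in spans["interictal"]:
            for rp, tp in pre:
                assert r != rp or abs(t - tp) >= 5.0


class TestPersistence:
    def test_segment_set_round_trip(self, tmp_path):
        from preictal.windowing import load_segment_set, save_segment_set

        pairs = _one_patient_pairs()
        ts = build_balanced_trainset(pairs, TrialConfig.trial(1), SPEC, seed=0,
                                     max_per_class=20)
        save_segment_set(ts, tmp_path / "set")
        back = load_segment_set(tmp_path / "set")
        assert back.split == ts.split and back.trial == ts.trial
        assert back.manifest().equals(ts.manifest())
        assert np.allclose(back.X, ts.X)


class TestTestset:
    def test_no_overlap_no_balance_chronological(self):
        pairs = _one_patient_pairs(interictal_s=600.0)
        ts = build_testset(pairs, TrialConfig.trial(1), SPEC, margin_min=0.5)
        assert not any(s.from_overlap for s in ts.segments)
        assert ts.count("preictal") == 300
        assert ts.count("preictal") != ts.count("interictal")
        by_rec = {}
        for s in ts.segments:
            by_rec.setdefault(s.recording_id, []).append(s.t_start)
        for starts in by_rec.values():
            assert starts == sorted(starts)
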
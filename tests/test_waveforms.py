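"""Preprocessing, R-peak/fiducial detection and the 205-feature extraction."""

import numpy as np
import pytest

from cardiocausal.cohort import pulse_landmark_times, pulse_waveform
from cardiocausal.cohort import _pulse_d1, _pulse_d2
from cardiocausal.registry import (
    CATEGORY_RANGES,
    LANDMARKS,
    build_registry,
    feature_column,
)
from cardiocausal.waveforms import (
    FiducialSet,
    WaveformRecord,
    detect_fiducials,
    detect_r_peaks,
    extract_beat_features,
    extract_record_features,
    preprocess,
)

FS = 125.0


def synth_record(ecg, ppg, fs=FS, label=0):
    return WaveformRecord("T", fs, [(np.asarray(ecg), np.asarray(ppg))], label)


class TestRegistry:
    def test_exactly_205_features_with_table_counts(self):
        reg = build_registry()
        assert len(reg) == 205
        counts = {}
        for d in reg:
            counts[d.category] = counts.get(d.category, 0) + 1
        assert counts == {"PTT": 10, "TD": 56, "AM": 45, "AI": 19, "AR": 55, "RI": 20}
        for cat, (lo, hi) in CATEGORY_RANGES.items():
            assert [d.index for d in reg if d.category == cat] == list(range(lo, hi + 1))

    def test_published_anchor_indices(self):
        by_index = {d.index: d for d in build_registry()}
        assert by_index[47].params == ("ppg_peak", "sdppg_c")
        assert by_index[52].params == ("sdppg_c", "dppg_valley")
        assert by_index[11].kind == "rri"

    def test_td_pairs_cover_all_landmark_pairs_once(self):
        pairs = {d.params for d in build_registry() if d.kind == "td"}
        assert len(pairs) == 55
        import itertools

        assert pairs == set(itertools.combinations(LANDMARKS, 2))


class TestPreprocess:
    def test_baseline_drift_removed(self, small_cohort):
        rec = small_cohort[0]
        ecg, ppg = rec.segments[0]
        t = np.arange(len(ppg)) / FS
        drift = 5.0 * np.sin(2 * np.pi * 0.05 * t)
        drifted = WaveformRecord("D", FS, [(ecg, ppg + drift)], 0)
        clean = preprocess(rec)[0].ppg
        dirty = preprocess(drifted)[0].ppg
        # a 4th-order band-pass at 0.5 Hz attenuates 0.05 Hz by ~(0.1)^8
        # (squared by forward-backward filtering); residual drift < 1 %
        resid = dirty - clean
        assert np.ptp(resid[int(2 * FS) : -int(2 * FS)]) < 0.01 * np.ptp(drift)

    def test_inband_pulse_preserved(self):
        t = np.arange(0, 20, 1 / FS)
        carrier = np.sin(2 * np.pi * 1.3 * t) + 0.3 * np.sin(2 * np.pi * 4.1 * t)
        out = preprocess(synth_record(carrier, carrier))[0]
        core = slice(int(3 * FS), -int(3 * FS))
        nrmse = np.sqrt(np.mean((out.ppg[core] - carrier[core]) ** 2)) / np.std(carrier)
        assert nrmse < 0.05

    def test_all_zero_segment_dropped(self, caplog):
        rec = synth_record(np.zeros(int(10 * FS)), np.zeros(int(10 * FS)))
        assert preprocess(rec) == []

    def test_short_and_nonfinite_segments_dropped(self):
        good = np.sin(np.arange(int(5 * FS)) / 10)
        bad = good.copy()
        bad[10] = np.nan
        rec = WaveformRecord(
            "M", FS, [(good[:100], good[:100]), (bad, good), (good, good)], 0
        )
        segs = preprocess(rec)
        assert [s.segment_id for s in segs] == [2]


class TestRPeaks:
    def test_sixty_bpm_thirty_seconds(self):
        t = np.arange(0, 30, 1 / FS)
        ecg = np.zeros_like(t)
        sched = np.arange(0.5, 29.5, 1.0)
        for bt in sched:
            z = (t - bt) / 0.02
            ecg += (1 - z * z) * np.exp(-0.5 * z * z)
        r = detect_r_peaks(ecg, FS)
        assert abs(len(r) - 30) <= 1
        matched = np.abs(r[:, None] - sched[None, :]).min(axis=1)
        assert np.all(matched <= 1.01 / FS)

    def test_flat_ecg_gives_empty(self):
        assert detect_r_peaks(np.zeros(1000), FS).size == 0

    def test_120_bpm_median_rr(self):
        t = np.arange(0, 20, 1 / FS)
        ecg = np.zeros_like(t)
        for bt in np.arange(0.4, 19.5, 0.5):
            z = (t - bt) / 0.02
            ecg += (1 - z * z) * np.exp(-0.5 * z * z)
        r = detect_r_peaks(ecg, FS)
        assert np.median(np.diff(r)) == pytest.approx(0.5, abs=1.01 / FS)


def analytic_channels(params_list, n_samp, fs):
    """Sample the closed-form pulse train and its exact derivatives."""
    t = np.arange(n_samp) / fs
    ppg = sum(pulse_waveform(t, p) for p in params_list)
    dppg = sum(_pulse_d1(t, p) for p in params_list)
    sdppg = sum(_pulse_d2(t, p) for p in params_list)
    return ppg, dppg, sdppg


class TestFiducials:
    def test_landmarks_within_two_samples_of_analytic_truth(self):
        # pulses with exactly known derivatives; the dense-grid landmark
        # locations of the closed form are the oracle
        base = dict(mu1=0.13, s1=0.055, a1=1.0, mu2=0.42, s2=0.09, a2=0.35)
        onsets = [0.25 + 0.9 * k for k in range(8)]
        params = [dict(onset=o, **base) for o in onsets]
        n = int(8.5 * FS)
        ppg, dppg, sdppg = analytic_channels(params, n, FS)
        r_times = np.array(onsets) - 0.2  # R precedes the pulse foot
        fids = detect_fiducials(ppg, dppg, sdppg, r_times, FS)
        assert len(fids) == 7
        checked = 0
        for fid, p, nxt in zip(fids, params, onsets[1:]):
            assert fid.valid, fid.reason
            truth = pulse_landmark_times(p, next_onset=nxt)
            for lm, t_true in truth.items():
                if lm in ("ppg_valley", "sdppg_f"):
                    # boundary landmarks: on the isolated closed-form pulse the
                    # foot is a flat tail and the f-wave minimum is set by the
                    # *next* pulse's rising curvature, so neither is a
                    # well-localized extremum of the single-pulse oracle
                    continue
                assert abs(fid.landmark_times_s[lm] - t_true) <= 2.01 / FS, lm
                checked += 1
        assert checked == 7 * 8

    def test_landmark_times_strictly_increasing(self, one_segment):
        _, _, _, fids = one_segment
        assert any(f.valid for f in fids)
        for fid in fids:
            if not fid.valid:
                continue
            times = [fid.landmark_times_s[lm] for lm in LANDMARKS]
            assert all(b > a for a, b in zip(times, times[1:]))
            assert times[0] >= fid.r_peak_time_s

    def test_monotone_ramp_has_no_dicrotic_landmarks(self):
        n = int(4 * FS)
        ramp = np.linspace(0, 1, n)
        d1 = np.gradient(ramp, 1 / FS)
        d2 = np.gradient(d1, 1 / FS)
        fids = detect_fiducials(ramp, d1, d2, np.array([0.5, 1.5, 2.5]), FS)
        assert fids and all(not f.valid for f in fids)

    def test_out_of_bounds_rri_flagged(self):
        n = int(10 * FS)
        x = np.zeros(n)
        fids = detect_fiducials(x, x, x, np.array([0.5, 3.6]), FS)
        assert fids[0].reason == "rri_out_of_bounds"


class TestFeatureExtraction:
    def test_full_vector_on_synthetic_beat(self, one_segment):
        _, seg, _, fids = one_segment
        fid = next(f for f in fids if f.valid)
        vec = extract_beat_features(fid, seg.ppg, seg.dppg, seg.sdppg, seg.fs)
        assert vec.shape == (205,)
        reg = build_registry()
        # PTT and TD entries non-negative on a valid beat
        for d in reg:
            if d.category in ("PTT", "TD"):
                assert vec[d.index - 1] >= 0, d.name

    def test_ptt_zero_when_landmark_coincides_with_r_peak(self, one_segment):
        _, seg, _, fids = one_segment
        fid = next(f for f in fids if f.valid)
        shifted = FiducialSet(
            beat_index=fid.beat_index,
            r_peak_time_s=fid.landmark_times_s["ppg_valley"],
            rri_s=fid.rri_s,
            landmark_times_s=fid.landmark_times_s,
            landmark_values=fid.landmark_values,
        )
        vec = extract_beat_features(shifted, seg.ppg, seg.dppg, seg.sdppg, seg.fs)
        assert vec[0] == 0.0  # ptt_ppg_valley

    def test_triangular_pulse_area(self):
        # triangle of base 0.8 s and height 2: area = b*h/2 = 0.8
        fs = 1000.0
        n = int(1.2 * fs)
        t = np.arange(n) / fs
        ppg = np.interp(t, [0.1, 0.5, 0.9], [0.0, 2.0, 0.0], left=0.0, right=0.0)
        times = dict.fromkeys(LANDMARKS, 0.0)
        times.update({lm: 0.1 + 0.07 * i for i, lm in enumerate(LANDMARKS)})
        times["ppg_valley"], times["ppg_valley_next"] = 0.1, 0.9
        fid = FiducialSet(0, 0.0, 0.8, times, {})
        vec = extract_beat_features(fid, ppg, np.gradient(ppg, 1 / fs), np.zeros(n), fs)
        ar_full = next(
            d for d in build_registry() if d.params == ("ppg_valley", "ppg_valley_next")
            and d.kind == "ar"
        )
        assert vec[ar_full.index - 1] == pytest.approx(0.8, rel=1e-3)

    def test_time_shift_invariance(self, one_segment):
        _, seg, r_times, _ = one_segment
        shift = 25  # samples
        def pad(x):
            return np.concatenate([np.full(shift, x[0]), x])
        fids0 = detect_fiducials(seg.ppg, seg.dppg, seg.sdppg, r_times, seg.fs)
        fids1 = detect_fiducials(
            pad(seg.ppg), pad(seg.dppg), pad(seg.sdppg), r_times + shift / seg.fs, seg.fs
        )
        v0 = extract_beat_features(
            next(f for f in fids0 if f.valid), seg.ppg, seg.dppg, seg.sdppg, seg.fs
        )
        v1 = extract_beat_features(
            next(f for f in fids1 if f.valid),
            pad(seg.ppg), pad(seg.dppg), pad(seg.sdppg), seg.fs,
        )
        np.testing.assert_allclose(v0, v1, rtol=0, atol=1e-9)

    def test_amplitude_scaling_behaviour(self, one_segment):
        _, seg, _, fids = one_segment
        fid = next(f for f in fids if f.valid)
        k = 3.7
        v1 = extract_beat_features(fid, seg.ppg, seg.dppg, seg.sdppg, seg.fs)
        vk = extract_beat_features(
            fid, k * seg.ppg, k * seg.dppg, k * seg.sdppg, seg.fs
        )
        for d in build_registry():
            i = d.index - 1
            if d.category in ("AM", "AI", "AR"):
                assert vk[i] == pytest.approx(k * v1[i], rel=1e-9), d.name
            elif d.category in ("PTT", "TD", "RI"):
                assert vk[i] == pytest.approx(v1[i], rel=1e-9, abs=1e-12), d.name

    def test_invalid_beat_rejected(self):
        bad = FiducialSet(0, 0.0, 1.0, {}, {}, valid=False, reason="x")
        with pytest.raises(ValueError, match="invalid"):
            extract_beat_features(bad, np.zeros(10), np.zeros(10), np.zeros(10), FS)

    def test_record_level_table_shape(self, small_cohort):
        df = extract_record_features(small_cohort[1])
        assert list(df.columns[:3]) == ["subject_id", "segment_id", "beat_index"]
        assert df.shape[1] == 208
        assert len(df) > 10
        assert df[feature_column(11)].between(0.3, 2.0).all()  # RRI bounds
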
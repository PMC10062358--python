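"""PPG measurement chain: preprocessing contract, quality gating, beat
detection against simulator truth, and the gated minute-HR rule."""

import numpy as np
import pytest

from afpulse.config import ProcessingConfig, SimConfig
from afpulse.ppg import (
    BeatDetection,
    QualityAnnotation,
    annotate_quality,
    compute_minute_hr,
    compute_rmssd,
    detect_beats,
    preprocess_ppg,
    process_record,
)
from afpulse.synth import render_ppg, simulate_af_rr, simulate_patient
from tests.conftest import quiet_profile


class TestPreprocess:
    def test_sinusoid_normalized_derivative(self):
        t = np.arange(0, 60, 1 / 25.0)
        pre = preprocess_ppg(np.sin(2 * np.pi * 1.0 * t), 25.0)
        assert pre.rate == 30.0
        assert not pre.degenerate
        assert abs(pre.samples.mean()) < 1e-9
        assert abs(pre.samples.std() - 1.0) < 1e-9
        # derivative of a sine is (up to filter attenuation) a cosine:
        # dominant frequency preserved at 1 Hz
        spec = np.abs(np.fft.rfft(pre.samples))
        freqs = np.fft.rfftfreq(len(pre.samples), 1 / 30.0)
        assert abs(freqs[np.argmax(spec)] - 1.0) < 0.05

    def test_constant_input_degenerate(self):
        pre = preprocess_ppg(np.full(1500, 3.7), 25.0)
        assert pre.degenerate
        assert np.all(pre.samples == 0.0)

    def test_white_noise_unit_variance(self):
        x = np.random.default_rng(0).normal(size=1500)
        pre = preprocess_ppg(x, 25.0)
        assert abs(pre.samples.std() - 1.0) < 1e-9

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="2 s"):
            preprocess_ppg(np.zeros(30), 25.0)


class TestQuality:
    def test_clean_minute_fully_sufficient(self, clean_af_signal, proc_config):
        _, ppg, _ = clean_af_signal
        pre = preprocess_ppg(ppg[5 * 1500 : 6 * 1500, 0], 25.0)
        ann = annotate_quality(pre, config=proc_config)
        assert ann.sufficient_fraction() == 1.0

    def test_noise_minute_fully_insufficient(self, proc_config):
        noise = np.random.default_rng(1).normal(0, 0.35, 1500)
        pre = preprocess_ppg(noise, 25.0)
        ann = annotate_quality(pre, config=proc_config)
        assert ann.sufficient_fraction() == 0.0

    def test_half_minute_artefact(self, clean_af_signal, proc_config):
        """A strong artefact over half the minute should leave roughly
        half the minute sufficient (within 10 percentage points)."""
        _, ppg, _ = clean_af_signal
        x = ppg[10 * 1500 : 11 * 1500, 0].astype(float).copy()
        x[:750] += np.random.default_rng(2).normal(0, 1.0, 750)
        pre = preprocess_ppg(x, 25.0)
        ann = annotate_quality(pre, config=proc_config)
        assert abs(ann.sufficient_fraction() - 0.5) <= 0.101

    def test_spans_tile_segment(self, clean_af_signal, proc_config):
        _, ppg, _ = clean_af_signal
        x = ppg[3 * 1500 : 4 * 1500, 0].astype(float).copy()
        x[600:900] += np.random.default_rng(3).normal(0, 1.2, 300)
        pre = preprocess_ppg(x, 25.0, t0=180.0)
        ann = annotate_quality(pre, config=proc_config)
        starts = [s for s, _, _ in ann.spans]
        ends = [e for _, e, _ in ann.spans]
        assert starts[0] == pytest.approx(180.0)
        assert ends[-1] == pytest.approx(180.0 + pre.duration)
        assert all(e0 == pytest.approx(s1) for e0, s1 in zip(ends[:-1], starts[1:]))


class TestBeatDetection:
    def test_clean_60bpm_count(self, proc_config):
        cfg = SimConfig(n_patients=1, duration_h=0.2, seed=0)
        prof = quiet_profile(rr_mean=1.0, rr_sd=0.0, duration_h=0.2)
        rt = simulate_af_rr(prof, 0.2, seed=1)
        ppg = render_ppg(rt, prof, cfg, seed=3)
        pre = preprocess_ppg(ppg[5 * 1500 : 6 * 1500, 0], 25.0, t0=300.0)
        ann = annotate_quality(pre, config=proc_config)
        beats = detect_beats(pre, ann, proc_config)
        assert abs(len(beats.beat_times) - 60) <= 1

    def test_fully_insufficient_yields_no_beats(self, clean_af_signal, proc_config):
        _, ppg, _ = clean_af_signal
        pre = preprocess_ppg(ppg[5 * 1500 : 6 * 1500, 0], 25.0)
        ann = QualityAnnotation(spans=[(0.0, 60.0, False)])
        beats = detect_beats(pre, ann, proc_config)
        assert len(beats.beat_times) == 0

    def test_af_beats_match_truth(self, clean_af_signal, proc_config):
        """>= 95% of detected beats within 150 ms of a true beat, after
        removing the fixed pulse-transit delay."""
        rhythm, ppg, _ = clean_af_signal
        hits = total = 0
        for m in range(3, 13):
            pre = preprocess_ppg(ppg[m * 1500 : (m + 1) * 1500, 0], 25.0, t0=m * 60.0)
            ann = annotate_quality(pre, config=proc_config)
            det = detect_beats(pre, ann, proc_config).beat_times - 0.25
            true = rhythm.beat_times[
                (rhythm.beat_times >= m * 60.0) & (rhythm.beat_times < (m + 1) * 60.0)
            ]
            for b in det:
                total += 1
                hits += int(np.min(np.abs(true - b)) < 0.15)
        assert total > 0 and hits / total >= 0.95

    def test_strictly_increasing_invariant(self):
        with pytest.raises(ValueError):
            BeatDetection(np.array([1.0, 0.9]))


class TestMinuteHr:
    def _ann(self, spans=None):
        return QualityAnnotation(spans=spans or [(0.0, 60.0, True)])

    def test_metronome_identity(self, proc_config):
        beats = BeatDetection(np.arange(0.0, 61.0, 1.0))  # 61 beats at 1.0 s
        est = compute_minute_hr(beats, self._ann(), 0, proc_config)
        assert est.hr == pytest.approx(60.0)

    def test_gate_at_20_intervals(self, proc_config):
        # 20 beats = 19 intervals -> insufficient under the >= 20-interval rule
        beats = BeatDetection(np.arange(0.0, 20.0, 1.0))
        assert compute_minute_hr(beats, self._ann(), 0, proc_config).insufficient
        # 21 beats at 0.8 s = 20 intervals -> HR 75
        beats = BeatDetection(np.arange(0.0, 21 * 0.8, 0.8)[:21])
        est = compute_minute_hr(beats, self._ann(), 0, proc_config)
        assert est.hr == pytest.approx(75.0)
        assert est.n_beats_used == 21

    def test_intervals_never_cross_insufficient_spans(self, proc_config):
        """Gating soundness: an interval across an insufficient gap is
        discarded even when both endpoint beats are detected."""
        spans = [(0.0, 25.0, True), (25.0, 35.0, False), (35.0, 60.0, True)]
        cfg = ProcessingConfig(min_intervals=10)
        # 0.5 s spacing inside the good spans; a big gap across the bad span
        bt = np.concatenate([np.arange(19.0, 25.0, 0.5), np.arange(35.0, 41.0, 0.5)])
        est = compute_minute_hr(BeatDetection(bt), self._ann(spans), 0, cfg)
        # 22 within-span intervals of 0.5 s; the 10 s crossing interval is
        # excluded, so HR reflects 0.5 s spacing exactly
        assert est.hr == pytest.approx(120.0)

    def test_device_floor_enforced(self):
        cfg = ProcessingConfig(min_intervals=5)
        bt = np.arange(0.0, 60.0, 3.5)  # ~17 bpm, below the 20 bpm floor
        est = compute_minute_hr(BeatDetection(bt), self._ann(), 0, cfg)
        assert est.insufficient

    def test_determinism(self, clean_af_signal, proc_config):
        _, ppg, _ = clean_af_signal
        pre = preprocess_ppg(ppg[4 * 1500 : 5 * 1500, 0], 25.0, t0=240.0)
        ann = annotate_quality(pre, config=proc_config)
        beats = detect_beats(pre, ann, proc_config)
        a = compute_minute_hr(beats, ann, 4, proc_config)
        b = compute_minute_hr(beats, ann, 4, proc_config)
        assert a == b


class TestRmssd:
    @pytest.mark.parametrize(
        "intervals, expected",
        [
            ([1.0, 1.0, 1.0], 0.0),
            ([0.8, 1.0, 0.8], 0.2),
            ([0.8, 0.8, 1.0], np.sqrt(0.04 / 2)),  # order sensitivity
        ],
    )
    def test_hand_computed(self, intervals, expected):
        assert compute_rmssd(intervals) == pytest.approx(expected)

    def test_too_few_intervals(self):
        with pytest.raises(ValueError):
            compute_rmssd([0.8])


class TestPipelineFidelity:
    def test_clean_minutes_within_2bpm(self):
        """Artefact-free AF minutes across the rate-control range: the
        pipeline HR stays within 2 bpm of simulator truth."""
        for rr_mean, seed in ((1.4, 11), (0.8, 12), (0.57, 13)):  # ~43/75/105 bpm
            cfg = SimConfig(n_patients=1, duration_h=0.4, dropout_fraction=0.0, seed=0)
            prof = quiet_profile(rr_mean=rr_mean, duration_h=0.4)
            rt = simulate_af_rr(prof, 0.4, seed=seed)
            ppg = render_ppg(rt, prof, cfg, seed=seed + 50)
            pc = ProcessingConfig()
            for m in range(24):
                true = rt.beat_times[
                    (rt.beat_times >= m * 60.0) & (rt.beat_times < (m + 1) * 60.0)
                ]
                true_hr = 60.0 / np.mean(np.diff(true))
                pre = preprocess_ppg(ppg[m * 1500 : (m + 1) * 1500, 0], 25.0, t0=m * 60.0)
                ann = annotate_quality(pre, config=pc)
                est = compute_minute_hr(detect_beats(pre, ann, pc), ann, m, pc)
                assert est.hr is not None, f"minute {m} at rr={rr_mean} insufficient"
                assert abs(est.hr - true_hr) <= 2.0

    def test_pulse_deficit_underestimates_fast_rates(self):
        """Strong deficit (slow refilling, tau 0.9 s) at >110 bpm: the
        pipeline underestimates on average."""
        cfg = SimConfig(
            n_patients=1, duration_h=0.4, dropout_fraction=0.0,
            pulse_deficit_tau=0.9, seed=0,
        )
        prof = quiet_profile(rr_mean=0.45, rr_sd=0.12, duration_h=0.4)
        rt = simulate_af_rr(prof, 0.4, seed=21)
        ppg = render_ppg(rt, prof, cfg, seed=22)
        pc = ProcessingConfig()
        errs = []
        for m in range(24):
            true = rt.beat_times[
                (rt.beat_times >= m * 60.0) & (rt.beat_times < (m + 1) * 60.0)
            ]
            true_hr = 60.0 / np.mean(np.diff(true))
            pre = preprocess_ppg(ppg[m * 1500 : (m + 1) * 1500, 0], 25.0, t0=m * 60.0)
            ann = annotate_quality(pre, config=pc)
            est = compute_minute_hr(detect_beats(pre, ann, pc), ann, m, pc)
            if est.hr is not None:
                errs.append(est.hr - true_hr)
        assert len(errs) >= 10
        assert np.mean(errs) < 0


class TestProcessRecord:
    def test_dropout_minutes_marked_insufficient(self):
        cfg = SimConfig(n_patients=1, duration_h=1.0, dropout_fraction=0.4, seed=33)
        rec = simulate_patient(cfg, 0)
        est = process_record(rec)
        merged = est.merge(rec.truth_minutes, on="minute_index")
        bad = merged[~merged["ppg_ok"]]
        assert len(bad) > 5
        assert bad["hr_ppg"].isna().all()
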
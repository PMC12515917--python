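"""Rule-engine contracts: baseline, variability, events, three-tier classes."""

import numpy as np
import pytest

from ctgkit.records import BinaryLabel, CTGClass, CTGRecord, EventKind, SimParams
from ctgkit.rules import (
    VariabilityLevel,
    classify_ctg,
    classify_variability,
    contraction_stats,
    detect_accelerations,
    detect_decelerations,
    detect_sinusoidal,
    estimate_baseline,
    to_binary,
)
from ctgkit.synth import inject_deceleration, inject_sinusoidal, simulate_record
from tests.conftest import constant_record

FS = 4.0


class TestBaseline:
    def test_constant_140_no_flags(self):
        rec = constant_record(140.0, duration_s=720)
        est = estimate_baseline(rec.fhr, rec.fhr_valid, FS)
        assert est.value == pytest.approx(140.0)
        assert not est.tachycardia and not est.bradycardia
        assert all(e - s >= 120 for s, e in est.stable_segments)

    def test_sustained_165_is_tachycardia(self):
        rec = constant_record(165.0, duration_s=720)
        assert estimate_baseline(rec.fhr, rec.fhr_valid, FS).tachycardia

    def test_sustained_105_is_bradycardia(self):
        rec = constant_record(105.0, duration_s=720)
        assert estimate_baseline(rec.fhr, rec.fhr_valid, FS).bradycardia

    def test_short_signal_indeterminate(self):
        rec = constant_record(140.0, duration_s=300)
        assert estimate_baseline(rec.fhr, rec.fhr_valid, FS).indeterminate

    def test_recovery_across_baselines_under_variability(self):
        for b in (110, 125, 142, 160):
            rec = simulate_record(SimParams(baseline_bpm=b, variability_amp=20,
                                            duration_s=1200, seed=b))
            est = estimate_baseline(rec.fhr, rec.fhr_valid, FS)
            assert abs(est.value - b) <= 2.0

    def test_excursions_excluded_from_estimate(self):
        base = simulate_record(SimParams(baseline_bpm=140, variability_amp=5,
                                         duration_s=1800, seed=3))
        rec = inject_deceleration(base, EventKind.EARLY_DECEL, 2, depth=40, duration_s=90)
        est = estimate_baseline(rec.fhr, rec.fhr_valid, FS)
        assert abs(est.value - 140) <= 2.0


class TestVariability:
    def test_small_sinusoid_is_minimal(self):
        t = np.arange(int(900 * FS)) / FS
        fhr = 140 + 2.0 * np.sin(2 * np.pi * t / 20)  # 4 bpm peak-to-trough
        v = classify_variability(fhr, np.ones_like(fhr, bool), FS)
        assert v.level == VariabilityLevel.MINIMAL
        assert v.amplitude_bpm == pytest.approx(4.0, abs=0.3)

    def test_amplitude_10_is_moderate(self):
        rec = simulate_record(SimParams(variability_amp=10, duration_s=1200, seed=5,
                                        contraction_rate=0))
        v = classify_variability(rec.fhr, rec.fhr_valid, FS)
        assert v.level == VariabilityLevel.MODERATE

    def test_flat_trace_is_absent(self):
        rec = constant_record(140.0, duration_s=600)
        assert classify_variability(rec.fhr, rec.fhr_valid, FS).level == VariabilityLevel.ABSENT

    def test_event_windows_excluded(self):
        rec = constant_record(140.0, duration_s=600)
        v = classify_variability(rec.fhr, rec.fhr_valid, FS, exclude=[(0, 600)])
        assert v.indeterminate


class TestAccelerations:
    def _with_bump(self, height, duration, duration_total=900.0):
        rec = constant_record(140.0, duration_s=duration_total)
        t = rec.time_s
        onset, peak = 400.0, 400.0 + min(duration / 2, 20)
        end = 400.0 + duration
        from ctgkit.synth import _half_cosine_bump

        rec.fhr = rec.fhr + height * _half_cosine_bump(t, onset, peak, end)
        return rec

    def test_15bpm_20s_detected_at_34_weeks(self):
        rec = self._with_bump(15, 20)
        out = detect_accelerations(rec.fhr, rec.fhr_valid, 140.0, 34, FS)
        assert len(out) == 1 and out[0].kind == EventKind.ACCELERATION

    def test_12bpm_20s_not_detected_at_34_weeks(self):
        rec = self._with_bump(12, 20)
        assert not detect_accelerations(rec.fhr, rec.fhr_valid, 140.0, 34, FS)

    def test_12bpm_20s_detected_at_30_weeks(self):
        rec = self._with_bump(12, 20)
        out = detect_accelerations(rec.fhr, rec.fhr_valid, 140.0, 30, FS)
        assert len(out) == 1

    def test_three_minute_excursion_is_prolonged(self):
        rec = self._with_bump(20, 180)
        out = detect_accelerations(rec.fhr, rec.fhr_valid, 140.0, 34, FS)
        assert len(out) == 1 and out[0].kind == EventKind.PROLONGED_ACCELERATION


class TestDecelerations:
    @pytest.fixture()
    def base(self):
        return simulate_record(SimParams(duration_s=1800, seed=8, variability_amp=6))

    def _detect(self, rec):
        return detect_decelerations(rec.fhr, rec.uc, rec.fhr_valid, rec.uc_valid, 142.0, FS)

    def test_aligned_gradual_dip_typed_early(self, base):
        rec = inject_deceleration(base, EventKind.EARLY_DECEL, 2, depth=25, duration_s=85)
        rep = self._detect(rec)
        assert [e.kind for e in rep.events] == [EventKind.EARLY_DECEL]

    def test_lagged_gradual_dip_typed_late(self, base):
        rec = inject_deceleration(base, EventKind.LATE_DECEL, 3, depth=25,
                                  duration_s=85, lag_s=25)
        rep = self._detect(rec)
        assert [e.kind for e in rep.events] == [EventKind.LATE_DECEL]

    def test_abrupt_deep_dip_typed_variable(self, base):
        rec = inject_deceleration(base, EventKind.VARIABLE_DECEL, 1, depth=25,
                                  duration_s=45, onset_to_nadir_s=8)
        rep = self._detect(rec)
        assert [e.kind for e in rep.events] == [EventKind.VARIABLE_DECEL]

    def test_missing_uc_makes_gradual_dips_indeterminate(self, base):
        rec = inject_deceleration(base, EventKind.EARLY_DECEL, 2, depth=25, duration_s=85)
        rec.uc_valid[:] = False
        rep = self._detect(rec)
        assert not rep.events
        assert len(rep.indeterminate) == 1
        assert any("no usable UC" in w for w in rep.warnings)

    def test_abrupt_dips_still_typed_without_uc(self, base):
        rec = inject_deceleration(base, EventKind.VARIABLE_DECEL, 1, depth=25,
                                  duration_s=45, onset_to_nadir_s=8)
        rec.uc_valid[:] = False
        rep = self._detect(rec)
        assert [e.kind for e in rep.events] == [EventKind.VARIABLE_DECEL]


class TestSinusoidal:
    def test_injected_pattern_detected(self):
        base = simulate_record(SimParams(duration_s=1800, seed=5))
        rec = inject_sinusoidal(base, cycles_per_min=4, duration_s=1500, start_s=60)
        found, window = detect_sinusoidal(rec.fhr, rec.fhr_valid, FS)
        assert found
        s, e = window
        assert e - s >= 1200

    def test_moderate_noise_not_sinusoidal(self):
        for seed in range(5):
            rec = simulate_record(SimParams(duration_s=1800, seed=seed, variability_amp=12))
            assert not detect_sinusoidal(rec.fhr, rec.fhr_valid, FS)[0]

    def test_nineteen_minute_pattern_too_short(self):
        base = simulate_record(SimParams(duration_s=1800, seed=5, variability_amp=12))
        t = base.time_s
        i0, i1 = base.sample_index(300), base.sample_index(300 + 1140)
        base.fhr[i0:i1] = 140 + 8 * np.sin(2 * np.pi * 4 / 60 * t[i0:i1])
        assert not detect_sinusoidal(base.fhr, base.fhr_valid, FS)[0]


class TestContractions:
    def _uc(self, n_contractions, duration_s=1800.0):
        t = np.arange(int(duration_s * FS)) / FS
        uc = np.full_like(t, 8.0)
        from ctgkit.synth import _half_cosine_bump

        for k in range(n_contractions):
            c = (k + 0.5) * duration_s / n_contractions
            uc += 50 * _half_cosine_bump(t, c - 35, c, c + 35)
        return uc

    def test_18_in_30min_is_tachysystole(self):
        uc = self._uc(18)
        st = contraction_stats(uc, np.ones_like(uc, bool), FS)
        assert st.rate_per_10min == pytest.approx(6.0, abs=0.1)
        assert st.tachysystole

    def test_12_in_30min_is_normal(self):
        uc = self._uc(12)
        st = contraction_stats(uc, np.ones_like(uc, bool), FS)
        assert st.rate_per_10min == pytest.approx(4.0, abs=0.1)
        assert not st.tachysystole

    def test_flat_uc_rate_zero(self):
        uc = np.full(int(1800 * FS), 8.0)
        st = contraction_stats(uc, np.ones_like(uc, bool), FS)
        assert st.rate_per_10min == 0.0 and not st.tachysystole

    def test_all_gap_indeterminate(self):
        uc = self._uc(12)
        assert contraction_stats(uc, np.zeros_like(uc, bool), FS).indeterminate

    def test_short_window_low_confidence(self):
        uc = self._uc(4, duration_s=600)
        assert contraction_stats(uc, np.ones_like(uc, bool), FS).low_confidence


class TestClassifyCTG:
    def test_normal_strip_is_class_i_with_reasons(self):
        rec = simulate_record(SimParams(duration_s=1800, seed=17, event_requests=[
            ("acceleration", {"at_s": 700, "height": 20, "duration_s": 30})],
            skip_conflicts=True))
        cls = classify_ctg(rec)
        assert cls.ctg_class == CTGClass.I
        assert cls.reasons

    def test_absent_variability_recurrent_late_decels_class_iii(self):
        p = SimParams(duration_s=1800, seed=23, variability_amp=0.5,
                      contraction_rate=4.0, skip_conflicts=True)
        p.event_requests = [("late_decel", {"contraction_index": i, "depth": 28,
                                            "duration_s": 85, "lag_s": 35})
                            for i in range(1, 11)]
        cls = classify_ctg(simulate_record(p))
        assert cls.ctg_class == CTGClass.III
        assert "recurrent-late-decelerations" in cls.reasons

    def test_minimal_variability_no_decels_class_ii(self):
        rec = simulate_record(SimParams(duration_s=1800, seed=29, variability_amp=3.5))
        cls = classify_ctg(rec)
        assert cls.ctg_class == CTGClass.II
        assert any("variability" in r for r in cls.reasons)

    def test_sinusoidal_pattern_class_iii(self):
        base = simulate_record(SimParams(duration_s=1800, seed=31, variability_amp=0.0))
        rec = inject_sinusoidal(base, cycles_per_min=4, duration_s=1400, start_s=100)
        cls = classify_ctg(rec)
        assert cls.ctg_class == CTGClass.III
        assert "sinusoidal-pattern" in cls.reasons

    def test_removing_uc_demotes_class_i_with_early_decels(self):
        p = SimParams(duration_s=1800, seed=37, skip_conflicts=True)
        p.event_requests = [("early_decel", {"contraction_index": i, "depth": 25,
                                             "duration_s": 85}) for i in (2, 5, 8)]
        rec = simulate_record(p)
        assert classify_ctg(rec).ctg_class == CTGClass.I
        rec_nouc = rec.copy()
        rec_nouc.uc_valid[:] = False
        cls = classify_ctg(rec_nouc)
        assert cls.ctg_class == CTGClass.II  # the unimodal misclassification mechanism
        assert any("indeterminate" in r for r in cls.reasons)

    def test_invariant_under_leading_gap_padding(self):
        rec = simulate_record(SimParams(duration_s=1800, seed=41))
        before = classify_ctg(rec).ctg_class
        pad = int(120 * FS)
        padded = CTGRecord(
            fhr=np.r_[np.full(pad, 140.0), rec.fhr],
            uc=np.r_[np.zeros(pad), rec.uc],
            fhr_valid=np.r_[np.zeros(pad, bool), rec.fhr_valid],
            uc_valid=np.r_[np.zeros(pad, bool), rec.uc_valid],
            fs=rec.fs,
        )
        assert classify_ctg(padded).ctg_class == before

    def test_exactly_one_class_everywhere(self):
        from ctgkit.synth import make_dataset

        for _img, rec in make_dataset(15, (0.4, 0.3, 0.3), seed=51, render=False):
            cls = classify_ctg(rec)
            assert cls.ctg_class in (CTGClass.I, CTGClass.II, CTGClass.III)
            if cls.ctg_class in (CTGClass.I, CTGClass.III):
                assert cls.reasons


class TestBinaryPolicy:
    @pytest.mark.parametrize("cls,policy,expected", [
        (CTGClass.I, "strict", BinaryLabel.NORMAL),
        (CTGClass.II, "strict", BinaryLabel.ABNORMAL),
        (CTGClass.III, "strict", BinaryLabel.ABNORMAL),
        (CTGClass.II, "ii_normal", BinaryLabel.NORMAL),
        (CTGClass.III, "ii_normal", BinaryLabel.ABNORMAL),
    ])
    def test_policies(self, cls, policy, expected):
        assert to_binary(cls, policy) == expected

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError):
            to_binary(CTGClass.I, "bogus")
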
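"""Generator contracts: baselines, variability scaling, event injection, rendering."""

import numpy as np
import pytest

from ctgkit.layout import ChartLayout
from ctgkit.records import (
    BinaryLabel,
    CTGClass,
    CTGRecord,
    EventAnnotation,
    EventKind,
    SimParams,
)
from ctgkit.synth import (
    inject_deceleration,
    inject_sinusoidal,
    make_dataset,
    render_chart,
    simulate_record,
)


class TestSimulateRecord:
    def test_default_baseline_and_variability_recovered(self):
        rec = simulate_record(SimParams(baseline_bpm=142, variability_amp=10,
                                        contraction_rate=0, duration_s=1200, seed=7))
        assert abs(rec.fhr.mean() - 142) < 1.5
        win = int(60 * rec.fs)
        ptps = [np.ptp(rec.fhr[i * win:(i + 1) * win]) for i in range(rec.n_samples // win)]
        assert abs(np.median(ptps) - 10) < 1.5

    def test_zero_variability_gives_constant_trace(self, flat_record):
        assert np.allclose(flat_record.fhr, flat_record.fhr[0])
        assert flat_record.fhr[0] == pytest.approx(142.0)

    def test_same_seed_bit_identical(self):
        p = SimParams(duration_s=900, seed=11)
        a, b = simulate_record(p), simulate_record(p)
        assert np.array_equal(a.fhr, b.fhr) and np.array_equal(a.uc, b.uc)
        assert [e.to_dict() for e in a.events] == [e.to_dict() for e in b.events]

    def test_contractions_are_unimodal_bumps_with_annotations(self, quiet_record):
        contr = quiet_record.events_of_kind(EventKind.CONTRACTION)
        assert len(contr) == round(4.0 * 1800 / 600)
        for e in contr:
            i = quiet_record.sample_index(e.nadir_or_peak_s)
            assert quiet_record.uc[i] == pytest.approx(8.0 + e.magnitude, abs=1.0)

    def test_gap_spec_invalidates_samples(self):
        rec = simulate_record(SimParams(duration_s=900, seed=0,
                                        gap_spec={"fhr": [(100, 130)]}))
        assert not rec.fhr_valid[rec.sample_index(110)]
        assert rec.fhr_valid[rec.sample_index(95)]
        assert rec.uc_valid.all()

    def test_overlapping_event_requests_rejected(self):
        p = SimParams(duration_s=1800, seed=1, event_requests=[
            ("acceleration", {"at_s": 300, "height": 20, "duration_s": 40}),
            ("acceleration", {"at_s": 320, "height": 20, "duration_s": 40}),
        ])
        with pytest.raises(ValueError, match="overlaps"):
            simulate_record(p)


class TestInjectDeceleration:
    @pytest.fixture()
    def base(self):
        return simulate_record(SimParams(duration_s=1800, seed=5, variability_amp=6))

    def test_early_nadir_coincides_with_contraction_peak(self, base):
        rec = inject_deceleration(base, EventKind.EARLY_DECEL, 2, depth=25, duration_s=80)
        peak = base.events_of_kind(EventKind.CONTRACTION)[2].nadir_or_peak_s
        ann = rec.events_of_kind(EventKind.EARLY_DECEL)[0]
        assert ann.nadir_or_peak_s == peak
        assert ann.nadir_or_peak_s - ann.onset_s >= 30

    def test_late_lag_echoed_in_annotation(self, base):
        rec = inject_deceleration(base, EventKind.LATE_DECEL, 3, depth=25,
                                  duration_s=80, lag_s=30)
        peak = base.events_of_kind(EventKind.CONTRACTION)[3].nadir_or_peak_s
        ann = rec.events_of_kind(EventKind.LATE_DECEL)[0]
        assert ann.nadir_or_peak_s - peak == pytest.approx(30.0)

    def test_variable_kind_and_constraints(self, base):
        rec = inject_deceleration(base, EventKind.VARIABLE_DECEL, 1, depth=20,
                                  duration_s=50, onset_to_nadir_s=10)
        ann = rec.events_of_kind(EventKind.VARIABLE_DECEL)[0]
        assert ann.nadir_or_peak_s - ann.onset_s == pytest.approx(10.0)
        assert 15 <= ann.duration_s < 120

    def test_variable_depth_below_15_rejected(self, base):
        with pytest.raises(ValueError, match="15"):
            inject_deceleration(base, EventKind.VARIABLE_DECEL, 1, depth=12, duration_s=50)

    def test_signal_actually_dips_by_depth(self, base):
        rec = inject_deceleration(base, EventKind.EARLY_DECEL, 2, depth=30, duration_s=80)
        ann = rec.events_of_kind(EventKind.EARLY_DECEL)[0]
        i = rec.sample_index(ann.nadir_or_peak_s)
        assert base.fhr[i] - rec.fhr[i] == pytest.approx(30, abs=0.5)

    def test_missing_contraction_rejected(self, base):
        with pytest.raises(ValueError, match="contraction_index"):
            inject_deceleration(base, EventKind.EARLY_DECEL, 99, depth=25)


class TestInjectSinusoidal:
    @pytest.fixture()
    def base(self):
        return simulate_record(SimParams(duration_s=1800, seed=9))

    def test_dominant_frequency_matches_request(self, base):
        rec = inject_sinusoidal(base, cycles_per_min=4, duration_s=1500, start_s=60)
        i0, i1 = rec.sample_index(60), rec.sample_index(1560)
        x = rec.fhr[i0:i1] - rec.fhr[i0:i1].mean()
        freqs = np.fft.rfftfreq(len(x), d=1 / rec.fs)
        dom = freqs[1:][np.argmax(np.abs(np.fft.rfft(x))[1:])]
        assert dom == pytest.approx(4 / 60, rel=0.05)

    @pytest.mark.parametrize("cpm,dur", [(2, 1500), (6, 1500), (4, 600)])
    def test_out_of_definition_requests_rejected(self, base, cpm, dur):
        with pytest.raises(ValueError):
            inject_sinusoidal(base, cycles_per_min=cpm, duration_s=dur)

    def test_overlapping_accelerations_suppressed(self):
        base = simulate_record(SimParams(duration_s=1800, seed=9, event_requests=[
            ("acceleration", {"at_s": 400, "height": 20, "duration_s": 40})]))
        rec = inject_sinusoidal(base, cycles_per_min=4, duration_s=1300, start_s=100)
        assert not rec.events_of_kind(EventKind.ACCELERATION)


class TestRenderChart:
    def test_constant_max_fhr_hits_band_top(self, paper_layout):
        from tests.conftest import constant_record

        dur = paper_layout.width_px * paper_layout.seconds_per_column
        rec = constant_record(210.0, duration_s=dur)
        img = render_chart(rec, paper_layout)
        top = paper_layout.fhr_band[0]
        cols = np.where(img.pixels[top] == paper_layout.trace_intensity)[0]
        assert len(cols) == paper_layout.width_px

    def test_zero_uc_hits_band_bottom(self, paper_layout):
        from tests.conftest import constant_record

        dur = paper_layout.width_px * paper_layout.seconds_per_column
        rec = constant_record(140.0, duration_s=dur, uc_mmhg=0.0)
        img = render_chart(rec, paper_layout)
        bottom = paper_layout.uc_band[1]
        assert (img.pixels[bottom] == paper_layout.trace_intensity).all()

    def test_gap_columns_contain_grid_only(self, paper_layout):
        dur = paper_layout.width_px * paper_layout.seconds_per_column
        rec = simulate_record(SimParams(duration_s=dur, seed=2,
                                        gap_spec={"fhr": [(100, 130)]}))
        img = render_chart(rec, paper_layout)
        a, b = paper_layout.fhr_band
        gap_cols = paper_layout.column_of_time(np.arange(101, 129))
        band = img.pixels[a:b + 1][:, gap_cols]
        assert not (band == paper_layout.trace_intensity).any()
        assert img.report["blank_fhr_columns"] == (~rec.fhr_valid).sum()

    def test_out_of_range_values_clipped_and_reported(self, paper_layout):
        from ctgkit.records import CTGRecord

        n = paper_layout.width_px
        rec = CTGRecord(fhr=np.full(n, 140.0), uc=np.full(n, 95.0),
                        fhr_valid=np.ones(n, bool), uc_valid=np.ones(n, bool), fs=4.0)
        rec.uc = np.full(n, 120.0)  # out-of-range values appear post-validation
        img = render_chart(rec, paper_layout)
        assert img.report["clipped_uc"] == n
        assert (img.pixels[paper_layout.uc_band[0]] == paper_layout.trace_intensity).all()


class TestMakeDataset:
    def test_cohort_scale_counts(self):
        data = make_dataset(326, (224 / 326, 51 / 326, 51 / 326), seed=0, render=False)
        labels = [rec.binary_label for _i, rec in data]
        assert labels.count(BinaryLabel.NORMAL) == 224
        assert labels.count(BinaryLabel.ABNORMAL) == 102

    def test_degenerate_mix_all_class_i(self):
        data = make_dataset(10, (1.0, 0.0, 0.0), seed=1, render=False)
        assert all(rec.figo_class == CTGClass.I for _i, rec in data)

    def test_same_seed_same_label_sequence(self):
        a = make_dataset(30, (0.5, 0.3, 0.2), seed=4, render=False)
        b = make_dataset(30, (0.5, 0.3, 0.2), seed=4, render=False)
        assert [r.figo_class for _, r in a] == [r.figo_class for _, r in b]
        assert all(np.array_equal(ra.fhr, rb.fhr) for (_, ra), (_, rb) in zip(a, b))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            make_dataset(0, (1, 0, 0), seed=0)
        with pytest.raises(ValueError):
            make_dataset(10, (0.5, 0.2, 0.2), seed=0)

    def test_rendered_images_match_layout(self):
        layout = ChartLayout.compact(duration_s=1800, width_px=64, height_px=48)
        data = make_dataset(4, (0.5, 0.25, 0.25), seed=2, layout=layout)
        for img, _rec in data:
            assert img.pixels.shape == (48, 64)


class TestEventAnnotation:
    def test_ordering_invariant_enforced(self):
        with pytest.raises(ValueError):
            EventAnnotation(EventKind.ACCELERATION, 10.0, 5.0, 20.0, 15.0)

    def test_positive_magnitude_enforced(self):
        with pytest.raises(ValueError):
            EventAnnotation(EventKind.CONTRACTION, 0.0, 5.0, 10.0, 0.0)

    def test_record_invariants_enforced(self):
        with pytest.raises(ValueError, match="equal length"):
            CTGRecord(fhr=np.full(10, 140.0), uc=np.full(9, 10.0),
                      fhr_valid=np.ones(10, bool), uc_valid=np.ones(9, bool))
        with pytest.raises(ValueError, match="bpm"):
            CTGRecord(fhr=np.full(10, 250.0), uc=np.full(10, 10.0),
                      fhr_valid=np.ones(10, bool), uc_valid=np.ones(10, bool))
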
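"""Phantom geometry and series synthesis."""

import math

import numpy as np
import pytest

from sapphire_t1.config import RunConfig
from sapphire_t1.phantom import (
    CARDIAC_LABELS,
    PhantomSpec,
    build_cardiac_phantom,
    build_vial_phantom,
    default_vial_t1s,
    simulate_experiment,
    synthesize_series,
)
from sapphire_t1.signal_model import TissueParams, signal_series


def septal_wall_width(label_map, center_row):
    """Width (pixels) of the myocardium run on the row through the LV center,
    on the septal (left) side."""
    row = label_map[center_row]
    myo = np.nonzero(row == CARDIAC_LABELS["myocardium"])[0]
    left = myo[myo < len(row) // 2]
    runs = np.split(left, np.nonzero(np.diff(left) > 1)[0] + 1)
    return max(len(r) for r in runs)


class TestCardiacGeometry:
    def test_compartment_t1_assignment(self, small_cardiac_truth):
        lm, t1 = small_cardiac_truth.label_map, small_cardiac_truth.t1_map
        assert np.all(t1[lm == CARDIAC_LABELS["myocardium"]] == 1578.0)
        assert np.all(t1[lm == CARDIAC_LABELS["blood"]] == 2048.0)
        assert np.all(t1[lm == CARDIAC_LABELS["fat"]] == 382.0)
        assert np.all(t1[lm == 0] == 0.0)

    def test_systolic_wall_thickness_scaling(self):
        spec = PhantomSpec(grid=650)
        dia = build_cardiac_phantom(spec, "diastole")
        sys_ = build_cardiac_phantom(spec, "systole")
        row = int(spec.resolved().lv_center[0])
        w_dia = septal_wall_width(dia.label_map, row)
        w_sys = septal_wall_width(sys_.label_map, row)
        assert w_sys / w_dia == pytest.approx(1.40, abs=2 / w_dia)

    def test_zero_fat_rim(self):
        truth = build_cardiac_phantom(PhantomSpec(grid=128, fat_rim_thickness=0.0))
        assert not np.any(truth.label_map == CARDIAC_LABELS["fat"])

    def test_pixel_count_conservation(self, small_cardiac_truth):
        counts = np.bincount(small_cardiac_truth.label_map.ravel())
        assert counts.sum() == 128 * 128

    def test_geometry_overflow_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(grid=64, lv_outer_radius=40.0, wall_thickness=10.0).resolved()


class TestVialPhantom:
    def test_seven_disjoint_vials_with_assigned_truths(self):
        truth = build_vial_phantom(grid=192)
        labels = np.unique(truth.label_map)
        assert list(labels) == list(range(8))  # background + 7 vials
        expected = default_vial_t1s()
        for i in range(1, 8):
            vals = truth.t1_map[truth.label_map == i]
            assert np.all(vals == pytest.approx(expected[i - 1]))

    def test_single_vial(self):
        truth = build_vial_phantom([1000.0], grid=64)
        assert set(np.unique(truth.label_map)) == {0, 1}

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            build_vial_phantom(grid=64, vial_radius=30.0)


class TestSynthesizeSeries:
    def test_noiseless_magnitudes_match_closed_form(
        self, small_cardiac_truth, diastolic_timings, noiseless_cardiac_series
    ):
        truth = small_cardiac_truth
        myo = truth.label_map == CARDIAC_LABELS["myocardium"]
        expected = signal_series(TissueParams(1578.0), diastolic_timings)
        got = noiseless_cardiac_series.frames[:, myo]
        assert np.allclose(np.abs(got), np.abs(expected)[:, None])
        # sign carried on the real axis
        assert np.allclose(got.real, expected[:, None])

    def test_noise_sd_is_reference_signal_over_snr(
        self, small_cardiac_truth, diastolic_timings
    ):
        series = synthesize_series(small_cardiac_truth, diastolic_timings, snr=60.0, seed=0)
        clean = synthesize_series(small_cardiac_truth, diastolic_timings, snr=np.inf)
        noise = series.frames - clean.frames
        assert noise.real.std() == pytest.approx(1.0 / 60.0, rel=0.02)
        assert noise.imag.std() == pytest.approx(1.0 / 60.0, rel=0.02)

    def test_seed_determinism(self, small_cardiac_truth, diastolic_timings):
        a = synthesize_series(small_cardiac_truth, diastolic_timings, snr=60.0, seed=5)
        b = synthesize_series(small_cardiac_truth, diastolic_timings, snr=60.0, seed=5)
        assert np.array_equal(a.frames, b.frames)

    def test_empirical_snr_in_unprepared_myocardium(self, diastolic_timings):
        """Measured SNR in the unprepared frame's myocardium matches the
        configured value within 5% at grid >= 256^2."""
        truth = build_cardiac_phantom(PhantomSpec(grid=256), "diastole")
        series = synthesize_series(truth, diastolic_timings, snr=60.0, seed=2)
        myo = truth.label_map == CARDIAC_LABELS["myocardium"]
        ref = np.abs(series.frames[0][myo])
        snr_emp = ref.mean() / ref.std(ddof=1)
        assert snr_emp == pytest.approx(60.0, rel=0.05)

    def test_mistriggered_frames_differ_only_in_moving_region(self, diastolic_timings):
        spec = PhantomSpec(grid=128)
        dia = build_cardiac_phantom(spec, "diastole")
        sys_ = build_cardiac_phantom(spec, "systole")
        import dataclasses

        timings = [
            dataclasses.replace(fr, phase_label="systole") if fr.index == 4 else fr
            for fr in diastolic_timings
        ]
        mis = synthesize_series(dia, timings, snr=np.inf, truth_systole=sys_)
        clean = synthesize_series(dia, diastolic_timings, snr=np.inf, truth_systole=sys_)
        moving = dia.label_map != sys_.label_map
        diff = np.abs(mis.frames - clean.frames)
        assert np.all(diff[:, ~moving] == 0)
        assert np.any(diff[4][moving] > 0)

    def test_systolic_frames_require_systolic_truths(self, small_cardiac_truth, diastolic_timings):
        import dataclasses

        timings = [dataclasses.replace(fr, phase_label="systole") for fr in diastolic_timings]
        with pytest.raises(ValueError):
            synthesize_series(small_cardiac_truth, timings, snr=np.inf)


class TestSimulateExperiment:
    def test_condition_times_repetition_count_and_determinism(self):
        cfg = RunConfig.model_validate(
            {
                "phantom": {"kind": "cardiac", "grid": 64},
                "schedule": {"variant": "diastolic"},
                "rr": {"mean_ms": 667.0},
                "mistrigger": {"mode": "share"},
                "noise": {"snr": 60.0},
                "conditions_factor": [0.0, 0.3],
                "repetitions": 2,
                "base_seed": 99,
            }
        )
        recs = list(simulate_experiment(cfg))
        assert len(recs) == 4
        seeds = [r.seed for r in recs]
        assert len(set(seeds)) == 4
        recs2 = list(simulate_experiment(cfg))
        for a, b in zip(recs, recs2):
            assert a.seed == b.seed
            assert np.array_equal(a.series.frames, b.series.frames)

    def test_single_noiseless_repetition(self):
        cfg = RunConfig.model_validate(
            {
                "phantom": {"kind": "vial", "grid": 64, "vial_t1_ms": [500.0, 1500.0]},
                "schedule": {"variant": "systolic", "td_ms": 300.0},
                "rr": {"mean_ms": 1125.0, "sd_ms": 0.0},
                "noise": {"snr": None},
                "repetitions": 1,
            }
        )
        recs = list(simulate_experiment(cfg))
        assert len(recs) == 1
        assert np.isinf(recs[0].series.snr)
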
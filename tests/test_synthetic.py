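"""Generators: determinism, ground-truth fidelity, and process statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import welch

import ictalkit as ik
from ictalkit.errors import ParameterError, PlacementError, ScheduleError, SpecError
from ictalkit.synthetic import (ScheduledEvent, SyntheticCohortSpec,
                                SyntheticEEGSpec, SyntheticImageSpec,
                                assemble_recording, fgn_autocovariance,
                                gen_baseline, gen_cohort, gen_fgn,
                                gen_puncta_image)

FS = 250.0


class TestBaseline:
    def test_shape_and_samples(self):
        rec = gen_baseline(SyntheticEEGSpec(duration=60, seed=1))
        assert rec.signal.shape == (4, 15_000)
        assert rec.sampling_rate == FS

    def test_seeded_determinism(self):
        a = gen_baseline(SyntheticEEGSpec(duration=10, seed=5))
        b = gen_baseline(SyntheticEEGSpec(duration=10, seed=5))
        np.testing.assert_array_equal(a.signal, b.signal)

    def test_invalid_spec_rejected(self):
        with pytest.raises(SpecError):
            SyntheticEEGSpec(duration=-1, seed=0)
        with pytest.raises(SpecError):
            SyntheticEEGSpec(duration=10, seed=0, baseline_amplitude=0)
        with pytest.raises(SpecError):
            SyntheticEEGSpec(duration=10, seed=0, sampling_rate=200)

    def test_psd_slope_matches_spectral_slope(self):
        # independent periodogram-regression oracle over 2-80 Hz
        rec = gen_baseline(SyntheticEEGSpec(duration=120, seed=3,
                                            spectral_slope=1.0))
        f, p = welch(rec.signal[0], fs=FS, nperseg=2048)
        m = (f >= 2) & (f <= 80)
        slope = np.polyfit(np.log10(f[m]), np.log10(p[m]), 1)[0]
        assert abs(slope - (-1.0)) < 0.2

    def test_rms_calibration(self):
        rec = gen_baseline(SyntheticEEGSpec(duration=60, seed=9))
        rms = np.sqrt(np.mean(rec.signal ** 2, axis=1))
        np.testing.assert_allclose(rms, 20.0, rtol=1e-9)


class TestFgn:
    def test_white_noise_case_uncorrelated(self):
        x = gen_fgn(0.5, 16_384, 1)
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r1) < 0.05

    def test_autocovariance_matches_closed_form(self):
        # mean sample autocovariance over seeds vs gamma(k), within 3 SE
        lags = np.arange(1, 11)
        acs = np.array([
            [np.mean(x[:-k] * x[k:]) for k in lags]
            for x in (gen_fgn(0.8, 8192, s) for s in range(40))
        ])
        mean, se = acs.mean(axis=0), acs.std(axis=0) / np.sqrt(len(acs))
        theory = fgn_autocovariance(0.8, lags)
        assert np.all(np.abs(mean - theory) < 3 * se + 1e-12)

    def test_seeded_determinism(self):
        np.testing.assert_array_equal(gen_fgn(0.7, 1024, 3),
                                      gen_fgn(0.7, 1024, 3))

    @pytest.mark.parametrize("h", [0.0, 1.0, -0.2, 1.5])
    def test_hurst_domain_errors(self, h):
        with pytest.raises(ParameterError):
            gen_fgn(h, 1024, 0)

    def test_non_power_of_two_rejected(self):
        with pytest.raises(ParameterError):
            gen_fgn(0.5, 1000, 0)


class TestAssembleRecording:
    def test_empty_schedule_has_empty_truth(self):
        rec, truth = assemble_recording(SyntheticEEGSpec(duration=30, seed=2))
        assert len(truth) == 0
        assert rec.meta["n_injected_events"] == 0

    def test_focal_event_rms_confined_to_target_channel(self):
        ev = ScheduledEvent(kind="focal", onset=100, duration=15,
                            target_channel=2, amplitude_ratio=5)
        spec = SyntheticEEGSpec(duration=150, seed=7, event_schedule=[ev])
        rec, truth = assemble_recording(spec)
        i0, i1 = int(100 * FS), int(115 * FS)
        win_rms = np.sqrt(np.mean(rec.signal[:, i0:i1] ** 2, axis=1))
        assert win_rms[2] >= 4 * 20.0
        others = [c for c in range(4) if c != 2]
        assert np.all(win_rms[others] <= 1.2 * 20.0)
        assert truth.iloc[0]["channels"] == "P3"

    def test_generalized_event_raises_coherence(self):
        ev = ScheduledEvent(kind="generalized", onset=100, duration=15,
                            amplitude_ratio=5, coherence_level=0.9)
        spec = SyntheticEEGSpec(duration=150, seed=7, event_schedule=[ev])
        rec, _ = assemble_recording(spec)
        i0, i1 = int(100 * FS), int(115 * FS)
        msc_event = ik.pairwise_mean_coherence(rec.signal[:, i0:i1], FS)
        msc_base = ik.pairwise_mean_coherence(rec.signal[:, :i0 - int(10 * FS)], FS)
        assert msc_event > msc_base

    def test_overlapping_events_rejected(self):
        evs = [ScheduledEvent(kind="focal", onset=10, duration=10,
                              target_channel=0),
               ScheduledEvent(kind="generalized", onset=15, duration=10)]
        with pytest.raises(ScheduleError):
            SyntheticEEGSpec(duration=60, seed=0, event_schedule=evs)

    def test_truth_table_is_exhaustive(self, archetype_case):
        _, truth, _ = archetype_case
        assert len(truth) == 4
        assert truth["event_id"].is_unique


class TestPunctaImage:
    def _spec(self, **kw):
        base = dict(field_size=(50.0, 50.0), pixel_size=0.1,
                    layer_bands={"A": (0.0, 50.0)},
                    puncta_per_layer={"A": 10}, seed=3)
        base.update(kw)
        return SyntheticImageSpec(**base)

    def test_zero_puncta_blank_image(self):
        spec = self._spec(puncta_per_layer={"A": 0}, noise_sd=0.0)
        img, truth = gen_puncta_image(spec)
        assert len(truth) == 0
        assert np.allclose(img, spec.background_level)

    def test_disk_analytic_area(self):
        spec = self._spec(puncta_per_layer={"A": 50},
                          area_distribution=(np.pi * 0.25, 0.0),
                          circularity_distribution=(1.0, 1.0))
        _, truth = gen_puncta_image(spec)
        np.testing.assert_allclose(truth["area_analytic_um2"], 0.785, atol=5e-4)

    def test_per_layer_bookkeeping(self):
        spec = SyntheticImageSpec(
            field_size=(100.0, 90.0), pixel_size=0.1,
            layer_bands={"I": (0, 30), "II": (30, 60), "III": (60, 90)},
            puncta_per_layer={"I": 30, "II": 30, "III": 30}, seed=5)
        _, truth = gen_puncta_image(spec)
        assert len(truth) == 90
        assert truth["layer"].value_counts().to_dict() == {
            "I": 30, "II": 30, "III": 30}

    def test_seeded_determinism(self):
        a_img, a_tab = gen_puncta_image(self._spec())
        b_img, b_tab = gen_puncta_image(self._spec())
        np.testing.assert_array_equal(a_img, b_img)
        pd.testing.assert_frame_equal(a_tab, b_tab)

    def test_placement_error_when_field_too_crowded(self):
        spec = self._spec(field_size=(3.0, 3.0),
                          layer_bands={"A": (0.0, 3.0)},
                          puncta_per_layer={"A": 100}, max_retries=20)
        with pytest.raises(PlacementError):
            gen_puncta_image(spec)

    def test_invalid_spec_rejected(self):
        with pytest.raises(SpecError):
            self._spec(pixel_size=0.0)
        with pytest.raises(SpecError):
            self._spec(circularity_distribution=(0.0, 1.2))


class TestCohort:
    def test_noiseless_points_on_line(self):
        c = gen_cohort(SyntheticCohortSpec(n_animals=6, slope=2, intercept=1,
                                           noise_sd=0, predictor_range=(0, 1),
                                           seed=0))
        np.testing.assert_allclose(c["response"], 2 * c["predictor"] + 1)

    def test_null_slope_recovered_within_sampling_error(self):
        # OLS sampling bound: se(slope) ~ sd / (sqrt(n) * sd_x) ~ 0.024
        c = gen_cohort(SyntheticCohortSpec(n_animals=200, slope=0, intercept=0,
                                           noise_sd=1, predictor_range=(0, 10),
                                           seed=4))
        fit = ik.linfit(c["predictor"], c["response"])
        assert abs(fit.slope) < 0.2

    def test_seeded_determinism_and_size_guard(self):
        spec = SyntheticCohortSpec(n_animals=5, slope=1, intercept=0,
                                   noise_sd=0.3, predictor_range=(0, 1), seed=8)
        pd.testing.assert_frame_equal(gen_cohort(spec), gen_cohort(spec))
        with pytest.raises(SpecError):
            SyntheticCohortSpec(n_animals=2, slope=1, intercept=0,
                                noise_sd=0.3, predictor_range=(0, 1), seed=8)
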
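"""Puncta segmentation, filtering, laminar metrics and regression."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree
from shapely.geometry import Polygon, box

import ictalkit as ik
from ictalkit.errors import ParameterError
from ictalkit.structure_function import GFAP_FILTER, GLAST_FILTER
from ictalkit.synthetic import SyntheticImageSpec, gen_puncta_image


@pytest.fixture(scope="module")
def puncta_case():
    spec = SyntheticImageSpec(
        field_size=(80.0, 60.0), pixel_size=0.1,
        layer_bands={"I": (0, 20), "II": (20, 40), "III": (40, 60)},
        puncta_per_layer={"I": 20, "II": 20, "III": 20}, seed=31)
    img, truth = gen_puncta_image(spec)
    return img, truth, spec


class TestSegmentParticles:
    def test_blank_image_empty_table(self):
        _, table = ik.segment_particles(np.zeros((64, 64)), 0.1)
        assert len(table) == 0

    def test_single_disk_area(self):
        yy, xx = np.mgrid[0:64, 0:64]
        img = ((xx - 32) ** 2 + (yy - 32) ** 2 <= 25).astype(float)
        _, table = ik.segment_particles(img, 0.1)
        assert len(table) == 1
        assert table.iloc[0]["area_um2"] == pytest.approx(0.785, rel=0.10)

    def test_generated_field_fully_recovered(self, puncta_case):
        img, truth, spec = puncta_case
        _, table = ik.segment_particles(img, spec.pixel_size)
        assert len(table) == len(truth)
        tree = cKDTree(truth[["cx_um", "cy_um"]].to_numpy())
        d, idx = tree.query(table[["cx_um", "cy_um"]].to_numpy())
        err = np.abs(table["area_um2"].to_numpy()
                     - truth["area_um2"].to_numpy()[idx])
        assert err.max() <= spec.pixel_size ** 2  # within 1 px^2

    def test_missing_calibration_rejected(self):
        with pytest.raises(ParameterError):
            ik.segment_particles(np.zeros((8, 8)), 0.0)


class TestApplyFilter:
    @staticmethod
    def _table(areas, circ=0.8):
        return pd.DataFrame({"area_um2": areas,
                             "circularity": [circ] * len(areas)})

    def test_glast_window_boundaries_inclusive(self):
        kept = ik.apply_filter(self._table([0.04, 0.05, 3.0, 3.05]),
                               GLAST_FILTER)
        assert sorted(kept["area_um2"]) == [0.05, 3.0]

    def test_low_circularity_excluded(self):
        kept = ik.apply_filter(self._table([1.0], circ=0.2), GLAST_FILTER)
        assert len(kept) == 0

    def test_gfap_has_no_upper_area_bound(self):
        kept = ik.apply_filter(self._table([0.5, 1.0, 50.0]), GFAP_FILTER)
        assert sorted(kept["area_um2"]) == [1.0, 50.0]

    def test_empty_table_passthrough(self):
        assert len(ik.apply_filter(self._table([]), GLAST_FILTER)) == 0

    def test_idempotent_and_order_independent(self):
        t = self._table([0.04, 0.5, 1.5, 3.2])
        once = ik.apply_filter(t, GLAST_FILTER)
        twice = ik.apply_filter(once, GLAST_FILTER)
        pd.testing.assert_frame_equal(once, twice)
        shuffled = ik.apply_filter(t.iloc[::-1].reset_index(drop=True),
                                   GLAST_FILTER)
        assert sorted(shuffled["area_um2"]) == sorted(once["area_um2"])


class TestLayerMetrics:
    def test_hand_computed_example(self):
        table = pd.DataFrame({"area_um2": [2.0], "circularity": [0.9],
                              "cx_um": [5.0], "cy_um": [5.0]})
        m = ik.layer_metrics(table, box(0, 0, 10, 10), layer="II")
        assert m.coverage_pct == pytest.approx(2.0)
        assert m.density_per_1000um2 == pytest.approx(10.0)
        assert m.mean_puncta_area_um2 == pytest.approx(2.0)

    def test_generator_ground_truth_recovered(self, puncta_case):
        img, truth, spec = puncta_case
        _, table = ik.segment_particles(img, spec.pixel_size)
        roi = box(0, 20, 80, 40)  # layer II band
        m = ik.layer_metrics(table, roi, layer="II")
        sub = truth[truth["layer"] == "II"]
        assert m.n_puncta == len(sub)
        assert m.coverage_pct == pytest.approx(
            100 * sub["area_um2"].sum() / roi.area, rel=0.05)
        assert m.mean_puncta_area_um2 == pytest.approx(
            sub["area_um2"].mean(), rel=0.05)

    def test_empty_roi_contract(self):
        empty = pd.DataFrame(columns=["area_um2", "circularity",
                                      "cx_um", "cy_um"])
        m = ik.layer_metrics(empty, box(0, 0, 10, 10))
        assert m.mean_puncta_area_um2 is None
        assert m.coverage_pct == 0.0
        assert m.density_per_1000um2 == 0.0


class TestSubdivideLayer1:
    def test_rectangle_splits_into_equal_thirds(self):
        bands = ik.subdivide_layer1(box(0, 0, 10, 30))
        assert [name for name, _ in bands] == ["I-1", "I-2", "I-3"]
        for _, poly in bands:
            assert poly.area == pytest.approx(100.0)

    def test_band_areas_partition_roi(self):
        roi = Polygon([(0, 0), (12, 0), (6, 30)])  # triangle
        bands = ik.subdivide_layer1(roi)
        assert sum(p.area for _, p in bands) == pytest.approx(roi.area)

    def test_degenerate_roi_rejected(self):
        with pytest.raises(ParameterError):
            ik.subdivide_layer1(Polygon([(0, 0), (1, 0), (2, 0)]))


class TestLinfit:
    def test_exact_line_recovered(self):
        x = np.arange(6.0)
        fit = ik.linfit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_permuted_response_has_no_association(self):
        rng = np.random.default_rng(6)
        x = np.linspace(0, 1, 200)
        y = rng.permutation(2 * x + 1)
        assert ik.linfit(x, y).r_squared < 0.05

    def test_cohort_slope_recovery(self):
        from ictalkit.synthetic import SyntheticCohortSpec, gen_cohort
        c = gen_cohort(SyntheticCohortSpec(
            n_animals=6, slope=0.5, intercept=0.0, noise_sd=0.02,
            predictor_range=(0, 1), seed=9))
        assert ik.linfit(c["predictor"], c["response"]).slope == \
            pytest.approx(0.5, abs=0.1)

    def test_degenerate_inputs(self):
        with pytest.raises(ParameterError):
            ik.linfit([1, 1, 1], [1, 2, 3])
        with pytest.warns(UserWarning):
            fit = ik.linfit([1, 2, 3], [5, 5, 5])
        assert fit.r_squared == 0.0

    def test_r_squared_affine_invariant(self):
        rng = np.random.default_rng(7)
        x = np.linspace(0, 1, 20)
        y = 3 * x + rng.standard_normal(20)
        r2 = ik.linfit(x, y).r_squared
        assert ik.linfit(10 * x - 4, 0.5 * y + 7).r_squared == \
            pytest.approx(r2, rel=1e-9)

    def test_parameter_recovery_over_seeded_cohorts(self):
        from ictalkit.synthetic import SyntheticCohortSpec, gen_cohort
        slopes = []
        for seed in range(100):
            c = gen_cohort(SyntheticCohortSpec(
                n_animals=6, slope=1.0, intercept=0.0, noise_sd=0.2,
                predictor_range=(0, 1), seed=seed))
            slopes.append(ik.linfit(c["predictor"], c["response"]).slope)
        assert np.mean(slopes) == pytest.approx(1.0, abs=0.1)


class TestR2Matrix:
    @staticmethod
    def _cohort():
        rng = np.random.default_rng(12)
        frames = []
        for layer in ["I", "II", "III"]:
            x = np.linspace(0, 1, 6)
            y = 2 * x + 1 if layer == "III" else rng.standard_normal(6)
            frames.append(pd.DataFrame({"layer": layer, "glast_size": x,
                                        "seizure_freq": y}))
        return pd.concat(frames, ignore_index=True)

    def test_single_cell_matches_linfit(self):
        cohort = self._cohort()
        grid = ik.r2_matrix(cohort[cohort.layer == "III"],
                            ["glast_size"], ["seizure_freq"])
        assert len(grid) == 1
        assert grid.iloc[0]["r_squared"] == pytest.approx(1.0)
        assert grid.iloc[0]["n"] == 6

    def test_noiseless_layer_stands_out(self):
        grid = ik.r2_matrix(self._cohort(), ["glast_size"], ["seizure_freq"])
        by_layer = grid.set_index("layer")["r_squared"]
        assert by_layer["III"] == pytest.approx(1.0)
        assert by_layer["I"] < 0.6 and by_layer["II"] < 0.6

    def test_empty_layer_absent_not_zero(self):
        cohort = self._cohort()
        grid = ik.r2_matrix(cohort, ["glast_size"], ["seizure_freq"],
                            layers=["I", "II", "III", "IV"])
        assert "IV" not in set(grid["layer"])

    def test_missing_column_rejected(self):
        with pytest.raises(ParameterError):
            ik.r2_matrix(self._cohort(), ["nope"], ["seizure_freq"])


class TestFlagOutliers:
    def test_gross_outlier_flagged_others_not(self):
        x = np.linspace(0, 1, 12)
        y = 2 * x + 1
        y[5] += 10.0
        flags = ik.flag_outliers(x, y)
        assert flags[5]
        assert flags.sum() == 1
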
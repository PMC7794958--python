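"""Dimensions, spheroid volumes, weight regression and retail classes."""

import math

import numpy as np
import pytest

from cucurbita.geometry import EllipseFit
from cucurbita.quantify import (WEIGHT_CLASSES, assign_weight_class,
                                class_summary, ellipse_dimensions,
                                fit_weight_model, predict_weight,
                                spheroid_volume, summarize_class_counts,
                                FruitRecord)


def _fit(major, minor, theta=0.0):
    return EllipseFit(center_row=0, center_col=0, major_px=major,
                      minor_px=minor, orientation_deg=theta,
                      difference_score=0.0)


def monte_carlo_spheroid_volume(d, h, n=200_000, seed=0):
    """Independent oracle: rejection sampling of the spheroid indicator."""
    rng = np.random.default_rng(seed)
    a, c = d / 2.0, h / 2.0
    pts = rng.uniform(-1.0, 1.0, size=(n, 3)) * (a, a, c)
    inside = (pts[:, 0] / a) ** 2 + (pts[:, 1] / a) ** 2 + (pts[:, 2] / c) ** 2 <= 1
    return inside.mean() * 8.0 * a * a * c


class TestEllipseDimensions:
    def test_unit_conversion(self):
        assert ellipse_dimensions(_fit(14, 12), gsd_cm=1.0) == (14.0, 12.0)

    def test_gsd_scaling(self):
        d, h = ellipse_dimensions(_fit(14, 12), gsd_cm=0.5)
        assert (d, h) == (7.0, 6.0)

    def test_orientation_irrelevant(self):
        assert ellipse_dimensions(_fit(14, 12, 0.0)) == \
               ellipse_dimensions(_fit(14, 12, 137.0))

    def test_nonpositive_gsd_rejected(self):
        with pytest.raises(ValueError):
            ellipse_dimensions(_fit(14, 12), gsd_cm=0.0)


class TestSpheroidVolume:
    def test_sphere_closed_form(self):
        assert spheroid_volume(10.0, 10.0) == pytest.approx(523.5988, abs=1e-3)

    def test_survey_mean_fruit(self):
        assert spheroid_volume(13.8, 12.4) == pytest.approx(1236.45, abs=0.1)

    def test_against_monte_carlo_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            d = rng.uniform(6, 21)
            h = rng.uniform(6.5, min(d, 19.0))
            mc = monte_carlo_spheroid_volume(d, h, seed=int(rng.integers(1 << 30)))
            assert spheroid_volume(d, h) == pytest.approx(mc, rel=0.01)

    def test_quadratic_in_diameter(self):
        assert spheroid_volume(20, 10) == pytest.approx(4 * spheroid_volume(10, 10))

    def test_nonpositive_dimension_rejected(self):
        with pytest.raises(ValueError):
            spheroid_volume(0.0, 5.0)

    def test_taller_than_wide_warns(self):
        with pytest.warns(UserWarning):
            spheroid_volume(8.0, 10.0)


class TestWeightModel:
    def test_exact_recovery_noise_free(self):
        v = np.array([300.0, 800.0, 1500.0, 2500.0])
        w = 0.9 * v + 50.0
        m = fit_weight_model(v, w)
        assert m.slope == pytest.approx(0.9)
        assert m.intercept == pytest.approx(50.0)
        assert m.r_squared == pytest.approx(1.0)

    def test_through_origin_flag(self):
        v = np.array([300.0, 800.0, 1500.0, 2500.0])
        m = fit_weight_model(v, 0.9 * v, through_origin=True)
        assert m.intercept == 0.0
        assert m.slope == pytest.approx(0.9)

    def test_calibration_recovery_under_noise(self):
        """40-fruit calibration with ~3% weight noise keeps r^2 > 0.99."""
        from cucurbita.scene import assign_weights, sample_fruit_population

        pop = sample_fruit_population(40, seed=3)
        pop = assign_weights(pop, slope=0.96, intercept=0.0,
                             noise_sd=35.0, seed=3)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            v = [spheroid_volume(f.diameter_cm, f.height_cm) for f in pop]
        m = fit_weight_model(v, [f.weight_g for f in pop])
        assert m.r_squared > 0.99
        assert m.slope == pytest.approx(0.96, rel=0.05)

    def test_constant_volumes_rejected(self):
        with pytest.raises(ValueError):
            fit_weight_model([500.0] * 5, [1.0, 2, 3, 4, 5])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_weight_model([1.0, 2.0], [1.0, 2.0])

    def test_predict_identity_and_floor(self):
        m = fit_weight_model([100.0, 200.0, 300.0], [100.0, 200.0, 300.0])
        assert predict_weight(m, 523.6) == pytest.approx(523.6)
        m2 = fit_weight_model([100.0, 200.0, 300.0], [50.0, 150.0, 250.0])
        assert predict_weight(m2, 0.0) == max(m2.intercept, 0.0)

    def test_prediction_monotone_in_volume(self):
        m = fit_weight_model([100.0, 200.0, 300.0], [90.0, 210.0, 290.0])
        vols = np.linspace(0, 3000, 10)
        preds = [predict_weight(m, v) for v in vols]
        assert all(b >= a for a, b in zip(preds, preds[1:]))


class TestWeightClasses:
    @pytest.mark.parametrize("weight,label,marketable", [
        (450.0, "<0.5", False),
        (500.0, "0.5-0.8", True),
        (799.9, "0.5-0.8", True),
        (800.0, "0.8-1.0", True),
        (1000.0, "1.0-1.5", True),
        (1499.9, "1.0-1.5", True),
        (1500.0, ">=1.5", True),
        (1600.0, ">=1.5", True),
        (0.0, "<0.5", False),
    ])
    def test_bin_assignment(self, weight, label, marketable):
        assert assign_weight_class(weight) == label
        from cucurbita.quantify import is_marketable
        assert is_marketable(weight) is marketable

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            assign_weight_class(-1.0)


class TestClassSummary:
    def test_survey_class_counts_marketable_share(self):
        table = summarize_class_counts([628, 351, 204, 535, 568])
        assert table.attrs["total"] == 2286
        assert table.attrs["marketable_share"] == pytest.approx(72.5, abs=0.05)

    def test_survey_class_percentages(self):
        table = summarize_class_counts([628, 351, 204, 535, 568])
        # round-half-even at one decimal
        assert table["percent"].tolist() == [27.5, 15.4, 8.9, 23.4, 24.8]

    def test_percentages_sum_to_about_100(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 1000, size=5)
        table = summarize_class_counts(counts)
        assert abs(table["percent"].sum() - 100.0) <= 0.2

    def test_single_record(self):
        rec = FruitRecord(id=1, x=0, y=0, diameter_cm=14, height_cm=12,
                          volume_cm3=1200.0, weight_g=1150.0,
                          weight_class=assign_weight_class(1150.0),
                          marketable=True)
        table = class_summary([rec])
        row = table[table["weight_class"] == "1.0-1.5"].iloc[0]
        assert row["count"] == 1
        assert row["percent"] == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            class_summary([])
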
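"""Descriptor definitions, the feature-table contract, scaling laws."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from enose.features import (
    DESCRIPTOR_NAMES,
    FeatureWindow,
    average_differential,
    energy_value,
    extract_features,
    integral_value,
    maximum_gradient,
    stable_average,
    variance_value,
)
from enose.preprocess import drop_dead_channels
from enose.synth import ResponseCurve


def _curve(values, t0=0.0):
    values = np.asarray(values, dtype=float)
    return ResponseCurve(0, t0 + np.arange(len(values), dtype=float), values)


FULL = FeatureWindow(30.0, 300.0)


def _full_curve(const=None, rng=None):
    n = 351
    if const is not None:
        return _curve(np.full(n, float(const)))
    return _curve(rng.normal(size=n))


class TestDescriptors:
    def test_integral_constant_is_rectangle_area(self):
        assert integral_value(_full_curve(2.0), FULL) == pytest.approx(540.0)

    def test_integral_linear_is_triangle_area(self):
        c = _curve(np.arange(11.0))  # v = t on [0, 10]
        assert integral_value(c, FeatureWindow(0.0, 10.0)) == pytest.approx(50.0)

    def test_integral_matches_summation_oracle(self, rng):
        c = _full_curve(rng=rng)
        v = c.values[30:301]
        oracle = float(np.sum((v[1:] + v[:-1]) / 2))
        assert integral_value(c, FULL) == pytest.approx(oracle, abs=1e-10)

    def test_variance_constant_zero(self):
        assert variance_value(_full_curve(3.3), FULL) == 0.0

    def test_variance_two_values(self):
        c = _curve([1.0, 3.0, 1.0, 3.0])
        assert variance_value(c, FeatureWindow(0.0, 3.0)) == pytest.approx(1.0)

    def test_variance_two_pass_oracle(self, rng):
        c = _full_curve(rng=rng)
        v = c.values[30:301]
        oracle = float(np.mean((v - v.mean()) ** 2))
        assert variance_value(c, FULL) == pytest.approx(oracle, rel=1e-10)

    def test_average_differential_linear_slope(self):
        c = _curve(0.5 * np.arange(351.0))
        assert average_differential(c, FULL) == pytest.approx(0.5)

    def test_average_differential_constant_zero(self):
        assert average_differential(_full_curve(9.0), FULL) == 0.0

    def test_average_differential_telescoping_identity(self, rng):
        c = _full_curve(rng=rng)
        v = c.values[30:301]
        assert average_differential(c, FULL) == pytest.approx(
            (v[-1] - v[0]) / (len(v) - 1), abs=1e-12
        )

    def test_max_gradient_monotone_decreasing(self):
        c = _curve(np.array([10.0, 7.0, 5.0, 4.0]))
        # least-negative first difference
        assert maximum_gradient(c, FeatureWindow(0.0, 3.0)) == pytest.approx(-1.0)

    def test_max_gradient_step(self):
        c = _curve(np.array([0.0, 0.0, 3.0, 3.0]))
        assert maximum_gradient(c, FeatureWindow(0.0, 3.0)) == pytest.approx(3.0)

    def test_max_gradient_brute_force(self, rng):
        c = _full_curve(rng=rng)
        v = c.values[30:301]
        oracle = max(v[i + 1] - v[i] for i in range(len(v) - 1))
        assert maximum_gradient(c, FULL) == pytest.approx(oracle)

    def test_stable_average_constant(self):
        for frac in (0.2, 0.5, 1.0):
            assert stable_average(_full_curve(4.2), FULL, frac) == pytest.approx(4.2)

    def test_stable_average_last_half(self):
        c = _curve(np.arange(10.0))
        assert stable_average(c, FeatureWindow(0.0, 9.0), 0.5) == pytest.approx(7.0)

    def test_stable_average_full_fraction_is_window_mean(self, rng):
        c = _full_curve(rng=rng)
        assert stable_average(c, FULL, 1.0) == pytest.approx(
            c.values[30:301].mean()
        )

    def test_energy_constant(self):
        # m * c^2 * dt over the 271-point window
        assert energy_value(_full_curve(2.0), FULL) == pytest.approx(271 * 4.0)

    def test_energy_zero_channel(self):
        assert energy_value(_full_curve(0.0), FULL) == 0.0

    def test_energy_summation_oracle(self, rng):
        c = _full_curve(rng=rng)
        oracle = float(sum(x * x for x in c.values[30:301]))
        assert energy_value(c, FULL) == pytest.approx(oracle, rel=1e-12)

    def test_window_outside_grid_raises(self):
        with pytest.raises(ValueError, match="outside"):
            integral_value(_curve(np.zeros(100)), FeatureWindow(30.0, 300.0))


class TestExtractFeatures:
    def test_eight_channels_give_48_features(self, small_dataset):
        table = extract_features(small_dataset)
        assert table.d == 48
        assert len(table.feature_names) == 48

    def test_dead_channel_exclusion_gives_36(self, small_dataset):
        reduced, _ = drop_dead_channels(small_dataset)
        table = extract_features(reduced)
        assert table.d == 36

    def test_empty_dataset_gives_empty_named_table(self):
        table = extract_features([])
        assert table.X.shape[0] == 0 and table.feature_names == []

    def test_feature_order_stable(self, small_dataset):
        t1 = extract_features(small_dataset)
        t2 = extract_features(small_dataset)
        assert t1.feature_names == t2.feature_names
        assert t1.feature_names[:6] == [f"ch0_{d}" for d in DESCRIPTOR_NAMES]

    def test_dead_channel_features_all_zero(self, small_dataset):
        table = extract_features(small_dataset)
        for j, name in enumerate(table.feature_names):
            if name.startswith(("ch2_", "ch6_")):
                assert np.all(table.X[:, j] == 0.0)

    @given(st.floats(0.5, 10.0))
    def test_scaling_laws(self, c):
        rng = np.random.default_rng(5)
        v = rng.uniform(0.5, 2.0, size=351)
        base = _curve(v)
        scaled = _curve(c * v)
        assert integral_value(scaled, FULL) == pytest.approx(
            c * integral_value(base, FULL), rel=1e-9
        )
        assert average_differential(scaled, FULL) == pytest.approx(
            c * average_differential(base, FULL), rel=1e-9
        )
        assert maximum_gradient(scaled, FULL) == pytest.approx(
            c * maximum_gradient(base, FULL), rel=1e-9
        )
        assert stable_average(scaled, FULL) == pytest.approx(
            c * stable_average(base, FULL), rel=1e-9
        )
        assert variance_value(scaled, FULL) == pytest.approx(
            c**2 * variance_value(base, FULL), rel=1e-9
        )
        assert energy_value(scaled, FULL) == pytest.approx(
            c**2 * energy_value(base, FULL), rel=1e-9
        )

    def test_inconsistent_channel_sets_rejected(self, small_dataset):
        broken = list(small_dataset)
        from enose.synth import SampleRecord

        broken[1] = SampleRecord(
            broken[1].sample_id, broken[1].label, broken[1].curves[:-1]
        )
        with pytest.raises(ValueError, match="channels"):
            extract_features(broken)
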
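"""Smoothing, derivatives, summary statistics, segments and FAD assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ffcpredict as f
from ffcpredict.descriptors import STATISTIC_NAMES, fad_length
from ffcpredict.errors import ConfigurationError, InsufficientDataError

from conftest import make_feature_frame
from fad_oracle import oracle_fad

STAT = {name: i for i, name in enumerate(STATISTIC_NAMES)}


class TestSmoothing:
    def test_constant_passes_unchanged(self):
        x = np.full(100, 3.7)
        assert np.allclose(f.smooth_channel(x, fps=25), x, atol=1e-10)

    def test_slow_sinusoid_barely_attenuated(self):
        # |H(0.1 Hz)|^2 = 1 / (1 + 0.01) => < 2% loss
        t = np.arange(2000) / 25.0
        y = f.smooth_channel(np.sin(2 * np.pi * 0.1 * t), fps=25)
        interior = y[200:-200]
        assert np.max(np.abs(interior)) > 0.98

    def test_fast_sinusoid_strongly_attenuated(self):
        # forward-backward digital response: |H(f)|^2 with the bilinear
        # frequency mapping, 1 / (1 + (tan(pi f/fs) / tan(pi fc/fs))^2);
        # at 5 Hz this is ~0.029, close to the analog prediction 1/26
        t = np.arange(2000) / 25.0
        y = f.smooth_channel(np.sin(2 * np.pi * 5.0 * t), fps=25)
        interior = np.max(np.abs(y[200:-200]))
        expected = 1.0 / (1.0 + (np.tan(np.pi * 5 / 25) / np.tan(np.pi * 1 / 25)) ** 2)
        assert interior == pytest.approx(expected, rel=0.10)
        assert interior < 0.05

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            f.smooth_channel(np.zeros(10), fps=1.5)


class TestDerivatives:
    def test_constant(self):
        d1, d2 = f.derivatives(np.full(50, 2.0), fps=25)
        assert np.allclose(d1, 0) and np.allclose(d2, 0)

    def test_ramp(self):
        fps = 25.0
        x = np.arange(50) / fps
        d1, d2 = f.derivatives(x, fps)
        assert np.allclose(d1[1:], 1.0)
        assert np.allclose(d2[2:], 0.0)

    def test_quadratic_second_derivative(self):
        fps = 10.0
        x = (np.arange(30) / fps) ** 2
        _, d2 = f.derivatives(x, fps)
        assert np.allclose(d2[2:], 2.0)

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            f.derivatives(np.zeros(2), fps=25)


class TestStatistics:
    def test_constant_signal(self):
        s = f.summarize_statistics(np.full(10, 4.2))
        assert s[STAT["mean"]] == pytest.approx(4.2)
        assert s[STAT["std"]] == pytest.approx(0, abs=1e-12)
        assert s[STAT["range"]] == 0
        assert s[STAT["rel_duration_above_mean"]] == 0
        assert s[STAT["slope"]] == pytest.approx(0, abs=1e-12)

    def test_hand_computed_example(self):
        s = f.summarize_statistics(np.array([0.0, 1.0, 2.0, 3.0]))
        assert s[STAT["mean"]] == pytest.approx(1.5)
        assert s[STAT["max"]] == 3.0
        assert s[STAT["rel_time_of_max"]] == 1.0
        assert s[STAT["rel_duration_above_mean"]] == 0.5

    @given(st.integers(1, 200))
    @settings(deadline=None, derandomize=True)
    def test_output_length_is_16(self, n):
        rng = np.random.default_rng(n)
        assert f.summarize_statistics(rng.normal(size=n)).shape == (16,)

    @given(st.floats(0.1, 50.0), st.integers(5, 100))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_positive_scaling_equivariance(self, alpha, n):
        x = np.random.default_rng(n).normal(size=n)
        s1 = f.summarize_statistics(x)
        s2 = f.summarize_statistics(alpha * x)
        scaled = ["mean", "std", "min", "max", "range", "median", "iqr", "rms",
                  "mad_median", "slope", "q1", "q3"]
        invariant = ["rel_time_of_max", "rel_time_of_min",
                     "rel_duration_above_mean", "rel_mean_crossings"]
        for name in scaled:
            assert s2[STAT[name]] == pytest.approx(alpha * s1[STAT[name]], rel=1e-9, abs=1e-12)
        for name in invariant:
            assert s2[STAT[name]] == pytest.approx(s1[STAT[name]], abs=1e-12)

    def test_empty_input(self):
        with pytest.raises(InsufficientDataError):
            f.summarize_statistics(np.array([]))


class TestSegments:
    def test_even_split(self):
        assert f.segment_bounds(300, 3) == [(0, 100), (100, 200), (200, 300)]

    def test_uneven_split_rounding(self):
        assert f.segment_bounds(10, 3) == [(0, 3), (3, 7), (7, 10)]

    @given(st.integers(1, 500), st.integers(1, 5))
    @settings(deadline=None, derandomize=True)
    def test_partition_property(self, n, k):
        if n < k:
            with pytest.raises(InsufficientDataError):
                f.segment_bounds(n, k)
            return
        bounds = f.segment_bounds(n, k)
        assert bounds[0][0] == 0 and bounds[-1][1] == n
        for (a, b), (c, d) in zip(bounds, bounds[1:]):
            assert b == c and b > a
        lengths = [b - a for a, b in bounds]
        assert max(lengths) - min(lengths) <= 1

    def test_segment_spec_validation(self):
        with pytest.raises(ConfigurationError):
            f.SegmentSpec(3, (4,))
        with pytest.raises(ConfigurationError):
            f.SegmentSpec(3, ())


class TestComputeFad:
    @pytest.mark.parametrize(
        "name,length", [("FF1", 1824), ("FF2", 1008), ("FF3", 960), ("FF4", 1008)]
    )
    def test_fad_lengths(self, tiny_dataset, name, length):
        table = tiny_dataset.groups[0].participants[0]
        fad = f.compute_fad(table, f.feature_set(name))
        assert fad.values.shape == (length,)
        assert fad_length(len(f.feature_set(name))) == length

    def test_constant_table_degenerates(self):
        values = np.tile(np.linspace(0, 1, 38), (50, 1))
        table = f.FrameFeatureTable("p", 25.0, np.arange(50) / 25.0,
                                    np.ones(50, bool), values)
        fad = f.compute_fad(table, f.feature_set("FF3"))
        stats = fad.values.reshape(20, 3, 16)
        assert np.allclose(stats[:, 0, STAT["std"]], 0, atol=1e-9)
        assert np.allclose(stats[:, 1:, :], 0, atol=1e-8)  # derivatives vanish
        assert np.allclose(stats[:, 0, STAT["mean"]], table.values[0, :20], atol=1e-9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        spec = f.feature_set("FF4")
        for trial in range(20):
            n = int(rng.integers(30, 150))
            df = make_feature_frame(n, rng=rng)
            values = df[list(f.REGISTRY.names)].to_numpy(float)
            table = f.FrameFeatureTable(f"p{trial}", 25.0, np.arange(n) / 25.0,
                                        np.ones(n, bool), values)
            fad = f.compute_fad(table, spec)
            sel = [f.REGISTRY.index(c) for c in spec.selected]
            expected = oracle_fad(values[:, sel], fps=25.0)
            np.testing.assert_allclose(fad.values, expected, rtol=1e-9, atol=1e-12)

    def test_segment_restriction_changes_only_window(self, tiny_dataset):
        table = tiny_dataset.groups[0].participants[0]
        spec = f.feature_set("FF4")
        parts = f.compute_fads(table, spec, f.SegmentSpec(3, (1, 3)))
        assert [p.segment_part for p in parts] == [1, 3]
        assert all(p.values.shape == (1008,) for p in parts)

    def test_segment_too_short(self):
        values = np.zeros((4, 38))
        table = f.FrameFeatureTable("p", 25.0, np.arange(4) / 25.0,
                                    np.ones(4, bool), values)
        with pytest.raises(InsufficientDataError):
            f.compute_fad(table, f.feature_set("FF4"), f.SegmentSpec(2, (1,)))
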
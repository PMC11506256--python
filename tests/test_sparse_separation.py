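"""Mono-source-zone detection, ratio selection and source reconstruction."""

import numpy as np
import pytest

from dermabss.sparse_separation import (MonoSourceZone,
                                        detect_monosource_zones,
                                        reconstruct_sources, select_ratios)


def _zones(specs):
    """Zones from (variance, ratio_mean) pairs."""
    return [MonoSourceZone(start=64 * k, length=64, variance=v,
                           ratio_mean=r, n_valid=64)
            for k, (v, r) in enumerate(specs)]


class TestDetection:
    def test_single_source_field_every_segment_retained_with_exact_ratio(self):
        x1 = np.random.default_rng(0).uniform(0.5, 1.5, size=512)
        zones = detect_monosource_zones(x1, 0.7 * x1, L=64)
        assert len(zones) == 8
        assert all(z.variance < 1e-28 for z in zones)   # float-exact ratio
        np.testing.assert_allclose([z.ratio_mean for z in zones], 0.7,
                                   atol=1e-14)

    def test_disjoint_sparse_sources_zones_inside_true_regions(self):
        # S1 active on the first half of the raster, S2 on the second half
        rng = np.random.default_rng(1)
        n, L = 1024, 64
        s1 = np.zeros(n)
        s2 = np.zeros(n)
        s1[:n // 2] = rng.uniform(0.5, 1.0, n // 2)
        s2[n // 2:] = rng.uniform(0.5, 1.0, n // 2)
        m = np.array([[0.86, 0.70], [0.13, 0.29]])
        x1 = m[0, 0] * s1 + m[0, 1] * s2
        x2 = m[1, 0] * s1 + m[1, 1] * s2
        zones = detect_monosource_zones(x1, x2, L=L)
        true_ratios = (m[1, 0] / m[0, 0], m[1, 1] / m[0, 1])
        for z in zones:
            inside_s1 = z.start + z.length <= n // 2
            inside_s2 = z.start >= n // 2
            assert inside_s1 or inside_s2
            np.testing.assert_allclose(
                z.ratio_mean, true_ratios[0] if inside_s1 else true_ratios[1],
                atol=1e-12)
        r1, r2 = select_ratios(zones)
        np.testing.assert_allclose((r1, r2), sorted(true_ratios), atol=1e-12)

    def test_zero_segment_discarded_by_guard_without_division_error(self):
        x1 = np.ones(256)
        x1[:64] = 0.0
        x2 = 0.5 * x1
        zones = detect_monosource_zones(x1, x2, L=64)
        assert all(z.start >= 64 for z in zones)

    def test_fewer_than_two_valid_segments_rejected(self):
        x1 = np.zeros(256)
        x1[:64] = 1.0
        with pytest.raises(ValueError, match="insufficient data"):
            detect_monosource_zones(x1, x1.copy(), L=64)

    def test_minimum_segment_length_enforced(self):
        with pytest.raises(ValueError, match="L"):
            detect_monosource_zones(np.ones(64), np.ones(64), L=4)

    def test_fallback_keeps_lowest_variance_segments(self):
        rng = np.random.default_rng(2)
        x1 = rng.uniform(0.5, 1.5, size=1024)
        x2 = rng.uniform(0.5, 1.5, size=1024)   # no mono-source structure
        zones = detect_monosource_zones(x1, x2, L=64, var_threshold=0.0,
                                        k_min=5)
        assert len(zones) == 5
        variances = [z.variance for z in zones]
        assert variances == sorted(variances)


class TestSelectRatios:
    def test_worked_instance_of_the_midpoint_rule(self):
        zones = _zones([(0.0, 2.0), (1e-6, 2.05), (1e-5, 5.0)])
        assert select_ratios(zones) == (2.0, 5.0)

    def test_orientation_larger_ratio_is_deoxy_column(self):
        zones = _zones([(0.0, 0.9), (1e-6, 0.4)])
        assert select_ratios(zones) == (0.4, 0.9)

    def test_invariant_to_order_preserving_permutations(self):
        zones = _zones([(0.0, 2.0), (1e-6, 2.05), (1e-5, 5.0)])
        shuffled = [zones[2], zones[0], zones[1]]
        assert select_ratios(shuffled) == select_ratios(zones)

    def test_literal_threshold_rule_available(self):
        # e = (2+5)/2 = 3.5 > |5-2|: the literal rule never triggers and
        # falls back to the farthest ratio
        zones = _zones([(0.0, 2.0), (1e-6, 2.05), (1e-5, 5.0)])
        assert select_ratios(zones, rule="literal") == (2.0, 5.0)

    def test_identical_ratios_rejected(self):
        with pytest.raises(ValueError, match="indistinguishable"):
            select_ratios(_zones([(0.0, 1.5), (1e-6, 1.5)]))


class TestReconstruction:
    def test_exact_two_source_algebra(self):
        rng = np.random.default_rng(3)
        s1 = np.clip(rng.standard_normal(512), 0, None)
        s2 = np.clip(rng.standard_normal(512), 0, None)
        m = np.array([[0.86, 0.70], [0.13, 0.29]])
        x1 = m[0, 0] * s1 + m[0, 1] * s2
        x2 = m[1, 0] * s1 + m[1, 1] * s2
        r1, r2 = m[1, 0] / m[0, 0], m[1, 1] / m[0, 1]
        y1, y2 = reconstruct_sources(x1, x2, r1, r2)
        np.testing.assert_allclose(y1, (r2 * m[0, 0] - m[1, 0]) * s1,
                                   atol=1e-10)
        np.testing.assert_allclose(y2, abs(r1 * m[0, 1] - m[1, 1]) * s2,
                                   atol=1e-10)
        assert y1.mean() >= 0 and y2.mean() >= 0

    def test_equal_ratios_rejected(self):
        x = np.ones(16)
        with pytest.raises(ValueError):
            reconstruct_sources(x, x, 0.5, 0.5)


def test_noise_free_monosource_ratio_recovery_is_exact():
    """On mixtures whose zones satisfy the sparsity hypothesis exactly, the
    detected ratio means equal the true column ratios to machine precision."""
    rng = np.random.default_rng(4)
    n, L = 2048, 64
    s1 = np.clip(np.sin(np.arange(n) / 150.0), 0, None) * \
        rng.uniform(0.5, 1.0, n)
    s2 = np.clip(-np.sin(np.arange(n) / 150.0), 0, None) * \
        rng.uniform(0.5, 1.0, n)
    m = np.array([[0.86, 0.70], [0.13, 0.29]])
    x1, x2 = m @ np.vstack([s1, s2])
    zones = detect_monosource_zones(x1, x2, L=L)
    r1, r2 = select_ratios(zones)
    np.testing.assert_allclose(r1, m[1, 0] / m[0, 0], atol=1e-13)
    np.testing.assert_allclose(r2, m[1, 1] / m[0, 1], atol=1e-13)
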
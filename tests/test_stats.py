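"""Ecotope partitioning, correlation distributions and community-state maps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metapatch.pipeline import OccupancyTable
from metapatch.stats import (EcotopeSeries, distribution_summary,
                             ecotope_pearson, partition_ecotopes,
                             state_density_map, trajectory_ensemble)


def _tables(n_landscapes, n_patches=85, n_frames=4, corridors=True, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for s in range(n_landscapes):
        E = rng.random((n_patches, n_frames))
        P = rng.random((n_patches, n_frames))
        out.append(OccupancyTable(
            E=E, P=P, times_min=np.arange(n_frames) * 10.0, landscape=s,
            corridor_E=rng.random((n_patches, n_frames)) if corridors else None,
            corridor_P=rng.random((n_patches, n_frames)) if corridors else None,
        ))
    return out


class TestPartition:
    def test_counts_scale_with_landscapes(self):
        series, counts = partition_ecotopes(_tables(3))
        assert counts == {"patch": 255, "corridor": 255}
        assert len(series) == 510

    def test_virtual_kinds_labeled(self):
        _, counts = partition_ecotopes(_tables(2), virtual=True)
        assert set(counts) == {"virtual_patch", "virtual_corridor"}

    def test_mask_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            partition_ecotopes(_tables(1, n_patches=50))

    def test_series_carry_their_data(self):
        tabs = _tables(1)
        series, _ = partition_ecotopes(tabs)
        s = series[12]     # patch 13
        assert s.kind == "patch" and s.index == 13
        assert np.array_equal(s.E, tabs[0].E[12])


class TestPearson:
    def test_perfectly_coupled_series(self):
        t = np.linspace(0, 1, 50)
        s = EcotopeSeries(0, "patch", 1, t, 2 * t + 0.1)
        assert ecotope_pearson(s) == pytest.approx(1.0)

    def test_perfectly_opposed_series(self):
        t = np.linspace(0, 1, 50)
        s = EcotopeSeries(0, "patch", 1, t, 1 - t)
        assert ecotope_pearson(s) == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(123)
        s = EcotopeSeries(0, "patch", 1, rng.random(288), rng.random(288))
        assert abs(ecotope_pearson(s)) < 0.15

    def test_zero_variance_is_missing(self):
        s = EcotopeSeries(0, "corridor", 1, np.ones(20), np.linspace(0, 1, 20))
        assert np.isnan(ecotope_pearson(s))

    def test_window_restricts_frames(self):
        E = np.concatenate([np.zeros(10), np.linspace(0, 1, 20)])
        P = np.concatenate([np.zeros(10), np.linspace(1, 0, 20)])
        s = EcotopeSeries(0, "patch", 1, E, P)
        times = np.arange(30) * 10.0
        r_late = ecotope_pearson(s, window=(100.0, 290.0), times=times)
        assert r_late == pytest.approx(-1.0)

    def test_too_short_series_rejected(self):
        s = EcotopeSeries(0, "patch", 1, np.array([0.1, 0.2]),
                          np.array([0.3, 0.1]))
        with pytest.raises(ValueError):
            ecotope_pearson(s)

    @settings(deadline=None, max_examples=25)
    @given(a=st.floats(0.01, 5), b=st.floats(-3, 3))
    def test_invariant_under_affine_rescaling(self, a, b):
        rng = np.random.default_rng(7)
        E = rng.random(60)
        P = rng.random(60)
        s0 = EcotopeSeries(0, "patch", 1, E, P)
        s1 = EcotopeSeries(0, "patch", 1, a * E + b, P)
        assert ecotope_pearson(s1) == pytest.approx(ecotope_pearson(s0),
                                                    abs=1e-9)


class TestDistributionSummary:
    def test_symmetric_sample_has_no_skew(self):
        rng = np.random.default_rng(0)
        summ = distribution_summary(rng.normal(0.2, 0.1, 2000))
        assert abs(summ.skewness) < 0.1
        assert not summ.bimodal

    def test_well_separated_mixture_called_bimodal(self):
        rng = np.random.default_rng(1)
        sample = np.concatenate([rng.normal(-0.2, 0.05, 250),
                                 rng.normal(0.6, 0.05, 250)])
        summ = distribution_summary(sample)
        assert summ.bimodal
        assert summ.bic_margin > 10

    def test_single_gaussian_not_bimodal(self):
        rng = np.random.default_rng(2)
        summ = distribution_summary(rng.normal(0.1, 0.2, 500))
        assert not summ.bimodal

    def test_skewed_unimodal_not_bimodal(self):
        rng = np.random.default_rng(3)
        summ = distribution_summary(rng.lognormal(0.0, 0.5, 1000))
        assert summ.skewness > 0.5
        assert not summ.bimodal

    def test_nan_values_excluded_and_small_samples_rejected(self):
        vals = np.concatenate([np.full(40, np.nan),
                               np.random.default_rng(4).normal(0, 1, 60)])
        assert distribution_summary(vals).n == 60
        with pytest.raises(ValueError):
            distribution_summary(np.ones(20))


class TestStateDensityMap:
    def test_succession_climax_corner(self):
        m = state_density_map(np.zeros(200), np.full(200, 1.0))
        assert m.peak() == pytest.approx((0.01, 0.51), abs=0.02)
        assert m.counts.sum() == 200

    def test_colonizer_dominated_corner(self):
        m = state_density_map(np.full(100, 1.0), np.zeros(100))
        assert m.peak() == pytest.approx((0.99, 0.51), abs=0.02)

    def test_low_density_colonizer_corner(self):
        m = state_density_map(np.full(100, 0.04), np.zeros(100))
        x, y = m.peak()
        assert x > 0.95 and y < 0.05

    def test_empty_patches_dropped_not_zeroed(self):
        E = np.array([0.0, 0.5]); P = np.array([0.0, 0.5])
        m = state_density_map(E, P)
        assert m.n_samples == 1
        assert m.n_dropped == 1
        assert m.counts.sum() == 1


class TestTrajectoryEnsemble:
    def _tabs(self, n):
        T = 6 * 48   # 48 h at 10-min frames
        tabs = []
        for s in range(n):
            E = np.full((85, T), 0.4)
            P = np.full((85, T), 0.4)
            tabs.append(OccupancyTable(E=E, P=P,
                                       times_min=np.arange(T) * 10.0,
                                       landscape=s))
        return tabs

    def test_configuration_counts(self):
        """72 landscapes x 6 frames/h -> 432 configurations per hourly bin."""
        ens = trajectory_ensemble(self._tabs(72))
        assert np.all(ens.configurations_per_hour == 432)
        assert ens.n_total == 432 * 48     # 20736 before exclusions

    def test_constant_landscapes_fill_single_column(self):
        ens = trajectory_ensemble(self._tabs(3), bins=40)
        occupied = (ens.counts > 0).sum(axis=1)
        assert np.all(occupied == 1)
        col = np.argmax(ens.counts[0])
        assert ens.frac_edges[col] <= 0.5 <= ens.frac_edges[col + 1]

    def test_count_conservation_with_exclusions(self):
        tabs = self._tabs(2)
        tabs[0].E[:, :12] = 0.0     # first 2 h of landscape 0 empty
        tabs[0].P[:, :12] = 0.0
        ens = trajectory_ensemble(tabs)
        assert ens.n_total == 2 * 6 * 48 - 12
        assert ens.counts.sum() == ens.n_total
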
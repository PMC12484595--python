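"""Vertical-distribution indicators against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from seiszoo import echo
from seiszoo.synthetic import ApproachScenario, gen_approach_track, gen_echogram
from conftest import make_layer


def brute_force_moments(sv_db, depths, dz, mask):
    """Independent double-loop oracle for CM and inertia."""
    num = den = 0.0
    for i in range(len(depths)):
        if mask[i]:
            continue
        w = 10 ** (sv_db[i] / 10) * dz
        num += depths[i] * w
        den += w
    cm = num / den
    iner = 0.0
    for i in range(len(depths)):
        if not mask[i]:
            iner += (depths[i] - cm) ** 2 * 10 ** (sv_db[i] / 10) * dz
    return cm, iner / den


class TestDomainConversion:
    def test_definitions(self):
        assert echo.db_to_linear(-70.0) == pytest.approx(1e-7)
        assert echo.db_to_linear(0.0) == 1.0

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-90, -40, size=(6, 7))
        assert np.allclose(echo.linear_to_db(echo.db_to_linear(x)), x, rtol=1e-12)


class TestExclusions:
    def make_grid(self):
        z = np.arange(1.0, 70.0, 2.0)
        t = np.arange(1.0, 9.0, 2.0)
        return echo.SvGrid(np.full((z.size, t.size), -75.0), z, t)

    def test_surface_five_masks_shallow_bins(self):
        g = echo.apply_exclusions(self.make_grid(), 5.0, bottom_clearance=0.0)
        masked_depths = g.depth_centers[g.mask[:, 0]]
        assert set(masked_depths) == {1.0, 3.0}

    def test_noop(self):
        g = echo.apply_exclusions(self.make_grid(), 0.0, bottom_clearance=0.0)
        assert not g.mask.any()

    def test_bottom_clearance(self):
        # centers 1..69 m, bottom edge 70 m: clearance 5 masks 67 and 69 m
        g = echo.apply_exclusions(self.make_grid(), 0.0, bottom_clearance=5.0)
        assert g.mask[-1].all() and g.mask[-2].all() and not g.mask[-3].any()

    def test_all_masked_errors(self):
        with pytest.raises(ValueError):
            echo.apply_exclusions(self.make_grid(), 70.0)


class TestProfileMoments:
    def test_point_mass(self):
        z = np.arange(1.0, 69.0, 2.0)
        sv = np.zeros(z.size)
        sv[np.where(z == 21.0)[0][0]] = 1e-6
        # point mass at 21 m (bin center); choose 21 as an exact center
        assert echo.center_of_mass(sv, z, 2.0) == pytest.approx(21.0)
        assert echo.inertia(sv, z, 2.0) == 0.0

    def test_equal_masses_at_10_and_30(self):
        z = np.array([10.0, 30.0])
        sv = np.array([1e-6, 1e-6])
        assert echo.center_of_mass(sv, z, 2.0) == pytest.approx(20.0)
        assert echo.inertia(sv, z, 2.0) == pytest.approx(100.0)

    def test_uniform_profile_symmetry(self):
        z = np.arange(1.0, 70.0, 2.0)
        assert echo.center_of_mass(np.ones(z.size), z, 2.0) == pytest.approx(35.0)

    def test_gaussian_sd5_inertia_near_25(self):
        z = np.arange(1.0, 70.0, 2.0)
        sv = np.exp(-((z - 35.0) ** 2) / (2 * 25.0))
        assert echo.inertia(sv, z, 2.0) == pytest.approx(25.0, rel=0.05)

    def test_zero_profile_sentinel(self):
        z = np.array([10.0, 30.0])
        assert np.isnan(echo.center_of_mass(np.zeros(2), z, 2.0))

    def test_area_scattering_closed_form(self):
        # one cell at sv = 1e-7 m^-1 and dz = 2 m
        expected = 4 * np.pi * 1852 ** 2 * 2e-7
        assert echo.area_scattering(np.array([1e-7]), 2.0) == pytest.approx(expected)
        assert echo.area_scattering(np.zeros(3), 2.0) == 0.0

    def test_area_scattering_linearity(self):
        rng = np.random.default_rng(1)
        sv = rng.uniform(0, 1e-6, 20)
        assert echo.area_scattering(2 * sv, 2.0) == pytest.approx(
            2 * echo.area_scattering(sv, 2.0))


class TestOracleEquivalence:
    def test_hundred_random_masked_grids(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(5, 40)
            z = np.arange(1.0, 1.0 + 2 * n, 2.0)
            sv_db = rng.uniform(-90, -50, n)
            mask = rng.random(n) < 0.3
            if mask.all():
                mask[rng.integers(n)] = False
            cm_o, in_o = brute_force_moments(sv_db, z, 2.0, mask)
            sv = echo.db_to_linear(sv_db)
            assert echo.center_of_mass(sv, z, 2.0, mask) == pytest.approx(cm_o, rel=1e-9)
            assert echo.inertia(sv, z, 2.0, mask) == pytest.approx(in_o, rel=1e-9)


class TestInvariances:
    def setup_method(self):
        rng = np.random.default_rng(5)
        self.z = np.arange(1.0, 61.0, 2.0)
        self.sv = rng.uniform(0, 1e-6, self.z.size)

    def test_positive_scaling(self):
        assert echo.center_of_mass(7 * self.sv, self.z, 2.0) == pytest.approx(
            echo.center_of_mass(self.sv, self.z, 2.0))
        assert echo.inertia(7 * self.sv, self.z, 2.0) == pytest.approx(
            echo.inertia(self.sv, self.z, 2.0))
        assert echo.area_scattering(7 * self.sv, 2.0) == pytest.approx(
            7 * echo.area_scattering(self.sv, 2.0))

    def test_depth_shift(self):
        cm0 = echo.center_of_mass(self.sv, self.z, 2.0)
        in0 = echo.inertia(self.sv, self.z, 2.0)
        assert echo.center_of_mass(self.sv, self.z + 4.0, 2.0) == pytest.approx(cm0 + 4.0)
        assert echo.inertia(self.sv, self.z + 4.0, 2.0) == pytest.approx(in0)

    def test_merged_time_bins_are_sa_weighted(self):
        rng = np.random.default_rng(6)
        a, b = rng.uniform(0, 1e-6, (2, self.z.size))
        cm_merged = echo.center_of_mass(a + b, self.z, 2.0)
        wa, wb = a.sum(), b.sum()
        cm_w = (wa * echo.center_of_mass(a, self.z, 2.0)
                + wb * echo.center_of_mass(b, self.z, 2.0)) / (wa + wb)
        assert cm_merged == pytest.approx(cm_w, rel=1e-12)


class TestIndicatorsByTime:
    def test_stationary_noise_free_layer(self, full_track, quiet_layer):
        grid, truth = gen_echogram(quiet_layer, full_track)
        ind = echo.indicators_by_time(grid)
        assert np.allclose(ind["cm_m"], ind["cm_m"].iloc[0])
        assert ind["cm_m"].iloc[0] == pytest.approx(25.0, abs=0.2)

    def test_all_masked_time_bin_dropped(self):
        z = np.arange(1.0, 11.0, 2.0)
        t = np.array([1.0, 3.0])
        g = echo.SvGrid(np.full((z.size, 2), -70.0), z, t)
        g.mask[:, 1] = True
        ind = echo.indicators_by_time(g)
        assert np.isnan(ind["cm_m"].iloc[1]) and np.isfinite(ind["cm_m"].iloc[0])

    def test_binning(self, full_track):
        grid, _ = gen_echogram(make_layer(seed=3), full_track)
        ind = echo.join_track(echo.indicators_by_time(grid), full_track)
        binned = echo.bin_by_distance(ind, 1000.0, 9000.0)
        assert len(binned) <= 9
        # constant indicator -> identical bin means
        const = ind.copy()
        const["cm_m"] = 30.0
        b2 = echo.bin_by_distance(const, 1000.0, 9000.0)
        assert np.allclose(b2["cm_m"], 30.0)


class TestIndicatorFit:
    def test_perfect_line_recovered(self):
        d = np.linspace(0, 9000, 50)
        df = pd.DataFrame({"distance_m": d, "cm_m": 20 + 0.001 * d,
                           "inertia_m2": 25 - 0.0005 * d})
        fit = echo.fit_indicator_glm(df, "cm")
        assert fit.slope == pytest.approx(0.001, rel=1e-9)
        assert fit.p_value < 1e-12
        fit2 = echo.fit_indicator_glm(df, "inertia")
        assert fit2.slope == pytest.approx(-0.0005, rel=1e-9)

    def test_constant_distance_rejected(self):
        df = pd.DataFrame({"distance_m": np.ones(10),
                           "cm_m": np.random.default_rng(0).normal(25, 1, 10)})
        with pytest.raises(ValueError, match="rank"):
            echo.IndicatorDistanceModel(df, "cm")

    def test_summary_has_slope(self, full_track):
        grid, _ = gen_echogram(make_layer(seed=1, inertia_slope=2.0), full_track)
        ind = echo.join_track(echo.indicators_by_time(grid), full_track)
        res = echo.fit_indicator_glm(ind, "inertia")
        assert res.n == len(ind.dropna())
        assert "coef" in str(res.summary()).lower()


class TestCsvRoundTrip:
    def test_grid_csv(self, tmp_path, full_track, quiet_layer):
        grid, _ = gen_echogram(quiet_layer, full_track)
        path = tmp_path / "grid.csv"
        grid.to_csv(path)
        back = echo.SvGrid.from_csv(path)
        assert np.allclose(back.sv_db, grid.sv_db)
        assert np.allclose(back.depth_centers, grid.depth_centers)
        assert np.allclose(back.time_centers, grid.time_centers)
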
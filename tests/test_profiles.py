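"""Unit tests for profile corrections and water-column diagnostics."""

import math

import numpy as np
import pytest

from bloomphen import (CorrectionsConfig, ProcessingError, ValidationError,
                       apply_fluorescence_calibration, bvf_profile,
                       correct_dark_offset, correct_npq, correct_oxygen,
                       density_sigma0, derive_all, euphotic_depth,
                       first_optical_depth, integrated_chl, mld, surface_chl)
from bloomphen.profiles import (GRAVITY, read_profiles_csv,
                                read_profiles_netcdf, write_profiles_csv,
                                write_profiles_netcdf)

from conftest import make_profile


# ---------------------------------------------------------------------- EOS

def test_eos80_check_value():
    """UNESCO one-atmosphere check value rho(35, 5, 0) = 1027.67547."""
    assert density_sigma0(35.0, 5.0) == pytest.approx(1027.67547, abs=1e-4)


# -------------------------------------------------------------- corrections

class TestDarkOffset:
    def test_constant_deep_offset_removed(self):
        z = np.arange(1.0, 1001.0, 1.0)
        chl = np.where(z < 100, 0.55, 0.05)
        p = make_profile(z, chl=chl)
        out = correct_dark_offset(p)
        assert np.allclose(out.chl[z < 100], 0.5)
        assert np.allclose(out.chl[z >= 900], 0.0)

    def test_zero_chl_unchanged(self):
        z = np.arange(1.0, 1001.0, 1.0)
        p = make_profile(z, chl=np.zeros_like(z))
        out = correct_dark_offset(p)
        assert np.array_equal(out.chl, p.chl)

    def test_planted_offset_recovered(self, clean_scenario, clean_world):
        _, profiles, _, _ = clean_world
        out = correct_dark_offset(profiles[0])
        offset = next(e["offset"] for e in out.provenance
                      if e["event"] == "dark_offset")
        assert offset == pytest.approx(clean_scenario.dark_offset, abs=1e-12)

    def test_too_few_deep_samples_skips(self):
        p = make_profile([1, 10, 50], chl=[0.5, 0.4, 0.3])
        out = correct_dark_offset(p)
        assert np.array_equal(out.chl, p.chl)
        assert any(e["event"] == "dark_offset_skipped" for e in out.provenance)

    def test_never_increases_chl(self):
        rng = np.random.default_rng(3)
        z = np.arange(1.0, 1001.0, 5.0)
        p = make_profile(z, chl=rng.uniform(0.0, 1.0, z.size))
        out = correct_dark_offset(p)
        assert np.all(out.chl <= p.chl + 1e-15)


class TestCalibration:
    def test_factor_two_halves(self):
        p = make_profile([1, 2], chl=[1.0, 0.4])
        assert np.allclose(apply_fluorescence_calibration(p, 2.0).chl,
                           [0.5, 0.2])

    def test_factor_one_identity(self):
        p = make_profile([1, 2], chl=[1.0, 0.4])
        assert np.array_equal(apply_fluorescence_calibration(p, 1.0).chl, p.chl)

    def test_inverse_composition(self):
        p = make_profile([1, 2], chl=[1.0, 0.4])
        back = apply_fluorescence_calibration(
            apply_fluorescence_calibration(p, 2.0), 0.5)
        assert np.allclose(back.chl, p.chl)

    def test_nonpositive_factor_rejected(self):
        p = make_profile([1, 2], chl=[1.0, 0.4])
        with pytest.raises(ValidationError):
            apply_fluorescence_calibration(p, 0.0)


class TestNpq:
    def test_quenched_surface_filled_from_ml_max(self):
        p = make_profile([5, 10, 20, 30, 60], chl=[0.2, 0.3, 0.5, 0.5, 0.1])
        out = correct_npq(p, mld=40.0, is_daytime=True)
        assert np.allclose(out.chl, [0.5, 0.5, 0.5, 0.5, 0.1])

    def test_monotone_decreasing_profile_untouched(self):
        p = make_profile([5, 10, 20, 30], chl=[0.5, 0.4, 0.3, 0.2])
        out = correct_npq(p, mld=40.0, is_daytime=True)
        assert np.array_equal(out.chl, p.chl)

    def test_night_identity(self):
        p = make_profile([5, 10, 20], chl=[0.2, 0.3, 0.5])
        out = correct_npq(p, mld=40.0, is_daytime=False)
        assert np.array_equal(out.chl, p.chl)

    def test_missing_mld_skips_with_log(self):
        p = make_profile([5, 10, 20], chl=[0.2, 0.3, 0.5])
        out = correct_npq(p, mld=None)
        assert np.array_equal(out.chl, p.chl)
        assert any(e["event"] == "npq_skipped" for e in out.provenance)

    def test_never_decreases_chl(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            z = np.sort(rng.uniform(1, 200, 30))
            z += np.arange(30) * 1e-6  # strictly increasing
            p = make_profile(z, chl=rng.uniform(0, 1, 30))
            out = correct_npq(p, mld=float(rng.uniform(10, 150)))
            assert np.all(out.chl >= p.chl - 1e-15)


@pytest.mark.parametrize("do_in,factor,expected",
                         [(100.0, 1.06, 106.0),
                          (100.0, 1.0, 100.0),
                          (200.0, 1.06, 212.0)])
def test_oxygen_gain(do_in, factor, expected):
    p = make_profile([1, 2], do=[do_in, do_in])
    assert np.allclose(correct_oxygen(p, factor).do, expected)


# --------------------------------------------------------- derived scalars

class TestEuphoticDepth:
    @pytest.mark.parametrize("kd", [0.1, 0.04605])
    def test_exponential_closed_form(self, kd):
        z = np.arange(0.0, 301.0, 1.0)
        p = make_profile(z, par=1000.0 * np.exp(-kd * z))
        assert euphotic_depth(p) == pytest.approx(math.log(100) / kd, abs=0.05)

    def test_constant_par_flags_below_profile(self):
        p = make_profile([0, 10, 20], par=[500.0, 500.0, 500.0])
        with pytest.raises(ProcessingError) as e:
            euphotic_depth(p)
        assert e.value.code == "zeu_below_profile"

    def test_nonpositive_surface_par_rejected(self):
        p = make_profile([0, 10], par=[0.0, 0.0])
        with pytest.raises(ValidationError):
            euphotic_depth(p)


@pytest.mark.parametrize("zeu,expected", [(46.0, 10.0), (4.6, 1.0), (92.0, 20.0)])
def test_first_optical_depth(zeu, expected):
    assert first_optical_depth(zeu) == pytest.approx(expected)


def test_first_optical_depth_rejects_nonpositive():
    with pytest.raises(ValidationError):
        first_optical_depth(0.0)


class TestSurfaceChl:
    def test_constant_field(self):
        z = np.arange(0.0, 51.0, 1.0)
        p = make_profile(z, chl=np.full_like(z, 0.3))
        assert surface_chl(p, 10.0) == pytest.approx(0.3)

    def test_linear_ramp_trapezoid(self):
        p = make_profile([0.0, 20.0], chl=[0.4, 0.0])
        assert surface_chl(p, 10.0) == pytest.approx(0.3)

    def test_single_sample_degenerate_mean(self):
        p = make_profile([5.0], chl=[0.7])
        assert surface_chl(p, 10.0) == pytest.approx(0.7)

    def test_no_samples_above_fod(self):
        p = make_profile([50.0, 60.0], chl=[0.1, 0.1])
        with pytest.raises(ProcessingError) as e:
            surface_chl(p, 10.0)
        assert e.value.code == "no_surface_samples"


class TestIntegratedChl:
    def test_rectangle(self):
        z = np.arange(0.0, 61.0, 1.0)
        p = make_profile(z, chl=np.full_like(z, 0.2))
        assert integrated_chl(p, 0.0, 50.0) == pytest.approx(10.0)

    def test_gaussian_scm_matches_analytic(self):
        z = np.arange(0.0, 201.0, 1.0)
        a, z0, sig = 0.35, 90.0, 15.0
        p = make_profile(z, chl=a * np.exp(-((z - z0) ** 2) / (2 * sig**2)))
        analytic = a * sig * math.sqrt(2 * math.pi)
        assert integrated_chl(p, 0.0, 200.0) == pytest.approx(analytic, rel=5e-3)

    def test_zero_field_deep_band(self):
        z = np.arange(0.0, 201.0, 1.0)
        p = make_profile(z, chl=np.where(z < 100, 0.5, 0.0))
        # integrand is 0 strictly below 100 m; the boundary trapezoid at
        # exactly 100 m carries the interpolated edge value only
        assert integrated_chl(p, 101.0, 200.0) == pytest.approx(0.0)

    def test_too_shallow_profile(self):
        p = make_profile([0, 50], chl=[0.1, 0.1])
        with pytest.raises(ProcessingError) as e:
            integrated_chl(p, 0.0, 100.0)
        assert e.value.code == "profile_too_shallow"

    def test_additive_over_adjacent_intervals(self, clean_world):
        _, profiles, _, _ = clean_world
        p = profiles[10]
        whole = integrated_chl(p, 0.0, 300.0)
        parts = integrated_chl(p, 0.0, 100.0) + integrated_chl(p, 100.0, 300.0)
        assert whole == pytest.approx(parts, abs=1e-10)


class TestMld:
    def test_sharp_two_layer_step(self):
        z = np.arange(1.0, 201.0, 1.0)
        rho = np.where(z <= 50, 1025.0, 1026.0)
        res = mld(make_profile(z, density=rho))
        assert abs(res.depth - 50.0) <= 1.0
        assert res.flag is None

    def test_linear_density_hand_solved(self):
        z = np.arange(0.0, 201.0, 1.0)
        res = mld(make_profile(z, density=1025.0 + 0.001 * z))
        assert res.depth == pytest.approx(40.0, abs=1e-9)

    def test_homogeneous_returns_bottom_with_flag(self):
        z = np.arange(1.0, 201.0, 1.0)
        res = mld(make_profile(z, density=np.full_like(z, 1025.0)))
        assert res.depth == pytest.approx(200.0)
        assert res.flag == "mld_at_profile_bottom"

    def test_no_reference_sample(self):
        p = make_profile([50, 100], density=[1025.0, 1026.0])
        with pytest.raises(ProcessingError) as e:
            mld(p)
        assert e.value.code == "no_reference_sample"

    def test_grid_refinement_invariance(self):
        # piecewise-linear density, coarse vs fine grid
        def profile(step):
            z = np.arange(0.0, 200.0 + step, step)
            rho = np.where(z <= 60, 1025.0, 1025.0 + 0.02 * (z - 60))
            return make_profile(z, density=rho)
        coarse = mld(profile(5.0)).depth
        fine = mld(profile(0.5)).depth
        assert abs(coarse - fine) <= 0.5


class TestBvf:
    def test_linear_stratification_closed_form(self):
        z = np.arange(0.0, 101.0, 1.0)
        rho = 1025.0 + 0.01 * z
        res = bvf_profile(make_profile(z, density=rho))
        expected = GRAVITY / 1025.5 * 0.01
        assert np.allclose(res.n2, expected, rtol=0.01)
        assert not res.unstable

    def test_homogeneous_zero(self):
        z = np.arange(0.0, 101.0, 1.0)
        res = bvf_profile(make_profile(z, density=np.full_like(z, 1025.0)))
        assert np.allclose(res.n2, 0.0)

    def test_inversion_flagged(self):
        res = bvf_profile(make_profile([0, 50], density=[1026.0, 1025.0]))
        assert np.all(res.n2 < 0) and res.unstable

    def test_sigma_convention_resolved(self):
        z = np.arange(0.0, 101.0, 1.0)
        full = bvf_profile(make_profile(z, density=1025.0 + 0.01 * z))
        sigma = bvf_profile(make_profile(z, density=25.0 + 0.01 * z))
        assert np.allclose(full.n2, sigma.n2, rtol=1e-6)


# ------------------------------------------------------------- derive_all

class TestDeriveAll:
    def test_planted_values_recovered(self, clean_scenario, clean_world,
                                      clean_corrections):
        _, profiles, truth, _ = clean_world
        d = derive_all(profiles[0], clean_corrections)
        assert d.zeu == pytest.approx(truth.true_zeu_by_day[0], abs=1.0)
        assert d.mld == pytest.approx(truth.true_mld_by_day[0], abs=1.0)
        assert d.fod == d.zeu / 4.6
        assert d.chl_surf == pytest.approx(truth.true_surface_chl_by_day[0],
                                           abs=1e-9)

    def test_missing_par_leaves_optical_fields_absent(self, clean_world,
                                                      clean_corrections):
        _, profiles, _, _ = clean_world
        import dataclasses
        p = dataclasses.replace(profiles[0], par=None, provenance=[])
        d = derive_all(p, clean_corrections)
        assert d.zeu is None and d.fod is None and d.chl_surf is None
        assert d.mld is not None
        assert d.flags["zeu"] == "no_par"

    def test_corrections_applied_exactly_once(self, clean_world,
                                              clean_corrections):
        _, profiles, _, _ = clean_world
        d1 = derive_all(profiles[5], clean_corrections)
        d2 = derive_all(profiles[5], clean_corrections)
        assert d1.chl_surf == d2.chl_surf and d1.zeu == d2.zeu
        offsets = [e for e in d1.provenance if e["event"] == "dark_offset"]
        assert len(offsets) == 1


def test_fod_equals_zeu_over_4p6(clean_world, clean_corrections):
    _, profiles, _, _ = clean_world
    for p in profiles[::60]:
        d = derive_all(p, clean_corrections)
        assert d.fod == d.zeu / 4.6


# -------------------------------------------------------------------- I/O

def test_csv_roundtrip(tmp_path, clean_world):
    _, profiles, _, _ = clean_world
    path = tmp_path / "profiles.csv"
    write_profiles_csv(profiles[:3], path)
    back = read_profiles_csv(path)
    assert len(back) == 3
    for a, b in zip(profiles[:3], back):
        assert a.timestamp == b.timestamp
        assert np.array_equal(a.depth, b.depth)
        assert np.array_equal(a.chl, b.chl)
        assert np.array_equal(a.density, b.density)


def test_netcdf_roundtrip(tmp_path, clean_world):
    _, profiles, _, _ = clean_world
    path = tmp_path / "profiles.nc"
    write_profiles_netcdf(profiles[:3], path)
    back = read_profiles_netcdf(path)
    assert len(back) == 3
    for a, b in zip(profiles[:3], back):
        assert a.timestamp == b.timestamp
        assert np.allclose(a.chl, b.chl)
        assert np.allclose(a.par, b.par)
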
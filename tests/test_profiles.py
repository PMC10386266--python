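"""Partitioning-profile construction, plateau reading and release conversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biphasepk import (
    AbsorptionInput,
    PartitioningProfile,
    ProfileDialect,
    ProfileError,
    ShapeSpec,
    estimate_plateau,
    parametric_profile,
    read_profile,
    release_function,
    write_profile,
)


class TestReadWrite:
    def test_percent_and_minutes_conversion(self, tmp_path):
        f = tmp_path / "p.csv"
        f.write_text("# run 1\ntime_min,organic_pct\n0,0\n30,0\n60,10\n270,59\n")
        prof = read_profile(f)
        np.testing.assert_allclose(prof.times, [0, 30, 60, 270])
        np.testing.assert_allclose(prof.organic_fraction, [0, 0, 0.10, 0.59])

    def test_hours_dialect(self, tmp_path):
        f = tmp_path / "p.csv"
        f.write_text("t_h,org\n0,0\n0.5,0\n4.5,59\n")
        prof = read_profile(f, ProfileDialect(time_col="t_h", organic_col="org",
                                              time_unit="h"))
        np.testing.assert_allclose(prof.times, [0, 30, 270])

    def test_overshoot_rejected(self, tmp_path):
        f = tmp_path / "p.csv"
        f.write_text("time_min,organic_pct\n0,0\n30,112\n")
        with pytest.raises(ProfileError, match="exceeds"):
            read_profile(f)

    def test_duplicate_time_names_row(self, tmp_path):
        f = tmp_path / "p.csv"
        f.write_text("time_min,organic_pct\n0,0\n30,5\n30,6\n")
        with pytest.raises(ProfileError, match="duplicate"):
            read_profile(f)

    def test_missing_column(self, tmp_path):
        f = tmp_path / "p.csv"
        f.write_text("time_min,aqueous_pct\n0,0\n30,5\n")
        with pytest.raises(ProfileError, match="organic"):
            read_profile(f)

    def test_round_trip_six_significant_digits(self, tmp_path):
        prof = parametric_profile(ShapeSpec("sigmoidal", 0.8))
        out = tmp_path / "w.csv"
        write_profile(prof, out)
        back = read_profile(out)
        np.testing.assert_allclose(back.times, prof.times, rtol=1e-6)
        np.testing.assert_allclose(back.organic_fraction, prof.organic_fraction,
                                   rtol=1e-5, atol=1e-7)


class TestParametricShapes:
    def test_zero_order_linear_ramp_value(self):
        spec = ShapeSpec("zero_order", 0.59, t_lag=30, t_ramp_end=270)
        prof = parametric_profile(spec, grid=np.arange(0, 271, 5.0))
        i = np.where(prof.times == 150.0)[0][0]
        assert prof.organic_fraction[i] == pytest.approx(0.295, abs=1e-12)

    def test_first_order_fast_rate_approaches_step(self):
        spec = ShapeSpec("first_order", 0.45, k=10.0)
        prof = parametric_profile(spec, grid=np.array([0.0, 30.0, 31.0, 270.0]))
        assert prof.organic_fraction[1] == 0.0
        assert prof.organic_fraction[2] == pytest.approx(0.45, abs=1e-4)

    def test_zero_plateau_gives_zero_profile(self):
        for shape in ("zero_order", "first_order", "square_root", "sigmoidal"):
            prof = parametric_profile(ShapeSpec(shape, 0.0))
            assert np.all(prof.organic_fraction == 0.0)

    def test_gastric_lag_zero(self):
        prof = parametric_profile(ShapeSpec("square_root", 0.35))
        assert np.all(prof.organic_fraction[prof.times <= 30.0] == 0.0)

    def test_deterministic(self):
        a = parametric_profile(ShapeSpec("sigmoidal", 0.8))
        b = parametric_profile(ShapeSpec("sigmoidal", 0.8))
        assert np.array_equal(a.organic_fraction, b.organic_fraction)

    def test_grid_shorter_than_lag_errors(self):
        with pytest.raises(ProfileError):
            parametric_profile(ShapeSpec("zero_order", 0.5, t_lag=30),
                               grid=np.array([0.0, 10.0, 20.0]))


class TestPlateau:
    def test_zero_order_plateau(self):
        prof = parametric_profile(ShapeSpec("zero_order", 0.59, t_ramp_end=200.0))
        est = estimate_plateau(prof)
        assert est.value == pytest.approx(0.59, abs=1e-12)
        assert est.stable

    def test_zero_profile(self):
        prof = parametric_profile(ShapeSpec("zero_order", 0.0))
        est = estimate_plateau(prof)
        assert est.value == 0.0 and est.stable

    def test_sigmoidal_plateau_from_closed_form(self):
        spec = ShapeSpec("sigmoidal", 0.80, t_mid=120.0)
        prof = parametric_profile(spec, grid=np.arange(0, 271, 5.0))
        # independent closed-form evaluation over the final 60-min window
        tw = np.arange(210.0, 271.0, 5.0) - spec.t_lag
        expected = np.mean(0.80 * tw ** spec.hill
                           / (spec.t_mid ** spec.hill + tw ** spec.hill))
        est = estimate_plateau(prof)
        assert est.value == pytest.approx(expected, abs=1e-12)
        assert est.value == pytest.approx(0.80, abs=0.01)
        assert est.stable

    def test_first_order_recovery_within_001(self):
        spec = ShapeSpec("first_order", 0.45, k=0.025)
        est = estimate_plateau(parametric_profile(spec))
        assert est.value == pytest.approx(0.45, abs=0.01)

    def test_short_profile_errors(self):
        prof = PartitioningProfile(times=[0.0, 30.0], organic_fraction=[0, 0.1])
        with pytest.raises(ProfileError):
            estimate_plateau(prof, window=60.0)


class TestReleaseFunction:
    def test_running_maximum_envelope(self):
        prof = PartitioningProfile(times=[0, 60, 120, 180],
                                   organic_fraction=[0, 0.30, 0.28, 0.50])
        rel = release_function(prof)
        np.testing.assert_allclose(rel.release, [0, 0.30, 0.30, 0.50])

    def test_step_profile_holds_plateau(self):
        prof = PartitioningProfile(times=[0, 29.999, 30, 270],
                                   organic_fraction=[0, 0, 1.0, 1.0])
        rel = release_function(prof)
        assert rel(29.0) == pytest.approx(0.0, abs=1e-4)
        assert rel(30.0) == 1.0
        assert rel(600.0) == 1.0

    def test_plateau_hold_beyond_last_knot(self):
        prof = parametric_profile(ShapeSpec("zero_order", 0.59))
        rel = release_function(prof)
        assert rel(600.0) == pytest.approx(0.59, abs=1e-12)

    def test_overshoot_clamped_to_one(self):
        prof = PartitioningProfile(times=[0, 100, 200],
                                   organic_fraction=[0, 0.9, 1.04])
        rel = release_function(prof)
        assert rel.f_inf == 1.0

    def test_normalize_to_plateau(self):
        prof = parametric_profile(ShapeSpec("zero_order", 0.4))
        rel = release_function(prof, normalize="to_plateau")
        assert rel.f_inf == pytest.approx(1.0)

    def test_zero_profile_flagged(self):
        prof = parametric_profile(ShapeSpec("zero_order", 0.0))
        rel = release_function(prof)
        assert rel.is_zero

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0),
                    min_size=2, max_size=29))
    def test_envelope_monotone_bounded_exact(self, tail_values):
        """Invariant: output non-decreasing, in [0,1], envelope-exact at knots."""
        values = [0.0] + tail_values  # assay profiles start empty
        times = np.arange(len(values), dtype=float) * 10.0
        prof = PartitioningProfile(times=times, organic_fraction=values)
        rel = release_function(prof)
        assert np.all(np.diff(rel.release) >= -1e-15)
        assert rel.release[0] == 0.0 and rel.release[-1] <= 1.0
        env = np.maximum.accumulate(np.clip(np.asarray(values), 0, 1))
        # knots after the implicit t=0 anchor reproduce the envelope exactly
        np.testing.assert_allclose(rel(times[1:]), env[1:], atol=1e-15)


class TestAbsorptionInputValidation:
    def test_decreasing_release_rejected(self):
        with pytest.raises(ProfileError):
            AbsorptionInput(times_min=[0, 10, 20], release=[0, 0.5, 0.4])

    def test_nonzero_origin_rejected(self):
        with pytest.raises(ProfileError):
            AbsorptionInput(times_min=[0, 10], release=[0.2, 0.5])
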
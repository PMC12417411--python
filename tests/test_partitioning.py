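"""Differential-O2 partitioning, recycling ratios and day respiration."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import photoresp as pr
from photoresp.partitioning import (MissingCurveClassError, build_respiration_series,
                                    photorespiration_rate, rd_in_light,
                                    recovery_inhibition)


@pytest.mark.parametrize("pn2, pn21, expected", [
    (-2.036, -6.548, 4.512),   # wheat at zero CO2: R_L - R_d
    (-1.893, -6.334, 4.441),   # bean at zero CO2
    (3.7, 3.7, 0.0),           # identical fluxes
])
def test_photorespiration_rate(pn2, pn21, expected):
    assert photorespiration_rate(pn2, pn21) == pytest.approx(expected, abs=1e-12)


def test_photorespiration_rate_vectorized_and_unclamped():
    out = photorespiration_rate(np.array([-2.0, -6.6]), np.array([-6.5, -6.5]))
    np.testing.assert_allclose(out, [4.5, -0.1])  # noise can drive it negative


class TestRecoveryInhibition:
    def test_wheat_ratio_at_lowest_ca(self):
        """Recovery ratio at zero CO2 from the wheat profile: ~60 %."""
        cfg = pr.default_config()
        wheat = pr.true_profiles(cfg)["wheat"]
        prof = recovery_inhibition(list(zip(wheat["ca"], wheat["rp"])), "wheat")
        assert prof.rp_max == pytest.approx(12.307)
        assert prof.ca_at_peak == 600.0
        assert prof.ratio[0] == pytest.approx((12.307 - 4.923) / 12.307, abs=1e-12)
        assert prof.ratio[0] * 100 == pytest.approx(60.0, abs=0.01)

    def test_constant_series_all_zero_ratios(self):
        prof = recovery_inhibition([(0, 5.0), (100, 5.0), (400, 5.0)])
        np.testing.assert_allclose(prof.ratio, 0.0)
        assert prof.ca_at_peak == 0.0  # ties break toward the lowest C_a

    def test_fully_suppressed_point_has_ratio_one(self):
        prof = recovery_inhibition([(0, 4.0), (300, 8.0), (1200, 0.0)])
        assert prof.ratio[-1] == pytest.approx(1.0)

    def test_ratio_bounded_zero_at_peak(self):
        prof = recovery_inhibition([(0, 4.9), (600, 12.3), (1200, 5.0)])
        assert np.all((prof.ratio >= 0) & (prof.ratio <= 1))
        assert prof.ratio[1] == 0.0

    def test_phase_labels_partition_grid_around_peak(self):
        prof = recovery_inhibition([(0, 4.0), (200, 9.0), (600, 12.0),
                                    (800, 10.0), (1200, 5.0)])
        assert prof.phase == ["recovery"] * 3 + ["inhibition"] * 2

    @pytest.mark.parametrize("bad", [
        [(0, 1.0), (100, 2.0)],          # too short
        [(0, 0.0), (100, 0.0), (200, 0.0)],  # all-zero profile
        [(0, -1.0), (100, 2.0), (200, 3.0)],  # negative flux
    ])
    def test_invalid_series_rejected(self, bad):
        with pytest.raises(ValueError):
            recovery_inhibition(bad)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.01, 20.0), min_size=3, max_size=12))
    def test_ratio_antimonotone_in_rp(self, rps):
        """Larger photorespiration at a level means a smaller ratio there."""
        ca = np.arange(len(rps), dtype=float) * 100
        prof = recovery_inhibition(list(zip(ca, rps)))
        order_rp = np.argsort(rps)
        assert np.all(np.diff(np.asarray(prof.ratio)[order_rp]) <= 1e-12)


class TestRdInLight:
    @pytest.mark.parametrize("rn, ratio, expected", [
        (3.862, 0.0, 3.862),
        (3.862, 1.0, 0.0),
        (3.862, 0.600, 3.862 * 0.4),  # = 1.5448
    ])
    def test_pointwise(self, rn, ratio, expected):
        assert rd_in_light(rn, ratio) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("rn, ratio", [(3.0, -0.1), (3.0, 1.1), (-1.0, 0.5)])
    def test_domain_errors(self, rn, ratio):
        with pytest.raises(ValueError):
            rd_in_light(rn, ratio)

    @settings(derandomize=True, max_examples=50)
    @given(rn=st.floats(0.0, 10.0), ratio=st.floats(0.0, 1.0))
    def test_never_exceeds_dark_rate(self, rn, ratio):
        assert rd_in_light(rn, ratio) <= rn + 1e-12


class TestBuildRespirationSeries:
    def test_noiseless_round_trip_matches_generator_truth(self, noiseless_config,
                                                          noiseless_curves):
        """The pipeline inverts the generator exactly on noiseless data."""
        series = build_respiration_series(noiseless_curves)
        truth = pr.true_profiles(noiseless_config)
        for sp, s in series.items():
            t = truth[sp]
            np.testing.assert_allclose(s.rp_mean, t["rp"], atol=1e-10)
            np.testing.assert_allclose(s.rd_mean, t["rd"], atol=1e-10)
            np.testing.assert_allclose(s.rl_mean, t["rp"] + t["rd"], atol=1e-10)
            for o2 in (0.21, 0.02):
                np.testing.assert_allclose(s.rn_mean[o2], t["rn"], atol=1e-10)

    def test_rl_closure_at_zero_ca(self, noiseless_curves):
        """At C_a = 0 the partition satisfies R_p = R_L - R_d exactly."""
        for s in build_respiration_series(noiseless_curves).values():
            assert s.rp_mean[0] == pytest.approx(s.rl_mean[0] - s.rd_mean[0], abs=1e-12)

    def test_single_replicate_has_nan_sd(self, noiseless_config):
        cfg = dataclasses.replace(noiseless_config, n_replicates=1)
        series = build_respiration_series(pr.simulate_dataset(cfg))
        for s in series.values():
            assert np.isnan(s.rp_sd).all() and np.isnan(s.rd_sd).all()
            assert np.isfinite(s.rp_mean).all()

    def test_missing_dark_curves_named_in_error(self, noiseless_curves):
        without_dark = [c for c in noiseless_curves if c.par > 0]
        with pytest.raises(MissingCurveClassError, match=r"dark \(PAR 0"):
            build_respiration_series(without_dark)

    def test_missing_low_o2_light_named_in_error(self, noiseless_curves):
        kept = [c for c in noiseless_curves
                if not (c.par > 0 and abs(c.o2_fraction - 0.02) < 1e-9)]
        with pytest.raises(MissingCurveClassError, match=r"light \(PAR > 0, 2% O2\)"):
            build_respiration_series(kept)

    def test_negative_rp_flagged_not_clamped(self):
        # handcrafted replicate where noise pushed P_n(2%) below P_n(21%)
        # at one level: R_p there is negative, flagged, and kept in the mean
        ca = np.array([0.0, 100.0, 400.0, 800.0, 1200.0])
        mk = lambda o2, par, pn: pr.GasExchangeCurve("x", 1, o2, par, ca,
                                                     np.asarray(pn, float))
        curves = [
            mk(0.21, 2000, [-6.5, 2.0, 10.0, 14.0, 15.0]),
            mk(0.02, 2000, [-2.0, 6.0, 9.5, 18.0, 19.0]),  # 9.5 < 10.0 at 400
            mk(0.21, 0, [-3.9, -3.4, -2.8, -2.0, -1.5]),
            mk(0.02, 0, [-3.9, -3.4, -2.8, -2.0, -1.5]),
        ]
        (s,) = build_respiration_series(curves).values()
        assert s.qc_negative_rp == [(1, 400.0)]
        assert s.rp_mean[2] == pytest.approx(-0.5)

    def test_alternate_rn_o2_level(self, noiseless_curves):
        s21 = build_respiration_series(noiseless_curves, rn_o2=0.21)
        s2 = build_respiration_series(noiseless_curves, rn_o2=0.02)
        for sp in s21:
            np.testing.assert_allclose(s21[sp].rd_mean, s2[sp].rd_mean, atol=1e-10)
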
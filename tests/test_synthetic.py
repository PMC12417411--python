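"""The synthetic gas-exchange generator and its self-consistency."""

import dataclasses

import numpy as np
import pytest

import photoresp as pr
from photoresp.partitioning import build_respiration_series, photorespiration_rate
from photoresp.synthetic import (SimulationConfig, SpeciesProfile, config_from_dict,
                                 config_to_dict, default_config, simulate_dataset,
                                 true_profiles)


class TestTrueProfiles:
    def test_wheat_rp_anchors(self):
        """Default wheat R_p hits its configured endpoints: 4.923 at zero
        CO2 and the 12.307 maximum at 600 μmol mol⁻¹."""
        t = true_profiles(default_config())["wheat"]
        i600 = list(t["ca"]).index(600.0)
        assert t["rp"][0] == pytest.approx(4.923, abs=1e-12)
        assert t["rp"][i600] == pytest.approx(12.307, abs=1e-12)
        assert np.argmax(t["rp"]) == i600

    def test_bean_rp_anchors(self):
        t = true_profiles(default_config())["bean"]
        assert t["rp"][0] == pytest.approx(4.686, abs=1e-12)
        assert t["rp"][list(t["ca"]).index(1000.0)] == pytest.approx(11.673, abs=1e-12)

    def test_rp_quadratic_is_vertex_symmetric(self):
        cfg = dataclasses.replace(default_config(),
                                  ca_levels=(0.0, 400.0, 600.0, 800.0, 1200.0))
        t = true_profiles(cfg)["wheat"]  # peak at 600; 400/800 are ±200 around it
        assert t["rp"][1] == pytest.approx(t["rp"][3], abs=1e-12)

    def test_rn_linear_between_endpoints(self):
        t = true_profiles(default_config())["wheat"]
        assert t["rn"][0] == pytest.approx(3.862)
        assert t["rn"][-1] == pytest.approx(1.453)
        assert np.allclose(np.diff(t["rn"]) / np.diff(t["ca"]),
                           (1.453 - 3.862) / 1200.0)

    def test_rd_satisfies_recycling_relation(self):
        """Generator R_d is R_n·(1 − ratio): self-consistent with the
        partitioning scheme, unimodal, peaking below the R_p peak."""
        t = true_profiles(default_config())["wheat"]
        np.testing.assert_allclose(t["rd"], t["rn"] * (1 - t["ratio"]), atol=1e-14)
        i_peak = int(np.argmax(t["rd"]))
        assert 0 < i_peak < len(t["ca"]) - 1
        assert t["ca"][i_peak] < 600.0

    @pytest.mark.parametrize("bad", [
        dict(rp_min=-1.0), dict(rp_min=13.0),       # bounds violated
        dict(rp_peak_ca=1500.0),                    # peak outside grid
        dict(rn_at_max_ca=-0.5),                    # negative dark respiration
    ])
    def test_invalid_profiles_rejected(self, bad):
        fields = dict(name="x", rp_min=4.9, rp_max=12.3, rp_peak_ca=600.0,
                      rn_at_zero=3.9, rn_at_max_ca=1.5,
                      gross=pr.ModRectHyperbolaParams(0.08, 2e-4, 1.5e-3, 0.0))
        fields.update(bad)
        with pytest.raises(ValueError):
            SimulationConfig(species=(SpeciesProfile(**fields),))

    def test_gross_with_respiration_term_rejected(self):
        with pytest.raises(ValueError, match="no respiration"):
            SpeciesProfile(name="x", rp_min=4.9, rp_max=12.3, rp_peak_ca=600.0,
                           rn_at_zero=3.9, rn_at_max_ca=1.5,
                           gross=pr.ModRectHyperbolaParams(0.08, 2e-4, 1.5e-3, rp=5.0)
                           ).validate(pr.DEFAULT_CA_LEVELS)


class TestSimulateDataset:
    def test_same_seed_bit_identical(self):
        cfg = default_config(seed=4)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        assert len(a) == len(b) == 2 * 5 * 4  # species x replicates x classes
        for ca_, cb in zip(a, b):
            assert np.array_equal(ca_.pn, cb.pn)

    def test_different_seed_differs(self):
        cfg = default_config(seed=4)
        a, b = simulate_dataset(cfg), simulate_dataset(cfg, seed=5)
        assert any(not np.array_equal(x.pn, y.pn) for x, y in zip(a, b))

    def test_noiseless_differential_recovers_rp_exactly(self, noiseless_config):
        truth = true_profiles(noiseless_config)
        curves = simulate_dataset(noiseless_config)
        by = {(c.species, c.replicate, c.o2_fraction, c.par): c for c in curves}
        for sp in truth:
            rp = photorespiration_rate(by[(sp, 1, 0.02, 2000.0)].pn,
                                       by[(sp, 1, 0.21, 2000.0)].pn)
            np.testing.assert_allclose(rp, truth[sp]["rp"], atol=1e-12)

    def test_pn21_at_zero_ca_is_total_respiration(self, noiseless_config):
        """At zero CO2 under light the 21 % O2 flux is −(R_p + R_d)."""
        truth = true_profiles(noiseless_config)
        for c in simulate_dataset(noiseless_config):
            if c.par > 0 and abs(c.o2_fraction - 0.21) < 1e-9:
                t = truth[c.species]
                assert c.pn[0] == pytest.approx(-(t["rp"][0] + t["rd"][0]), abs=1e-12)

    def test_ci_is_fixed_fraction_of_ca(self, noiseless_config):
        for c in simulate_dataset(noiseless_config):
            np.testing.assert_allclose(c.ci, 0.75 * c.ca, atol=1e-12)

    def test_fvcb_gross_generator_round_trips(self):
        """Pipeline closure also holds with a biochemical gross shape."""
        sp = SpeciesProfile(name="x", rp_min=4.9, rp_max=12.3, rp_peak_ca=600.0,
                            rn_at_zero=3.9, rn_at_max_ca=1.5,
                            gross=pr.FvCBParams(vcmax=90, j=140, tpu=11, rd=0.0))
        cfg = SimulationConfig(species=(sp,), noise_sd=0.0, seed=1)
        series = build_respiration_series(simulate_dataset(cfg))["x"]
        truth = true_profiles(cfg)["x"]
        np.testing.assert_allclose(series.rp_mean, truth["rp"], atol=1e-10)
        np.testing.assert_allclose(series.rd_mean, truth["rd"], atol=1e-10)

    def test_rp_means_track_truth_across_seeds(self):
        """With sd 0.3 and n = 5, the recovered R_p means stay within
        3·(0.3/√5) of truth at ≥95 % of grid points over 100 seeds."""
        cfg = default_config()
        truth = true_profiles(cfg)
        tol = 3 * 0.3 / np.sqrt(5)
        inside = total = 0
        for seed in range(100):
            series = build_respiration_series(simulate_dataset(cfg, seed=seed))
            for sp, s in series.items():
                err = np.abs(s.rp_mean - truth[sp]["rp"])
                inside += int((err <= tol).sum())
                total += err.size
        assert inside / total >= 0.95


def test_config_dict_round_trip():
    cfg = default_config(seed=9)
    assert config_from_dict(config_to_dict(cfg)) == cfg


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(ci_ratio=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(noise_sd=-0.1)
    with pytest.raises(ValueError):
        SimulationConfig(n_replicates=0)
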
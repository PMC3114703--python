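"""Generator checks: closed forms, conservation, noise behaviour."""

import math

import numpy as np
import pytest

from microloop import (InputError, ParameterError, SimulationParams,
                       mean_trajectory, simulate_dilution_assay,
                       simulate_gel, simulate_lane_bands,
                       simulate_microcosm)
from microloop.simulate import enrich_for_stimulation


def zero_rate_params(**overrides):
    base = dict(mu_b=0.0, delta_v=0.0, graze=0.0, enrich=0.0,
                autotroph_boost=0.0, decay_v=0.0, cv_noise=0.0,
                bacteria0=1.0e6)
    base.update(overrides)
    return SimulationParams(**base)


class TestMicrocosmDynamics:
    def test_zero_rates_keep_bacteria_constant(self):
        series = simulate_microcosm(zero_rate_params(), "V", [0, 48, 96])
        np.testing.assert_allclose(series["bacteria"].counts, 1.0e6)

    def test_pure_growth_matches_closed_form_exponential(self):
        params = zero_rate_params(mu_b=0.5)
        series = simulate_microcosm(params, "V", [0, 48, 96])["bacteria"]
        expected = 1.0e6 * np.exp(0.5 * np.array([0, 2, 4]))
        np.testing.assert_allclose(series.counts, expected, rtol=1e-9)

    def test_viruses_conserved_as_burst_size_times_lysed_cells(self):
        """With no viral decay, viruses gained = burst × cells lysed.

        Lysed cells come from an independent fine-step trapezoid
        integration of delta_v·B(t) over the closed-form bacterial
        trajectory.
        """
        params = zero_rate_params(mu_b=0.3, delta_v=0.4, viruses0=5.0e7)
        traj = mean_trajectory(params, "V", [0, 96])
        gained = traj[-1, 1] - traj[0, 1]
        net = params.net_bacterial_rate("V")  # 0.3 - 0.4
        t = np.linspace(0, 4, 40001)  # days
        b = params.bacteria0 * np.exp(net * t)
        lysed = np.trapezoid(params.delta_v * b, t)
        assert gained == pytest.approx(27.0 * lysed, rel=1e-3)

    def test_treatment_v_suppresses_grazing_and_enrichment(self):
        params = zero_rate_params(mu_b=0.5, graze=0.3, enrich=0.4)
        v = simulate_microcosm(params, "V", [0, 96])["bacteria"]
        # V net rate is mu_b alone: no grazing, no enrichment boost
        assert v.counts[-1] == pytest.approx(1.0e6 * math.exp(0.5 * 4),
                                             rel=1e-9)

    def test_increasing_grazing_decreases_final_bacteria(self):
        finals = []
        for graze in (0.0, 0.2, 0.4):
            params = SimulationParams(mu_b=0.6, delta_v=0.1, graze=graze,
                                      enrich=0.0, autotroph_boost=0.0,
                                      cv_noise=0.05, seed=3)
            s = simulate_microcosm(params, "VF", [0, 96])["bacteria"]
            finals.append(s.counts[-1])
        assert finals[0] > finals[1] > finals[2]

    def test_identical_seeds_reproduce_identical_counts(self):
        params = SimulationParams(cv_noise=0.1, seed=11)
        a = simulate_microcosm(params, "VFA", [0, 48, 96], replicate=1)
        b = simulate_microcosm(params, "VFA", [0, 48, 96], replicate=1)
        for var in a:
            np.testing.assert_array_equal(a[var].counts, b[var].counts)

    def test_unsorted_times_rejected(self):
        with pytest.raises(InputError):
            simulate_microcosm(zero_rate_params(), "V", [0, 96, 48])

    def test_negative_rate_rejected(self):
        with pytest.raises(ParameterError):
            SimulationParams(mu_b=-0.1)


class TestDilutionAssaySimulator:
    def test_no_lysis_gives_flat_counts_and_zero_slope(self):
        params = zero_rate_params()
        assay = simulate_dilution_assay(
            params, {"bacteria": 1.0e6, "viruses": 3.0e7})
        assert assay.true_slope == 0.0
        assert np.ptp(assay.viral_counts) == 0.0

    def test_true_slope_closed_form(self):
        params = zero_rate_params(delta_v=0.4)
        assay = simulate_dilution_assay(
            params, {"bacteria": 3.0e6, "viruses": 3.0e7},
            dilution_factor=1.0 / 3.0)
        # b = 1.0e6 after dilution; slope = 27 * 0.4 * 1e6 / 24
        assert assay.b == pytest.approx(1.0e6)
        assert assay.true_slope == pytest.approx(4.5e5)

    def test_noisy_slope_estimate_is_unbiased(self):
        """Monte-Carlo: least-squares slope within 2 SE of the truth."""
        from microloop import fit_viral_production
        params = zero_rate_params(delta_v=0.4, cv_noise=0.05)
        slopes = []
        for seed in range(100):
            assay = simulate_dilution_assay(
                params, {"bacteria": 3.0e6, "viruses": 3.0e7}, seed=seed)
            slopes.append(fit_viral_production(assay).slope)
        slopes = np.array(slopes)
        se = slopes.std(ddof=1) / math.sqrt(slopes.size)
        assert abs(slopes.mean() - 4.5e5) < 2 * se

    def test_dilution_factor_bounds(self):
        with pytest.raises(InputError):
            simulate_dilution_assay(zero_rate_params(),
                                    {"bacteria": 1e6, "viruses": 1e7},
                                    dilution_factor=1.5)


class TestGelSimulator:
    def test_identical_lanes_give_identical_bands(self):
        profile = np.full(10, 0.1)
        bm = simulate_gel({"A": profile, "B": profile}, position_jitter=0.0)
        np.testing.assert_array_equal(bm.intensity[0], bm.intensity[1])

    def test_detection_floor_drops_faint_phylotype(self):
        profiles = {"A": [0.999, 0.001]}
        bm = simulate_gel(profiles, detection_floor=0.004)
        assert bm.positions.size == 1

    def test_unnormalized_profile_rejected(self):
        with pytest.raises(InputError):
            simulate_gel({"A": [0.5, 0.4]})

    def test_jittered_lanes_keep_canonical_band_count(self):
        rng = np.random.default_rng(5)
        profiles = {f"L{i}": np.full(12, 1 / 12) for i in range(3)}
        raw = simulate_lane_bands(profiles, position_jitter=1.0, seed=9)
        assert all(len(bands) == 12 for bands in raw.values())


def test_enrichment_solver_hits_target_stimulation():
    """Net-rate increment reproduces an exact abundance stimulation."""
    r_v = 0.5
    r_t = enrich_for_stimulation(25.0, r_v, window_h=48.0)
    stim = 100 * (math.exp(r_t * 2) - math.exp(r_v * 2))
    assert stim == pytest.approx(25.0, abs=1e-9)
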
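"""Generator calibration, path simulation and trace rendering."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.linalg import expm

import gapekin as g
from gapekin.synthetic_data import EmissionModel, SaltRule, StatePath
from gapekin.trace_correction import CorrectionParams, compute_fret


class TestCalibration:
    def test_ed28_branching_fractions(self, ed28_rate_matrix):
        # hand-derived from flux balance pi_s/pi_mid = f_s * tau_s/tau_mid
        b = ed28_rate_matrix.branching
        assert b["high"] == pytest.approx(0.583129, abs=1e-4)
        assert b["low"] == pytest.approx(0.402491, abs=1e-4)
        assert b["high"] + b["low"] == pytest.approx(0.985, abs=1e-3)

    def test_exit_rates_match_dwell_times(self, ed28_rate_matrix):
        rates = ed28_rate_matrix.exit_rates()
        assert rates[0] == pytest.approx(1 / 100.25, rel=1e-12)  # high
        assert rates[2] == pytest.approx(1 / 42.48, rel=1e-12)  # low

    def test_stationary_matches_supplied_occupancies(self, ed28_rate_matrix):
        # independent oracle: long-time limit of the transition semigroup
        p_inf = expm(ed28_rate_matrix.generator * 1e6)
        for row in p_inf:
            np.testing.assert_allclose(row, [0.1183, 0.8471, 0.0346], atol=1e-3)
        np.testing.assert_allclose(
            ed28_rate_matrix.stationary_distribution(),
            [0.1183, 0.8471, 0.0346],
            atol=1e-3,
        )

    def test_two_state_symmetric(self):
        rm = g.calibrate_rate_matrix({"a": 10.0, "b": 10.0}, {"a": 0.5, "b": 0.5})
        assert rm.generator[0, 1] == pytest.approx(0.1)
        assert rm.generator[1, 0] == pytest.approx(0.1)

    def test_mid_centered_forbids_direct_high_low(self, ed28_rate_matrix):
        q = ed28_rate_matrix.generator
        assert q[0, 2] == 0.0 and q[2, 0] == 0.0

    def test_occupancy_sum_checked(self):
        with pytest.raises(ValueError, match="sum"):
            g.calibrate_rate_matrix(
                {"high": 100.0, "mid": 400.0, "low": 40.0},
                {"high": 0.3, "mid": 0.3, "low": 0.3},
            )

    def test_inconsistent_inputs_warn(self):
        # branching fractions sum to 15 for these inputs: warn, not fail
        with pytest.warns(UserWarning, match="branching"):
            g.calibrate_rate_matrix(
                {"high": 10.0, "mid": 100.0, "low": 10.0},
                {"high": 0.3, "mid": 0.4, "low": 0.3},
            )


class TestStatePath:
    def test_degenerate_generator_single_segment(self):
        rm = g.RateMatrix(states=("only",), generator=np.zeros((1, 1)))
        path = g.simulate_state_path(rm, 50.0, seed=0)
        assert path.states == ("only",)
        assert path.duration == 50.0

    def test_seed_determinism(self, ed28_rate_matrix):
        p1 = g.simulate_state_path(ed28_rate_matrix, 5000.0, seed=3)
        p2 = g.simulate_state_path(ed28_rate_matrix, 5000.0, seed=3)
        assert p1.states == p2.states
        np.testing.assert_array_equal(p1.entry, p2.entry)

    def test_time_fraction_matches_stationary(self, ed28_rate_matrix):
        path = g.simulate_state_path(ed28_rate_matrix, 1e5, seed=5)
        n_visits = len(path.states)
        pi_mid = 0.8471
        se = np.sqrt(pi_mid * (1 - pi_mid) / n_visits)
        assert abs(path.fraction_in_state("mid") - pi_mid) < 3 * se

    def test_holding_time_law(self, ed28_rate_matrix):
        # mid visits: empirical mean vs 1/exit-rate over >= 1000 visits
        rng = np.random.default_rng(8)
        durations = []
        while len(durations) < 1000:
            path = g.simulate_state_path(ed28_rate_matrix, 2e5, rng)
            dur = (path.exit - path.entry)[
                np.array([s == "mid" for s in path.states])
            ]
            durations.extend(dur[1:-1])  # interior visits only (uncensored)
        durations = np.asarray(durations[:2000])
        tau = 1.0 / ed28_rate_matrix.exit_rates()[1]
        se = tau / np.sqrt(len(durations))
        assert abs(durations.mean() - tau) < 3 * se

    def test_non_irreducible_generator_rejected(self):
        q = np.array([[0.0, 0.0], [1.0, -1.0]])
        rm = g.RateMatrix(states=("a", "b"), generator=q)
        with pytest.raises(ValueError, match="irreducible"):
            g.simulate_state_path(rm, 10.0, seed=0)


class TestRenderTrace:
    def test_symmetric_noiseless_channels(self):
        em = EmissionModel(
            state_fret={"x": 0.5}, total_intensity=200.0, noise_sd=0.0,
            leakage=0.0, gamma=1.0, background_donor=0.0, background_acceptor=0.0,
            frame_period=1.0,
        )
        path = StatePath(states=("x",), entry=np.array([0.0]), exit=np.array([10.0]))
        tr = g.render_trace(path, em, seed=0)
        np.testing.assert_allclose(tr.donor, 100.0)
        np.testing.assert_allclose(tr.acceptor, 100.0)

    def test_leakage_gamma_expectations(self):
        em = EmissionModel(
            state_fret={"x": 0.5}, total_intensity=220.0, noise_sd=0.0,
            leakage=0.12, gamma=1.7, background_donor=0.0, background_acceptor=0.0,
            frame_period=1.0,
        )
        path = StatePath(states=("x",), entry=np.array([0.0]), exit=np.array([5.0]))
        tr = g.render_trace(path, em, seed=0)
        np.testing.assert_allclose(tr.donor, 110 / 1.7)
        np.testing.assert_allclose(tr.acceptor, 110 + 0.12 * 110 / 1.7)

    @pytest.mark.parametrize("e_true", [0.545, 0.440, 0.339])
    def test_noiseless_round_trip_recovers_state_fret(self, e_true):
        em = EmissionModel(
            state_fret={"x": e_true}, noise_sd=0.0,
            background_donor=0.0, background_acceptor=0.0, frame_period=0.5,
        )
        path = StatePath(states=("x",), entry=np.array([0.0]), exit=np.array([20.0]))
        tr = g.render_trace(path, em, seed=0)
        ft = compute_fret(tr, CorrectionParams())
        np.testing.assert_allclose(ft.raw_efficiency, e_true, atol=1e-10)

    def test_frame_fret_time_weighted(self):
        path = StatePath(states=("a", "b"), entry=np.array([0.0, 1.5]),
                         exit=np.array([1.5, 4.0]))
        e = path.frame_fret({"a": 0.2, "b": 0.8}, 1.0, 4)
        np.testing.assert_allclose(e, [0.2, 0.5, 0.8, 0.8])

    def test_bleach_metadata_recorded(self):
        em = EmissionModel(state_fret={"x": 0.5}, noise_sd=0.0,
                           bleach_rate_donor=1.0, bleach_rate_acceptor=1.0,
                           frame_period=0.5)
        path = StatePath(states=("x",), entry=np.array([0.0]), exit=np.array([100.0]))
        tr = g.render_trace(path, em, seed=4)
        assert "bleach_frame_acceptor" in tr.metadata
        ba = tr.metadata["bleach_frame_acceptor"]
        if ba is not None:
            # donor rises after acceptor death (energy transfer lost)
            assert tr.donor[ba:].mean() >= tr.donor[:ba].mean() or \
                tr.metadata["bleach_frame_donor"] is not None


class TestCohort:
    def test_all_free_dna_static(self, ed28_rate_matrix):
        cfg = g.paper_calibrated_config(n_molecules=5, duration=100.0, seed=2,
                                        free_dna_fraction=1.0)
        cohort = g.simulate_cohort(cfg)
        for path in cohort.paths:
            assert path.states == ("free_dna",)

    def test_bit_identical_under_same_seed(self):
        cfg = g.paper_calibrated_config(n_molecules=4, duration=200.0, seed=9)
        c1, c2 = g.simulate_cohort(cfg), g.simulate_cohort(cfg)
        for t1, t2 in zip(c1.traces, c2.traces):
            np.testing.assert_array_equal(t1.donor, t2.donor)
            np.testing.assert_array_equal(t1.acceptor, t2.acceptor)

    def test_growing_cohort_keeps_existing_molecules(self):
        small = g.simulate_cohort(g.paper_calibrated_config(n_molecules=3, duration=200.0, seed=9))
        big = g.simulate_cohort(g.paper_calibrated_config(n_molecules=6, duration=200.0, seed=9))
        for t1, t2 in zip(small.traces, big.traces[:3]):
            np.testing.assert_array_equal(t1.donor, t2.donor)

    def test_salt_rule_slows_named_exit(self, ed28_rate_matrix):
        rule = SaltRule(reference_mM=50.0, exit_exponents={"high": np.log(0.5) / np.log(3.0)})
        scaled = rule.apply(ed28_rate_matrix, 150.0)
        assert scaled.exit_rates()[0] == pytest.approx(0.5 / 100.25, rel=1e-9)
        # other states untouched
        assert scaled.exit_rates()[2] == pytest.approx(1 / 42.48, rel=1e-9)
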
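"""Segmentation, dwell extraction and dwell-time estimators."""

import numpy as np
import pytest

import gapekin as g
from conftest import path_to_dwells, true_frame_labels
from gapekin.state_kinetics import (
    SegmentationModel,
    dwell_cdf,
    dwells_from_labels,
    fit_exponential_lifetime,
    label_frames,
    mean_dwell,
    occupancy,
    segment_states,
    compare_conditions,
)
from gapekin.trace_correction import FretTrace


def _fret(e, dt=0.5, mol="m"):
    e = np.asarray(e, float)
    return FretTrace(molecule_id=mol, frame_period=dt, efficiency=e,
                     raw_efficiency=e, total=np.full_like(e, 220.0),
                     analysis_end=len(e))


class TestSegmentation:
    def test_noiseless_alternation_exact_dwells(self):
        e = np.concatenate([np.full(100, 0.44), np.full(50, 0.545)])
        dwells = segment_states(_fret(e))
        assert [d.state for d in dwells] == ["mid", "high"]
        assert dwells[0].duration_s == pytest.approx(50.0)
        assert dwells[1].duration_s == pytest.approx(25.0)
        assert dwells[0].left_censored and not dwells[0].right_censored
        assert dwells[1].right_censored and not dwells[1].left_censored

    def test_all_mid_single_dwell_both_censored(self):
        dwells = segment_states(_fret(np.full(80, 0.44)))
        assert len(dwells) == 1
        d = dwells[0]
        assert d.state == "mid" and d.left_censored and d.right_censored

    def test_empty_pre_bleach_region_gives_no_dwells(self):
        e = np.full(30, 0.44)
        ft = FretTrace(molecule_id="m", frame_period=0.5, efficiency=e,
                       raw_efficiency=e, total=np.full(30, 220.0), analysis_end=0)
        assert segment_states(ft) == []

    def test_idempotent_on_reconstructed_trace(self):
        e = np.concatenate([np.full(40, 0.339), np.full(120, 0.44), np.full(60, 0.545)])
        model = SegmentationModel()
        dwells = segment_states(_fret(e), model)
        # rebuild a noiseless trace from the dwells and re-segment
        rebuilt = np.concatenate([
            np.full(int(round(d.duration_s / 0.5)), model.state_means[d.state])
            for d in dwells
        ])
        again = segment_states(_fret(rebuilt), model)
        assert [(d.state, d.duration_s) for d in again] == \
            [(d.state, d.duration_s) for d in dwells]

    def test_frame_accuracy_on_simulated_cohort(self, small_cohort):
        from gapekin.trace_correction import correct_trace

        cfg = small_cohort.config
        model = SegmentationModel()
        accs = []
        for tr, path in zip(small_cohort.traces, small_cohort.paths):
            ft = correct_trace(tr, default_background=(
                cfg.emission.background_donor, cfg.emission.background_acceptor))
            if ft.degenerate or ft.analysis_end < 50:
                continue
            labels = label_frames(ft, model)
            truth = true_frame_labels(path, dict(cfg.emission.state_fret),
                                      cfg.frame_period, ft.analysis_end)
            accs.append(np.mean(labels == truth))
        assert np.mean(accs) > 0.95

    @pytest.mark.parametrize("method", ["threshold", "hmm"])
    def test_both_methods_recover_clean_structure(self, method):
        e = np.concatenate([np.full(60, 0.44), np.full(40, 0.545), np.full(60, 0.44)])
        dwells = segment_states(_fret(e), SegmentationModel(method=method))
        assert [d.state for d in dwells] == ["mid", "high", "mid"]


class TestMeanDwell:
    def test_complete_dwells_arithmetic_mean(self):
        dwells = [g.DwellRecord("m", "high", 0, t) for t in (10.0, 20.0, 30.0)]
        assert mean_dwell(dwells, "high") == pytest.approx(20.0)

    def test_censored_dwells_add_exposure_not_exits(self):
        dwells = [
            g.DwellRecord("m", "high", 0, 30.0),
            g.DwellRecord("m", "high", 0, 30.0),
            g.DwellRecord("m", "high", 0, 40.0, right_censored=True),
        ]
        assert mean_dwell(dwells, "high") == pytest.approx(50.0)

    def test_all_censored_is_undefined(self):
        dwells = [g.DwellRecord("m", "high", 0, 5.0, right_censored=True)]
        with pytest.raises(ValueError, match="exits"):
            mean_dwell(dwells, "high")

    def test_censored_mle_unbiased_monte_carlo(self):
        # 1e4 exponential dwells of mean 100 s, censored at 120 s
        rng = np.random.default_rng(17)
        x = rng.exponential(100.0, 10_000)
        dwells = [
            g.DwellRecord("m", "s", 0, min(v, 120.0), right_censored=v > 120.0)
            for v in x
        ]
        est = mean_dwell(dwells, "s")
        n_exits = sum(1 for d in dwells if not d.right_censored)
        se = 100.0 / np.sqrt(n_exits)
        assert abs(est - 100.0) < 3 * se

    def test_equals_brute_force_frame_oracle(self, small_cohort):
        """total time / exits computed independently from raw frame labels."""
        from gapekin.trace_correction import correct_trace

        cfg = small_cohort.config
        model = SegmentationModel()
        for tr in small_cohort.traces[:10]:
            ft = correct_trace(tr, default_background=(10.0, 10.0))
            if ft.degenerate:
                continue
            labels = label_frames(ft, model)
            dwells = dwells_from_labels(labels, ft.frame_period, ft.molecule_id)
            for state in set(labels):
                frames_in = int(np.sum(labels == state))
                # exits = label changes out of the state, excluding trace end
                exits = int(np.sum((labels[:-1] == state) & (labels[1:] != state)))
                if exits == 0:
                    continue
                oracle = frames_in * ft.frame_period / exits
                assert mean_dwell(dwells, state) == pytest.approx(oracle, rel=1e-12)


class TestOccupancy:
    def test_single_state_is_one(self):
        assert occupancy([g.DwellRecord("m", "mid", 0, 12.0)]) == {"mid": 1.0}

    def test_three_state_arithmetic(self):
        dwells = [
            g.DwellRecord("m", "mid", 0, 800.0),
            g.DwellRecord("m", "high", 0, 150.0),
            g.DwellRecord("m", "low", 0, 50.0),
        ]
        occ = occupancy(dwells)
        assert occ == pytest.approx({"mid": 0.80, "high": 0.15, "low": 0.05})

    def test_sums_to_one_with_censoring(self, small_cohort):
        dwells = [d for p in small_cohort.paths for d in path_to_dwells(p)]
        assert sum(occupancy(dwells).values()) == pytest.approx(1.0, abs=1e-9)


class TestDwellCdf:
    def test_steps(self):
        dwells = [g.DwellRecord("m", "s", 0, t) for t in (3.0, 1.0, 2.0)]
        t, f, n_cens = dwell_cdf(dwells, "s")
        np.testing.assert_allclose(t, [1, 2, 3])
        np.testing.assert_allclose(f, [1 / 3, 2 / 3, 1.0])
        assert n_cens == 0

    def test_censored_excluded_but_counted(self):
        dwells = [
            g.DwellRecord("m", "s", 0, 5.0),
            g.DwellRecord("m", "s", 0, 9.0, right_censored=True),
        ]
        t, f, n_cens = dwell_cdf(dwells, "s")
        assert len(t) == 1 and n_cens == 1

    def test_single_dwell(self):
        t, f, _ = dwell_cdf([g.DwellRecord("m", "s", 0, 5.0)], "s")
        np.testing.assert_allclose(t, [5.0])
        np.testing.assert_allclose(f, [1.0])

    def test_no_complete_dwells_is_error(self):
        with pytest.raises(ValueError, match="complete"):
            dwell_cdf([g.DwellRecord("m", "s", 0, 5.0, left_censored=True)], "s")

    def test_within_dkw_band_of_true_exponential(self):
        rng = np.random.default_rng(23)
        dwells = [g.DwellRecord("m", "s", 0, v) for v in rng.exponential(100.0, 249)]
        t, f, _ = dwell_cdf(dwells, "s")
        band = np.sqrt(np.log(2 / 0.05) / (2 * len(t)))
        truth = 1 - np.exp(-t / 100.0)
        assert np.max(np.abs(f - truth)) < band


class TestLifetimeFit:
    def test_exact_exponential_grid_recovered(self):
        t = -106.0 * np.log(1 - (np.arange(1, 500) - 0.5) / 499)
        fit = fit_exponential_lifetime(t, n_boot=10, seed=0)
        assert fit.tau_s == pytest.approx(106.0, rel=1e-3)

    def test_too_few_dwells_rejected(self):
        with pytest.raises(ValueError, match=">="):
            fit_exponential_lifetime(np.ones(5), n_boot=10)

    def test_bootstrap_se_positive_and_deterministic(self):
        d = np.random.default_rng(3).exponential(100.0, 100)
        f1 = fit_exponential_lifetime(d, n_boot=200, seed=5)
        f2 = fit_exponential_lifetime(d, n_boot=200, seed=5)
        assert f1.se_s > 0 and f1.se_s == f2.se_s

    def test_mle_reported_from_dwell_records(self):
        rng = np.random.default_rng(7)
        dwells = [g.DwellRecord("m", "high", 0, v) for v in rng.exponential(100.0, 50)]
        fit = fit_exponential_lifetime(dwells, state="high", n_boot=50, seed=0)
        assert fit.tau_mle_s == pytest.approx(np.mean([d.duration_s for d in dwells]))
        assert fit.se_mle_s == pytest.approx(fit.tau_mle_s / np.sqrt(50))


class TestCompareConditions:
    @staticmethod
    def _dwells(mean, n, seed, state="high"):
        rng = np.random.default_rng(seed)
        return [g.DwellRecord("m", state, 0, v) for v in rng.exponential(mean, n)]

    def test_identical_inputs_no_shift(self):
        a = self._dwells(100.0, 60, 1)
        cmp = compare_conditions(a, list(a))
        s = cmp.states["high"]
        assert s.delta_tau_s == 0.0 and not s.shift_to_longer

    def test_antisymmetry_of_delta(self):
        a, b = self._dwells(100.0, 60, 1), self._dwells(150.0, 60, 2)
        fwd = compare_conditions(a, b).states["high"].delta_tau_s
        rev = compare_conditions(b, a).states["high"].delta_tau_s
        assert fwd == pytest.approx(-rev)

    def test_underpowered_flag(self):
        a, b = self._dwells(100.0, 5, 1), self._dwells(150.0, 5, 2)
        s = compare_conditions(a, b).states["high"]
        assert s.underpowered and not s.shift_to_longer

    def test_salt_slowed_exit_declared_longer(self, ed28_rate_matrix):
        """Halving the high-state exit rate (150 vs 50 mM scenario) shifts
        the high-state dwell distribution to longer dwells."""
        from gapekin.synthetic_data import SaltRule, simulate_state_path

        rule = SaltRule(exit_exponents={"high": np.log(0.5) / np.log(3.0)})
        slow = rule.apply(ed28_rate_matrix, 150.0)
        rng = np.random.default_rng(31)
        a = [d for i in range(40)
             for d in path_to_dwells(simulate_state_path(ed28_rate_matrix, 3000.0, rng), f"a{i}")]
        b = [d for i in range(40)
             for d in path_to_dwells(simulate_state_path(slow, 3000.0, rng), f"b{i}")]
        s = compare_conditions(a, b, "50mM", "150mM").states["high"]
        assert s.shift_to_longer and s.delta_tau_s > 0
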
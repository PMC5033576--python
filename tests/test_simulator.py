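"""Discrete-time population dynamics: stationarity, conservation,
exponential free growth, drug action and stochastic/mean-field agreement."""

import math

import numpy as np
import pytest

from oncokin.model_core import KineticParameters, balanced_composition
from oncokin.simulator import (DRUG_CATALOGUE, Administration, DrugSpec,
                               TreatmentSchedule, apply_administration,
                               discrete_growth_factor, doubling_time,
                               initialize_state, simulate, step)


def _toy_params(**over):
    base = dict(T_C_stem=8.0, T_C_limp=8.0, T_G0_stem=10.0, T_G0_limp=10.0,
                R_A=0.0, R_ADiff=0.0, R_NDiff=0.0, P_G0toG1_stem=1.0,
                P_G0toG1_limp=1.0, P_sym=1.0, P_sleep=0.0, T_A=2.0, T_N=2.0,
                N_LIMP=3, CKF_stem=1.0)
    base.update(over)
    return KineticParameters(**base)


class TestFreeGrowth:
    def test_pure_stem_doubling(self):
        """All losses off, P_sleep=0, P_sym=1: the population doubles every
        T_C exactly."""
        p = _toy_params()
        state = initialize_state(1.0, p, cell_density=1e4)
        v0 = state.volume
        for _ in range(int(p.T_C_stem)):
            step(state)
        assert state.volume == pytest.approx(2.0 * v0, rel=1e-12)
        for _ in range(int(p.T_C_stem)):
            step(state)
        assert state.volume == pytest.approx(4.0 * v0, rel=1e-12)

    def test_zero_growth_gives_uniform_age_profile(self, scc_params):
        """At the proliferation/loss balance point the stationary
        intra-cycle age distribution is flat (up to the tiny R_A discount)."""
        from oncokin.model_core import ProliferationProfile, calibrate_p_sleep
        from oncokin.clinical import SUBTYPE_INDEPENDENTS
        prof = ProliferationProfile(T_d=1e9, GF=0.36, AF=0.01, NF=0.2,
                                    SF=0.0002)
        ind0 = SUBTYPE_INDEPENDENTS["SCC"].replace(R_A=0.0)
        ps = calibrate_p_sleep(prof, ind0)
        flat = scc_params.replace(P_sleep=ps, R_A=0.0)
        state = initialize_state(10.0, flat)
        ages = state.cyc_s / state.cyc_s[0]
        assert np.allclose(ages, 1.0, atol=1e-4)

    def test_initialized_state_is_stationary(self, scc_params):
        """Compartment fractions drift less than 0.1% over 10 days."""
        state = initialize_state(524.0, scc_params)
        f0 = {k: v / state.total_cells
              for k, v in state.compartment_counts().items()}
        for _ in range(240):
            step(state)
        f1 = {k: v / state.total_cells
              for k, v in state.compartment_counts().items()}
        for k, v in f0.items():
            if v > 0:
                assert abs(f1[k] - v) / v < 1e-3

    def test_log_linear_growth_and_rate(self, adc_params, scc_params):
        """Free growth is exponential (R^2 > 0.9999) at the analytic rate
        (within 1%)."""
        for params in (adc_params, scc_params):
            traj = simulate(524.0, params, None, 120,
                            record_compartments=False)
            fit = doubling_time(traj, skip_hours=2 * params.T_C_stem)
            assert fit.r_squared > 0.9999
            analytic = balanced_composition(params).T_d
            assert fit.days == pytest.approx(analytic, rel=0.01)

    def test_expectation_mode_is_deterministic(self, scc_params):
        t1 = simulate(100.0, scc_params, None, 20)
        t2 = simulate(100.0, scc_params, None, 20)
        assert np.array_equal(t1.volume_mm3, t2.volume_mm3)

    def test_initial_volume_and_necrotic_fraction(self, scc_params):
        """A 10 mm sphere holds (pi/6)*1000 mm^3 of cells at the balanced
        composition (20% necrotic for the squamous baseline)."""
        v = math.pi / 6.0 * 1000.0
        state = initialize_state(v, scc_params)
        assert state.total_cells == pytest.approx(v * 1e6, rel=1e-12)
        assert state.necr / state.total_cells == pytest.approx(0.20, abs=2e-3)


class TestConservation:
    def test_per_tick_cell_accounting(self, random_params_pool):
        """Cells leaving a compartment arrive elsewhere: the change in the
        total equals births minus cleared dead cells, each tick."""
        for params in random_params_pool[:5]:
            state = initialize_state(50.0, params)
            for _ in range(30):
                t0, b0, r0 = state.total_cells, state.born, state.removed
                step(state)
                resid = (state.total_cells - t0) - (state.born - b0) \
                    + (state.removed - r0)
                assert abs(resid) <= 1e-9 * t0


class TestHandComputedTicks:
    def test_two_ticks_match_manual_arithmetic(self):
        """Two expectation ticks of a small configuration, checked against
        a by-hand spreadsheet calculation."""
        p = _toy_params(P_sym=0.5, P_sleep=0.25, P_G0toG1_stem=0.5,
                        P_G0toG1_limp=0.5, N_LIMP=2)
        state = initialize_state(1.0, p, cell_density=1e3)
        # overwrite with a simple configuration: 80 stem cells one tick
        # before mitosis, 40 LIMP gen-1 cells two ticks before, 16 in G0
        state.cyc_s[:] = 0.0
        state.cyc_l[:] = 0.0
        state.cyc_s[-1] = 80.0
        state.cyc_l[0, -2] = 40.0
        state.g0_s = 16.0
        state.g0_l[:] = 0.0
        state.diff = 0.0
        state.apop = 0.0
        state.necr = 0.0
        step(state)
        # tick 1: 80 stem mitoses -> 120 stem newborns (P_sym=0.5) and 40
        # LIMP gen-1 newborns; 25% of newborns sleep; G0 (16 cells) leaks
        # 1/10 of which half re-enter -> 0.8 to G1, 0.8 to necrosis
        assert state.cyc_s[0] == pytest.approx(0.75 * 120 + 0.8)
        assert state.g0_s == pytest.approx(16.0 - 1.6 + 0.25 * 120)
        assert state.cyc_l[0, 0] == pytest.approx(0.75 * 40)
        assert state.g0_l[0] == pytest.approx(0.25 * 40)
        assert state.cyc_l[0, -1] == pytest.approx(40.0)   # aged one tick
        assert state.necr == pytest.approx(0.8)
        step(state)
        # tick 2: the 40 gen-1 cells divide -> 80 gen-2 newborns; dormant
        # pools leak 10% again (half back to G1 of their own generation,
        # half to necrosis); the necrotic pool cleared 50% of its content
        assert state.cyc_l[1, 0] == pytest.approx(0.75 * 80)
        assert state.cyc_l[0, 1] == pytest.approx(0.75 * 40)
        assert state.cyc_l[0, 0] == pytest.approx(0.05 * 10.0)
        assert state.g0_l[1] == pytest.approx(0.25 * 80)
        assert state.necr == pytest.approx(0.5 * 0.8 + 0.05 * (44.4 + 10.0))


class TestDrugAction:
    def test_zero_ckr_reproduces_free_growth(self, scc_params):
        sched = TreatmentSchedule.from_day_drug(
            [(1, "cisplatin"), (1, "gemcitabine")])
        with_drug = simulate(100.0, scc_params, sched, 30,
                             ckr={"cisplatin": 0.0, "gemcitabine": 0.0})
        free = simulate(100.0, scc_params, None, 30)
        assert np.array_equal(with_drug.volume_mm3, free.volume_mm3)

    def test_cycle_specific_drug_spares_dormant_and_diff(self, scc_params):
        state = initialize_state(100.0, scc_params)
        g0_before = state.g0_s + state.g0_l.sum()
        diff_before = state.diff
        gem = DRUG_CATALOGUE["gemcitabine"].with_ckr(1.0)
        apply_administration(state, [gem], ckf_stem=1.0)
        assert state.cyc_s.sum() + state.cyc_l.sum() == pytest.approx(0.0)
        assert state.g0_s + state.g0_l.sum() == pytest.approx(g0_before)
        assert state.diff == pytest.approx(diff_before)

    def test_additive_hits_match_direct_arithmetic(self, scc_params):
        """cisplatin 0.3 + gemcitabine 0.2: half the cycling cells and 30%
        of the dormant cells are marked hit."""
        state = initialize_state(100.0, scc_params)
        cyc_before = state.cyc_s.sum() + state.cyc_l.sum()
        g0_before = state.g0_s + state.g0_l.sum()
        drugs = [DRUG_CATALOGUE["cisplatin"].with_ckr(0.3),
                 DRUG_CATALOGUE["gemcitabine"].with_ckr(0.2)]
        apply_administration(state, drugs, ckf_stem=1.0)
        hit = state.hit_cyc_s.sum() + state.hit_cyc_l.sum()
        assert hit == pytest.approx(0.5 * cyc_before, rel=1e-12)
        assert state.hit_g0_s + state.hit_g0_l == \
            pytest.approx(0.3 * g0_before, rel=1e-12)
        assert state.volume == pytest.approx(100.0, rel=1e-12)

    def test_stem_resistance_scales_with_ckf(self, scc_params):
        state = initialize_state(100.0, scc_params)
        stem_before = state.cyc_s.sum()
        apply_administration(state, [DRUG_CATALOGUE["gemcitabine"].with_ckr(0.4)],
                             ckf_stem=0.5)
        assert state.cyc_s.sum() == pytest.approx(0.8 * stem_before)

    def test_final_volume_monotone_in_ckr(self, scc_params):
        sched = TreatmentSchedule.from_day_drug(
            [(1, "cisplatin"), (1, "gemcitabine"), (8, "gemcitabine")])
        finals = []
        for c in (0.0, 0.2, 0.5, 0.9):
            traj = simulate(200.0, scc_params, sched, 30,
                            ckr={"cisplatin": c, "gemcitabine": 0.2},
                            record_compartments=False)
            finals.append(traj.volume_mm3[-1])
        assert all(b < a for a, b in zip(finals, finals[1:]))

    def test_hit_cells_cleared_within_cycle_plus_apoptosis_time(self, scc_params):
        """Cycling cohorts hit by a drug are removed within T_C + T_A."""
        state = initialize_state(100.0, scc_params)
        apply_administration(state, [DRUG_CATALOGUE["gemcitabine"].with_ckr(0.5)],
                             ckf_stem=1.0)
        horizon = int(scc_params.T_C_stem + 8 * scc_params.T_A)
        for _ in range(horizon):
            step(state)
        hit_left = state.hit_cyc_s.sum() + state.hit_cyc_l.sum()
        assert hit_left == pytest.approx(0.0, abs=1e-9)

    def test_drop_after_each_administration(self, scc_params):
        """Treatment produces regression after each session followed by
        regrowth (non-monotone trajectory)."""
        sched = TreatmentSchedule.from_day_drug(
            [(7, "gemcitabine"), (7, "cisplatin"), (14, "gemcitabine"),
             (28, "gemcitabine"), (28, "cisplatin"), (35, "gemcitabine"),
             (49, "gemcitabine"), (49, "cisplatin"), (56, "gemcitabine")],
            onset_shift_days=1)
        traj = simulate(524.0, scc_params, sched, 80,
                        ckr={"cisplatin": 0.3, "gemcitabine": 0.2},
                        record_compartments=False)
        v = traj.volume_mm3
        for day in (7, 28, 49):
            before = v[day * 24]
            after_min = v[day * 24:(day + 14) * 24].min()
            assert after_min < before
        assert v[-1] > v.min()     # repopulation after the last session

    def test_unknown_drug_rejected(self):
        with pytest.raises(KeyError):
            TreatmentSchedule([Administration(0.0, ("nonexistent",))])


class TestStochasticMode:
    def test_same_seed_reproduces(self, scc_params):
        t1 = simulate(5.0, scc_params, None, 5, mode="stochastic", seed=11,
                      cell_density=1e5, record_compartments=False)
        t2 = simulate(5.0, scc_params, None, 5, mode="stochastic", seed=11,
                      cell_density=1e5, record_compartments=False)
        assert np.array_equal(t1.volume_mm3, t2.volume_mm3)
        with pytest.raises(ValueError):
            simulate(5.0, scc_params, None, 1, mode="stochastic")

    def test_ensemble_mean_tracks_expectation(self, scc_params):
        """The stochastic ensemble mean stays within 3 standard errors of
        the mean-field trajectory."""
        days, reps = 15, 30
        exp = simulate(2.0, scc_params, None, days, cell_density=1e5,
                       record_compartments=False)
        finals = np.array([
            simulate(2.0, scc_params, None, days, mode="stochastic",
                     seed=1000 + r, cell_density=1e5,
                     record_compartments=False).volume_mm3[-1]
            for r in range(reps)])
        se = finals.std(ddof=1) / math.sqrt(reps)
        assert abs(finals.mean() - exp.volume_mm3[-1]) < 3 * se + 1e-12


class TestCompositionOracle:
    def test_long_run_fractions_match_closed_form(self, random_params_pool):
        """Simulated long-run compartment fractions agree with the
        balanced-growth composition within 0.5% relative."""
        checked = 0
        for params in random_params_pool:
            comp = balanced_composition(params)
            state = initialize_state(50.0, params)
            for _ in range(40 * 24):
                step(state)
            cc = state.compartment_counts()
            living = cc["stem"] + cc["limp"] + cc["diff"]
            total = state.total_cells
            for value, target in [(cc["cycling"] / living, comp.GF),
                                  (cc["g0"] / living, comp.QF),
                                  (cc["diff"] / living, comp.diff_fraction),
                                  (cc["stem"] / living, comp.SF),
                                  (cc["apoptotic"] / total, comp.AF),
                                  (cc["necrotic"] / total, comp.NF)]:
                if target > 1e-9:
                    assert value == pytest.approx(target, rel=5e-3)
            checked += 1
        assert checked >= 20


class TestDoublingTime:
    def test_exact_exponential(self):
        from oncokin.simulator import Trajectory
        t = np.arange(0, 2400.0)
        v = 100.0 * 2 ** (t / (100.0 * 24.0))
        fit = doubling_time(Trajectory(time_h=t, volume_mm3=v))
        assert fit.days == pytest.approx(100.0, rel=1e-9)
        assert not fit.negative_growth

    def test_flat_and_shrinking(self):
        from oncokin.simulator import Trajectory
        t = np.arange(0, 100.0)
        flat = doubling_time(Trajectory(time_h=t, volume_mm3=np.full(100, 7.0)))
        assert math.isinf(flat.days)
        shrink = doubling_time(Trajectory(time_h=t,
                                          volume_mm3=100 * 2 ** (-t / 240.0)))
        assert shrink.negative_growth and shrink.days < 0
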
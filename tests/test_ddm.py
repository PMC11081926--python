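"""Evidence accumulation: signals, first-passage times, session walks."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from patchleave import ddm, task
from patchleave.ddm import DDMParams, InputSignal


def make_signal(values, onsets=None, horizon=None):
    values = np.asarray(values, float)
    if onsets is None:
        onsets = np.arange(len(values)) * 3.5
    if horizon is None:
        horizon = onsets[-1] + 3.5
    return InputSignal(np.asarray(onsets, float), values, horizon)


@st.composite
def piecewise_signals(draw):
    n = draw(st.integers(2, 12))
    vals = draw(st.lists(st.floats(0.0, 0.53), min_size=n, max_size=n))
    return make_signal(vals)


class TestSignals:
    def test_constant_signal(self, rng):
        p = task.build_partner(task.PartnerSpec(-0.125, "fair", "S12"), rng)
        p.proportions[:] = 0.5
        sig = ddm.fairness_signal(p)
        assert np.unique(sig.values).tolist() == [0.5]

    def test_step_semantics(self):
        sig = make_signal([0.5, 0.4])
        assert sig.value_at(2.0) == 0.5
        assert sig.value_at(4.0) == 0.4

    def test_onset_values_match_decisions(self, rng):
        p = task.build_partner(task.PartnerSpec(-0.175, "unfair", "S4"), rng)
        sig = ddm.fairness_signal(p)
        assert np.allclose(sig.value_at(p.onsets), p.proportions)

    def test_reward_scaling(self, rng):
        p = task.build_partner(task.PartnerSpec(-0.125, "fair", "S12"), rng)
        sig = ddm.reward_signal(p, reward_scale=0.01)
        assert np.allclose(sig.values, 0.01 * p.credits_shared)
        assert (sig.values[p.credits_shared == 0] == 0).all()

    def test_zero_scale_rejected(self, rng):
        p = task.build_partner(task.PartnerSpec(-0.125, "fair", "S12"), rng)
        with pytest.raises(ValueError):
            ddm.reward_signal(p, reward_scale=0.0)

    def test_standard_signal_is_zero(self, rng):
        p = task.build_partner(task.PartnerSpec(-0.125, "fair", "S12"), rng)
        assert ddm.signal_for_variant("standard", p).values.sum() == 0.0


class TestNoiselessLeaving:
    def test_closed_form(self):
        params = DDMParams("standard", threshold=10, drift_gain=0.5,
                           noise_sd=0.0)
        sig = InputSignal.constant(0.0, 105.0)
        out = ddm.simulate_leaving(params, sig, 1)
        assert out.leaving_time == pytest.approx(20.0, abs=2 * params.dt)
        assert not out.censored
        det = ddm.deterministic_leaving(params, sig)
        assert det.leaving_time == pytest.approx(20.0)

    def test_zero_net_drift_censors(self):
        params = DDMParams("standard", threshold=5, drift_gain=0.4,
                           noise_sd=0.0)
        sig = InputSignal.constant(0.4, 50.0)
        out = ddm.simulate_leaving(params, sig, 1)
        assert out.censored and out.leaving_time == 50.0

    @given(sig=piecewise_signals(),
           theta=st.floats(0.5, 20), k=st.floats(0.05, 1.5),
           eps=st.floats(0.0, 0.4))
    def test_simulator_matches_integrator(self, sig, theta, k, eps):
        """Euler path at sigma=0 equals the exact piecewise integral."""
        params = DDMParams("fairness", threshold=theta, drift_gain=k,
                           noise_sd=0.0, start_bias=min(eps, theta * 0.9),
                           dt=0.002)
        det = ddm.deterministic_leaving(params, sig)
        sim = ddm.simulate_leaving(params, sig, 3)
        assert sim.censored == det.censored
        assert sim.leaving_time == pytest.approx(det.leaving_time,
                                                 abs=2 * params.dt)

    @given(sig=piecewise_signals(), k=st.floats(0.3, 1.5))
    def test_monotone_in_threshold(self, sig, k):
        lts = []
        for theta in (2.0, 6.0, 12.0):
            p = DDMParams("fairness", theta, k, 0.0)
            lts.append(ddm.deterministic_leaving(p, sig).leaving_time)
        assert lts == sorted(lts)

    def test_dt_halving_stability(self):
        sig = make_signal([0.5, 0.3, 0.1, 0.0])
        for dt in (0.002, 0.001):
            p1 = DDMParams("fairness", 4, 0.6, 0.0, dt=dt)
            p2 = DDMParams("fairness", 4, 0.6, 0.0, dt=dt / 2)
            t1 = ddm.simulate_leaving(p1, sig, 1).leaving_time
            t2 = ddm.simulate_leaving(p2, sig, 1).leaving_time
            assert abs(t1 - t2) <= dt + 1e-9


class TestStochasticProperties:
    def test_trace_starts_at_bias_and_stays_nonnegative(self):
        params = DDMParams("standard", threshold=3, drift_gain=0.2,
                           noise_sd=0.8, start_bias=0.4, dt=0.001)
        sig = InputSignal.constant(0.3, 40.0)
        out, trace = ddm.simulate_leaving(params, sig, 7, return_trace=True)
        assert trace.ea[0] == pytest.approx(0.4)
        assert (trace.ea >= 0).all()
        assert out.leaving_time <= 40.0

    def test_pathwise_dominance_larger_input_slower(self):
        """Pointwise-larger input gives pathwise (hence stochastically)
        larger leaving times under shared noise."""
        n_steps = int(60.0 / 0.002)
        horizons = np.full(64, 60.0)
        seeds = np.arange(1, 65, dtype=np.int64)
        lts = {}
        for x in (0.0, 0.3):
            xbar = np.full((64, n_steps), x)
            out, cens = ddm._fp_seeded(
                xbar, horizons, np.array([5.0]), np.array([0.5]),
                np.array([0.4]), np.array([0.0]), 0.002, seeds, False)
            lts[x] = out[0]
        assert (lts[0.3] >= lts[0.0]).all()

    def test_pathwise_monotone_in_params(self):
        n_steps = int(80.0 / 0.002)
        xbar = np.full((64, n_steps), 0.2)
        horizons = np.full(64, 80.0)
        seeds = np.arange(1, 65, dtype=np.int64)

        def run(theta, k):
            out, _ = ddm._fp_seeded(
                xbar, horizons, np.array([theta]), np.array([k]),
                np.array([0.3]), np.array([0.0]), 0.002, seeds, False)
            return out[0]

        assert (run(8.0, 0.6) >= run(4.0, 0.6)).all()   # threshold up
        assert (run(6.0, 0.9) <= run(6.0, 0.5)).all()   # drift up

    def test_euler_noise_scaling_integrates_correctly(self):
        """Free diffusion: accumulated sd after t seconds is sigma*sqrt(t)
        under the Euler-Maruyama discretization (the literal per-step
        reading would give sigma*sqrt(t/dt))."""
        params = DDMParams("standard", threshold=1e6, drift_gain=0.0,
                           noise_sd=0.5, dt=0.001)
        sig = InputSignal.constant(0.0, 4.0)
        finals = []
        for seed in range(300):
            # start high enough that the zero-clamp never binds
            p = ddm.params_with(params, start_bias=100.0,
                                threshold=1e6)
            _, trace = ddm.simulate_leaving(p, sig, seed, return_trace=True)
            finals.append(trace.ea[-1] - 100.0)
        assert np.std(finals) == pytest.approx(0.5 * 2.0, rel=0.2)


class TestLTDistribution:
    def test_sample_size(self, rng):
        env = task.build_group("high_generosity", "S12", rng, n_partners=4)
        p = DDMParams("fairness", 10, 0.5, 0.3, dt=0.005)
        lts = ddm.simulate_lt_distribution(p, env, 1000, 5)
        assert lts.shape == (1000,)
        assert (lts <= 101.5 + 1e-9).all()

    def test_standard_variant_environment_free(self, rng):
        """With X = 0 and no noise every simulation leaves at the same
        time regardless of the environment."""
        high = task.build_group("high_generosity", "S12", rng, n_partners=4)
        low = task.build_group("low_generosity", "S12", rng, n_partners=4)
        p = DDMParams("standard", 10, 0.5, 0.0, dt=0.005)
        a = ddm.simulate_lt_distribution(p, high, 50, 1)
        b = ddm.simulate_lt_distribution(p, low, 50, 2)
        assert np.allclose(a, b)

    def test_fairness_generosity_ordering(self, rng):
        """Richer mixtures keep the input high for longer, slowing the
        leave accumulator: mean LT is larger in the high-generosity
        environment at fixed parameters."""
        high = task.build_group("high_generosity", "S12", rng, n_partners=4)
        low = task.build_group("low_generosity", "S12", rng, n_partners=4)
        p = DDMParams("fairness", 10, 0.5, 0.3, dt=0.005)
        a = ddm.simulate_lt_distribution(p, high, 3000, 11)
        b = ddm.simulate_lt_distribution(p, low, 3000, 12)
        assert a.mean() > b.mean()

    def test_censored_recorded_at_censor_value(self, rng):
        env = task.build_group("high_generosity", "S12", rng, n_partners=4)
        p = DDMParams("fairness", 29, 0.1, 0.1, dt=0.005)  # rarely crosses
        lts = ddm.simulate_lt_distribution(p, env, 100, 3)
        assert (lts <= 101.5 + 1e-9).all()
        assert (lts == 101.5).mean() > 0.5


class TestSessionWalk:
    def test_never_crossing_agent(self, rng):
        session = task.build_session("S12", rng, n_partners_per_group=6,
                                     n_groups=2)
        p = DDMParams("standard", 29.9, 0.0, 0.0, dt=0.005)
        params = {g.environment_type: p for g in session.groups}
        rec = ddm.simulate_participant_session(params, session, rng)
        assert rec["censored"].all()
        assert (rec["leaving_time_s"] == 101.5).all()
        # 300 s block: interactions of 105 s + 8 s travel -> 3 per group
        assert (rec.groupby("group_index").size() == 3).all()

    def test_schedule_bound(self, rng):
        session = task.build_session("S12", rng, n_partners_per_group=30,
                                     n_groups=2)
        p = DDMParams("fairness", 8, 0.6, 0.3, dt=0.005)
        params = {g.environment_type: p for g in session.groups}
        rec = ddm.simulate_participant_session(params, session, rng)
        for _, grp in rec.groupby("group_index"):
            spent = grp["leaving_time_s"].sum() + 8.0 * len(grp)
            assert spent <= 300.0 + 101.5 + 8.0  # one interaction overhang

    def test_higher_threshold_fewer_partners(self, rng):
        session = task.build_session("S12", rng, n_partners_per_group=40,
                                     n_groups=4)
        lo = DDMParams("fairness", 4, 0.6, 0.2, dt=0.005)
        hi = DDMParams("fairness", 16, 0.6, 0.2, dt=0.005)
        n = {}
        for name, p in (("lo", lo), ("hi", hi)):
            params = {g.environment_type: p for g in session.groups}
            rec = ddm.simulate_participant_session(
                params, session, np.random.default_rng(5))
            n[name] = len(rec)
        assert n["hi"] < n["lo"]

    def test_missing_environment_params(self, rng):
        session = task.build_session("S12", rng, n_partners_per_group=4,
                                     n_groups=2)
        p = DDMParams("standard", 10, 0.5, 0.1)
        with pytest.raises(ValueError):
            ddm.simulate_participant_session({"high_generosity": p},
                                             session, rng)


class TestParamValidation:
    @pytest.mark.parametrize("kw", [
        dict(threshold=-1), dict(noise_sd=-0.1), dict(dt=0.0),
        dict(start_bias=11.0), dict(threshold=np.nan),
    ])
    def test_invalid(self, kw):
        base = dict(variant="fairness", threshold=10, drift_gain=0.5,
                    noise_sd=0.3)
        base.update(kw)
        with pytest.raises(ValueError):
            DDMParams(**base)

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            DDMParams("bayesian", 10, 0.5, 0.3)
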
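"""Drift-diffusion models of the decision to leave a social interaction.

The accumulator integrates evidence toward leaving,

    dEA = (k - X(t)) dt + noise,      EA(0) = eps,  EA(t) >= 0 for all t,

and the agent leaves the first time EA exceeds the threshold theta.  X is a
piecewise-constant input built from the partner's decision stream; three
variants differ only in X:

* ``fairness``: X(t) = F(t), the proportion shared by the most recently
  revealed decision;
* ``reward``:   X(t) = a * R(t), the credits shared scaled into F's range
  (a ~ 0.01);
* ``standard``: X(t) = 0, a partner-blind benchmark.

The per-step noise is Euler-Maruyama scaled, sd = sigma * sqrt(dt), so the
process converges to a diffusion as dt -> 0.  A ``noise_scaling="literal"``
switch instead adds N(0, sigma) per step — the verbatim reading of a
per-step Gaussian term — for comparison only; at dt = 0.001 that reading
integrates to a sd of roughly 245 * sigma over a minute, which no plausible
threshold contains.

Accumulation restarts at the starting bias with every new partner; there is
no across-partner carryover, collapsing bound, or non-decision time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from . import task
from .task import GroupSpec, PartnerTrajectory, SessionSpec

__all__ = [
    "DDMParams",
    "InputSignal",
    "LeaveOutcome",
    "EvidenceTrace",
    "fairness_signal",
    "reward_signal",
    "signal_for_variant",
    "simulate_leaving",
    "deterministic_leaving",
    "simulate_lt_distribution",
    "simulate_participant_session",
]

VARIANTS = ("standard", "reward", "fairness")
DEFAULT_DT = 0.001
DEFAULT_REWARD_SCALE = 0.01


@dataclass(frozen=True)
class DDMParams:
    """Free parameters of one leaving-DDM variant.

    ``drift_gain`` is the constant input gain k of the accumulator (distinct
    from the trajectory decay rate); ``noise_sd`` is the diffusion sigma;
    ``start_bias`` the prior inclination to leave eps; ``threshold`` theta.
    """

    variant: str
    threshold: float
    drift_gain: float
    noise_sd: float
    start_bias: float = 0.0
    dt: float = DEFAULT_DT
    reward_scale: float = DEFAULT_REWARD_SCALE

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown DDM variant {self.variant!r}")
        for name in ("threshold", "drift_gain", "noise_sd", "start_bias",
                     "dt", "reward_scale"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.start_bias < self.threshold:
            raise ValueError("start_bias must lie in [0, threshold)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.reward_scale <= 0:
            raise ValueError("reward_scale must be positive")


@dataclass(frozen=True)
class InputSignal:
    """Piecewise-constant, right-continuous input on [0, horizon].

    ``breakpoints[i]`` is the onset of segment ``i`` with value
    ``values[i]``; the first breakpoint is 0 (the first offer is visible at
    connection).
    """

    breakpoints: np.ndarray
    values: np.ndarray
    horizon: float
    censor_time: float | None = None  # onset of final decision, if known

    def __post_init__(self):
        bp = np.asarray(self.breakpoints, dtype=float)
        va = np.asarray(self.values, dtype=float)
        if bp.size == 0 or bp.size != va.size:
            raise ValueError("breakpoints and values must be non-empty, equal length")
        if bp[0] != 0.0 or np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must start at 0 and increase")
        if self.horizon <= bp[-1]:
            raise ValueError("horizon must exceed the last breakpoint")
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "values", va)

    def value_at(self, t) -> np.ndarray:
        idx = np.minimum(
            np.searchsorted(self.breakpoints, np.asarray(t, float), side="right") - 1,
            len(self.values) - 1,
        )
        return self.values[np.maximum(idx, 0)]

    @classmethod
    def constant(cls, value: float, horizon: float) -> "InputSignal":
        return cls(np.array([0.0]), np.array([float(value)]), horizon)


@dataclass(frozen=True)
class LeaveOutcome:
    leaving_time: float
    censored: bool


@dataclass(frozen=True)
class EvidenceTrace:
    times: np.ndarray
    ea: np.ndarray


# ---------------------------------------------------------------------------
# Signals
# ---------------------------------------------------------------------------


def fairness_signal(trajectory: PartnerTrajectory) -> InputSignal:
    """F(t): proportion of the most recently revealed sharing decision."""
    if len(trajectory.proportions) == 0:
        raise ValueError("trajectory has no decisions")
    return InputSignal(trajectory.onsets, trajectory.proportions,
                       horizon=trajectory.horizon,
                       censor_time=trajectory.censor_time)


def reward_signal(trajectory: PartnerTrajectory,
                  reward_scale: float = DEFAULT_REWARD_SCALE) -> InputSignal:
    """a * R(t): credits shared, scaled into the range of F."""
    if reward_scale <= 0:
        raise ValueError("reward_scale must be positive")
    return InputSignal(trajectory.onsets,
                       reward_scale * trajectory.credits_shared,
                       horizon=trajectory.horizon,
                       censor_time=trajectory.censor_time)


def signal_for_variant(variant: str, trajectory: PartnerTrajectory,
                       reward_scale: float = DEFAULT_REWARD_SCALE) -> InputSignal:
    if variant == "fairness":
        return fairness_signal(trajectory)
    if variant == "reward":
        return reward_signal(trajectory, reward_scale)
    if variant == "standard":
        return InputSignal(trajectory.onsets,
                           np.zeros_like(trajectory.proportions),
                           horizon=trajectory.horizon,
                           censor_time=trajectory.censor_time)
    raise ValueError(f"unknown DDM variant {variant!r}")


# ---------------------------------------------------------------------------
# Numba first-passage kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _fp_seeded(xbar, horizons, thetas, drifts, sigmas, epses, dt, seeds,
               literal_noise):
    """First-passage times over step-averaged input signals.

    ``xbar[s, i]`` is the exact time-average of the input over step ``i``
    of simulation ``s``, so the noiseless path equals the continuous
    integral at every step edge regardless of where segment onsets fall.
    Each sim reseeds from ``seeds[s]`` before every grid point (common
    random numbers).  Censored sims report the horizon.
    """
    n_points = thetas.size
    n_sims, n_steps = xbar.shape
    lts = np.empty((n_points, n_sims))
    censored = np.zeros((n_points, n_sims), dtype=np.bool_)
    sqdt = np.sqrt(dt)
    for p in range(n_points):
        theta = thetas[p]
        k = drifts[p]
        step_sd = sigmas[p] if literal_noise else sigmas[p] * sqdt
        eps = epses[p]
        for s in range(n_sims):
            np.random.seed(seeds[s])
            horizon = horizons[s]
            ea = eps
            crossed = False
            t = 0.0
            for i in range(n_steps):
                if t >= horizon:
                    break
                ea += (k - xbar[s, i]) * dt
                if step_sd > 0.0:
                    ea += step_sd * np.random.standard_normal()
                if ea < 0.0:
                    ea = 0.0
                t = (i + 1) * dt
                if ea > theta:
                    crossed = True
                    break
            if crossed:
                lts[p, s] = min(t, horizon)
            else:
                lts[p, s] = horizon
                censored[p, s] = True
    return lts, censored


@njit(cache=True)
def _fp_noise_bank(xbar, horizons, thetas, drifts, step_sds, epses, dt,
                   noise):
    """Grid first-passage with a precomputed shared noise bank.

    ``noise`` is an (n_sims, n_steps) array of standard normal increments,
    identical across grid points — the common-random-numbers policy made
    explicit.  ``step_sds`` are per-point per-step noise s.d.s (already on
    the chosen discretization scale).
    """
    n_points = thetas.size
    n_sims, n_steps = xbar.shape
    lts = np.empty((n_points, n_sims))
    censored = np.zeros((n_points, n_sims), dtype=np.bool_)
    for p in range(n_points):
        theta = thetas[p]
        k = drifts[p]
        step_sd = step_sds[p]
        eps = epses[p]
        for s in range(n_sims):
            horizon = horizons[s]
            ea = eps
            crossed = False
            t = 0.0
            for i in range(n_steps):
                if t >= horizon:
                    break
                ea += (k - xbar[s, i]) * dt + step_sd * noise[s, i]
                if ea < 0.0:
                    ea = 0.0
                t = (i + 1) * dt
                if ea > theta:
                    crossed = True
                    break
            if crossed:
                lts[p, s] = min(t, horizon)
            else:
                lts[p, s] = horizon
                censored[p, s] = True
    return lts, censored


@njit(cache=True)
def _trace_one(xbar, horizon, theta, k, sigma, eps, dt, seed,
               literal_noise):
    """Single-path simulation returning the full evidence trace."""
    n_steps = xbar.size
    ea_out = np.empty(n_steps + 1)
    np.random.seed(seed)
    step_sd = sigma if literal_noise else sigma * np.sqrt(dt)
    ea = eps
    ea_out[0] = ea
    t = 0.0
    n = 0
    crossed = False
    for i in range(n_steps):
        if t >= horizon:
            break
        ea += (k - xbar[i]) * dt
        if step_sd > 0.0:
            ea += step_sd * np.random.standard_normal()
        if ea < 0.0:
            ea = 0.0
        t = (i + 1) * dt
        n += 1
        ea_out[n] = ea
        if ea > theta:
            crossed = True
            break
    return min(t, horizon), crossed, ea_out[: n + 1]


def stepwise_mean_input(onsets, values, horizon: float, dt: float,
                        n_steps: int | None = None) -> np.ndarray:
    """Exact per-step time-average of a piecewise-constant signal.

    Integrating the input exactly over each Euler step keeps the noiseless
    discrete path equal to the continuous integral at every step edge, so
    first-passage times agree with the analytic solver to within one step
    even when segment onsets fall inside a step.
    """
    onsets = np.asarray(onsets, float)
    values = np.asarray(values, float)
    if n_steps is None:
        n_steps = int(np.ceil(horizon / dt))
    ends = np.append(onsets[1:], max(horizon, onsets[-1] + dt))
    seg_cum = np.concatenate([[0.0], np.cumsum(values * (ends - onsets))])

    def integral(t):
        idx = np.clip(np.searchsorted(onsets, t, side="right") - 1,
                      0, len(values) - 1)
        inside = np.clip(t, onsets[idx], ends[idx]) - onsets[idx]
        return seg_cum[idx] + values[idx] * inside

    edges = np.minimum(np.arange(n_steps + 1) * dt, horizon)
    return np.diff(integral(edges)) / dt


def _kernel_seed(rng: np.random.Generator | int | None) -> int:
    if rng is None:
        rng = np.random.default_rng()
    if isinstance(rng, (int, np.integer)):
        return int(rng) % (2**31 - 1)
    return int(rng.integers(2**31 - 1))


# ---------------------------------------------------------------------------
# Simulation API
# ---------------------------------------------------------------------------


def simulate_leaving(params: DDMParams, signal: InputSignal,
                     rng: np.random.Generator | int | None = None,
                     return_trace: bool = False,
                     noise_scaling: str = "euler"):
    """Simulate one leaving decision; optionally return the evidence trace.

    Returns a :class:`LeaveOutcome`, or ``(LeaveOutcome, EvidenceTrace)``
    when ``return_trace`` is set.  Censored outcomes report the horizon.
    """
    if noise_scaling not in ("euler", "literal"):
        raise ValueError("noise_scaling must be 'euler' or 'literal'")
    literal = noise_scaling == "literal"
    seed = _kernel_seed(rng)
    xbar = stepwise_mean_input(signal.breakpoints, signal.values,
                               signal.horizon, params.dt)
    if return_trace:
        t, crossed, ea = _trace_one(xbar, signal.horizon, params.threshold,
                                    params.drift_gain, params.noise_sd,
                                    params.start_bias, params.dt, seed,
                                    literal)
        lt = t if crossed else signal.horizon
        times = np.arange(ea.size) * params.dt
        return (LeaveOutcome(float(lt), not crossed),
                EvidenceTrace(times, ea))
    lts, cens = _fp_seeded(
        xbar[None, :], np.array([signal.horizon]),
        np.array([params.threshold]), np.array([params.drift_gain]),
        np.array([params.noise_sd]), np.array([params.start_bias]),
        params.dt, np.array([seed], dtype=np.int64), literal)
    return LeaveOutcome(float(lts[0, 0]), bool(cens[0, 0]))


def deterministic_leaving(params: DDMParams, signal: InputSignal) -> LeaveOutcome:
    """Noiseless first-passage time, exact within each constant segment.

    With sigma = 0 the accumulator is piecewise-linear (clamped at zero), so
    the crossing time solves a linear equation inside one segment.  Used as
    the independent oracle for the stochastic simulator.
    """
    theta, k, eps = params.threshold, params.drift_gain, params.start_bias
    bp = signal.breakpoints
    ends = np.append(bp[1:], signal.horizon)
    ea = eps
    for t0, t1, x in zip(bp, ends, signal.values):
        slope = k - x
        if slope > 0 and ea + slope * (t1 - t0) > theta:
            return LeaveOutcome(float(t0 + (theta - ea) / slope), False)
        ea = max(0.0, ea + slope * (t1 - t0))
    return LeaveOutcome(float(signal.horizon), True)


def _environment_sampler(environment: GroupSpec):
    """Draw fresh partner trajectories from the environment's composition.

    High/low-generosity mixes are 3:1 / 1:3 fair:unfair; effort and S3
    environments are 1:1.  Decay rates are drawn from the variant's class
    sets, matching how groups are built.
    """
    win, n_fair = task.COMPOSITION_WINDOWS[environment.environment_type]
    p_fair = n_fair / win
    variant = environment.study_variant

    def draw(rng: np.random.Generator) -> PartnerTrajectory:
        cls = "fair" if rng.random() < p_fair else "unfair"
        rates = task.DECAY_RATES[variant][cls]
        rate = float(rates[rng.integers(len(rates))])
        spec = task.PartnerSpec(decay_rate=rate, fairness_class=cls,
                                study_variant=variant)
        return task.build_partner(spec, rng)

    return draw


def sample_signal_bank(variant: str, environment: GroupSpec, n_sims: int,
                       rng: np.random.Generator, dt: float,
                       reward_scale: float = DEFAULT_REWARD_SCALE):
    """Pre-draw ``n_sims`` partner signals from the environment mixture.

    Returns ``(xbar, horizons, censor_times)`` where ``xbar`` holds the
    step-averaged input per simulation, shared across grid points under
    common random numbers.
    """
    draw = _environment_sampler(environment)
    trajectories = [draw(rng) for _ in range(n_sims)]
    horizons = np.array([t.horizon for t in trajectories])
    censor = np.array([t.censor_time for t in trajectories])
    n_steps = int(np.ceil(horizons.max() / dt))
    xbar = np.zeros((n_sims, n_steps))
    if variant not in VARIANTS:
        raise ValueError(f"unknown DDM variant {variant!r}")
    if variant != "standard":
        for s, traj in enumerate(trajectories):
            values = (traj.proportions if variant == "fairness"
                      else reward_scale * traj.credits_shared)
            xbar[s] = stepwise_mean_input(traj.onsets, values, traj.horizon,
                                          dt, n_steps)
    return xbar, horizons, censor


def simulate_lt_distribution(params: DDMParams, environment: GroupSpec,
                             n_sims: int,
                             rng: np.random.Generator | int | None = None,
                             noise_scaling: str = "euler") -> np.ndarray:
    """Model leaving-time distribution for one environment.

    Each simulation draws a fresh partner from the environment's mixture,
    builds the variant's input signal, and simulates one leaving time.
    Censored simulations enter the sample at the censoring value (onset of
    the final decision), mirroring how non-leaves are censored in data.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    out = np.empty(n_sims)
    done = 0
    while done < n_sims:  # chunked to bound the signal-bank footprint
        chunk = min(512, n_sims - done)
        xbar, horizons, censor = sample_signal_bank(
            params.variant, environment, chunk, rng, params.dt,
            params.reward_scale)
        seeds = rng.integers(2**31 - 1, size=chunk).astype(np.int64)
        lts, cens = _fp_seeded(
            xbar, horizons,
            np.array([params.threshold]), np.array([params.drift_gain]),
            np.array([params.noise_sd]), np.array([params.start_bias]),
            params.dt, seeds, noise_scaling == "literal")
        vals = lts[0].copy()
        vals[cens[0]] = censor[cens[0]]
        out[done:done + chunk] = vals
        done += chunk
    return out


def simulate_participant_session(params_by_environment: dict,
                                 session: SessionSpec,
                                 rng: np.random.Generator,
                                 participant_id: str = "p0",
                                 noise_scaling: str = "euler"):
    """Walk a session timeline with one agent; one record per interaction.

    Within each 300 s block: connect to the next queued partner, accumulate
    until crossing (or exhaust the 30 decisions), add the 8 s travel delay,
    repeat while block time remains.  Censored interactions record the onset
    of the final sharing decision as the leaving time.

    Returns a :class:`pandas.DataFrame` of leaving-time records.
    """
    import pandas as pd

    env_types = {g.environment_type for g in session.groups}
    missing = env_types - set(params_by_environment)
    if missing:
        raise ValueError(f"missing DDM params for environments: {sorted(missing)}")

    rows = []
    for gi, group in enumerate(session.groups):
        params = params_by_environment[group.environment_type]
        clock = 0.0
        for pi, partner in enumerate(group.partners):
            if clock >= group.duration:
                break
            signal = signal_for_variant(params.variant, partner,
                                        params.reward_scale)
            outcome = simulate_leaving(params, signal, rng,
                                       noise_scaling=noise_scaling)
            lt = partner.censor_time if outcome.censored else outcome.leaving_time
            rows.append({
                "participant_id": participant_id,
                "study_variant": session.study_variant,
                "group_index": gi,
                "environment_type": group.environment_type,
                "partner_index": pi,
                "decay_rate": partner.spec.decay_rate,
                "fairness_class": partner.spec.fairness_class,
                "leaving_time_s": float(lt),
                "censored": bool(outcome.censored),
                "censor_time_s": partner.censor_time,
                "proportion_at_leaving": float(
                    fairness_signal(partner).value_at(lt)),
                "credits_earned": _credits_earned(partner, lt,
                                                  outcome.censored),
            })
            # censored interactions occupy the full stream before travel
            clock += (partner.horizon if outcome.censored
                      else outcome.leaving_time) + session.travel_delay
    return pd.DataFrame(rows)


def _credits_earned(partner: PartnerTrajectory, lt: float,
                    censored: bool) -> float:
    """Credits from decisions fully shown before leaving (all 30 if censored)."""
    if censored:
        return float(partner.credits_shared.sum())
    complete = (partner.onsets + partner.durations) <= lt
    return float(partner.credits_shared[complete].sum())


def params_with(params: DDMParams, **kwargs) -> DDMParams:
    """Convenience: a copy of ``params`` with fields replaced."""
    return replace(params, **kwargs)
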
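"""Synthetic social patch-leaving task: partners, groups and sessions.

Partners in this task are dictator-game allocators whose shared proportion
decays exponentially over their 30 sharing decisions,

    p_t = s * exp(k * t),

with ``s = 0.5`` (an equal split, replaced on trial 0 by a uniform "first
offer" draw) and a per-trial decay rate ``k <= 0`` that defines fair versus
unfair partners.  Social environments (groups) differ either in the ratio of
fair to unfair partners (generosity manipulation) or in the button-press
effort required to travel between partners (effort manipulation).  Everything
here is seeded and deterministic given a :class:`numpy.random.Generator`.

Three study variants are supported:

``S12``
    Two decay rates (−0.125 fair, −0.2 unfair); proportions below 0.05 are
    replaced by zero; credits per decision are drawn uniformly from [50, 200]
    under the constraint that every six consecutive decisions sum to 500.
``S3``
    As ``S12`` but the floor is a clamp at 0.05 (no zero offers) and the
    environment manipulation is travel effort, with a 1:1 partner mix.
``S4``
    Seventeen decay rates, per-decision Gaussian trajectory noise
    (sd 0.015), credits ~ Normal(400, 30), and a jittered trial schedule
    averaging 3.5 s per trial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "PartnerSpec",
    "SharingDecision",
    "PartnerTrajectory",
    "GroupSpec",
    "SessionSpec",
    "EffortCalibration",
    "decay_proportion",
    "apply_fairness_rule",
    "sample_first_offer",
    "noisy_trajectory_s4",
    "sample_credit_block",
    "stake_from_credits",
    "sample_credits_s4",
    "build_partner",
    "build_group",
    "build_session",
    "effort_requirement",
    "sample_trial_duration_s4",
    "session_to_frame",
    "default_config",
]

# ---------------------------------------------------------------------------
# Task constants (per study variant)
# ---------------------------------------------------------------------------

STUDY_VARIANTS = ("S12", "S3", "S4")

N_DECISIONS = 30
BLOCK_DURATION_S = 300.0
TRAVEL_DELAY_S = 8.0
DECISION_INTERVAL_S = 3.5
FAIRNESS_FLOOR = 0.05
START_PROPORTION = 0.5

FIRST_OFFER_BOUNDS = {
    "S12": (0.475, 0.525),
    "S3": (0.475, 0.525),
    "S4": (0.47, 0.53),
}

# Fair partners decay slowly, unfair partners fast.
DECAY_RATES = {
    "S12": {"fair": (-0.125,), "unfair": (-0.2,)},
    "S3": {"fair": (-0.125,), "unfair": (-0.2,)},
    "S4": {
        "fair": tuple(np.round(np.arange(-0.075, -0.1151, -0.005), 3)),
        "unfair": tuple(np.round(np.arange(-0.140, -0.1751, -0.005), 3)),
    },
}

S4_TRAJECTORY_NOISE_SD = 0.015

CREDIT_BLOCK_LEN = 6
CREDIT_BLOCK_SUM = 500
CREDIT_BOUNDS = (50, 200)
ZERO_STAKE_BOUNDS = (200.0, 2000.0)

S4_CREDIT_MEAN = 400.0
S4_CREDIT_SD = 30.0
S4_DISPLAY_S = 1.0
S4_JITTER_BOUNDS = (2.0, 3.0)  # uniform; mean 2.5 s, so trials average 3.5 s

FAIRNESS_RULE = {"S12": "zero_replace", "S3": "clamp", "S4": "clamp"}

GROUPS_PER_SESSION = {"S12": 8, "S3": 8, "S4": 10}
ENVIRONMENT_TYPES = {
    "S12": ("high_generosity", "low_generosity"),
    "S3": ("high_effort", "low_effort"),
    "S4": ("high_generosity", "low_generosity"),
}

# Partners are pre-built well beyond what a 300 s block can consume.
PARTNERS_PER_GROUP = 60

# fair count per consecutive window of partners
COMPOSITION_WINDOWS = {
    "high_generosity": (4, 3),  # 3 fair : 1 unfair per window of 4
    "low_generosity": (4, 1),
    "high_effort": (2, 1),  # 1:1 overall, balanced in every pair
    "low_effort": (2, 1),
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PartnerSpec:
    """One partner's generative parameters."""

    decay_rate: float
    fairness_class: str  # "fair" | "unfair"
    study_variant: str
    n_decisions: int = N_DECISIONS

    def __post_init__(self):
        if self.study_variant not in STUDY_VARIANTS:
            raise ValueError(f"unknown study variant {self.study_variant!r}")
        if self.fairness_class not in ("fair", "unfair"):
            raise ValueError(f"unknown fairness class {self.fairness_class!r}")
        allowed = DECAY_RATES[self.study_variant][self.fairness_class]
        if not any(np.isclose(self.decay_rate, a) for a in allowed):
            raise ValueError(
                f"decay rate {self.decay_rate} not valid for "
                f"{self.study_variant}/{self.fairness_class}"
            )


@dataclass(frozen=True)
class SharingDecision:
    trial_index: int
    proportion: float
    stake: float
    credits_shared: float
    onset_time: float


@dataclass
class PartnerTrajectory:
    """One partner's full 30-decision stream, as arrays plus metadata.

    ``credit_values`` holds the sampled absolute credit amounts (the values
    constrained to sum to 500 per six-decision block in S12/S3);
    ``credits_shared`` equals them except on zero-proportion trials, where
    nothing is shared.
    """

    spec: PartnerSpec
    proportions: np.ndarray
    stakes: np.ndarray
    credit_values: np.ndarray
    credits_shared: np.ndarray
    onsets: np.ndarray
    durations: np.ndarray
    first_offer_bounds: tuple[float, float]

    @property
    def decisions(self) -> list[SharingDecision]:
        return [
            SharingDecision(i, float(self.proportions[i]), float(self.stakes[i]),
                            float(self.credits_shared[i]), float(self.onsets[i]))
            for i in range(len(self.proportions))
        ]

    @property
    def horizon(self) -> float:
        """End of the interaction if the agent never leaves."""
        return float(self.onsets[-1] + self.durations[-1])

    @property
    def censor_time(self) -> float:
        """Onset of the final sharing decision (the censoring value)."""
        return float(self.onsets[-1])


@dataclass
class GroupSpec:
    environment_type: str
    study_variant: str
    partners: list[PartnerTrajectory]
    duration: float = BLOCK_DURATION_S
    border_label: str = ""

    def __post_init__(self):
        if not self.border_label:
            self.border_label = self.environment_type.replace("_", " ")


@dataclass
class SessionSpec:
    study_variant: str
    groups: list[GroupSpec]
    travel_delay: float = TRAVEL_DELAY_S
    decision_interval: float = DECISION_INTERVAL_S
    group_order_seed: int = 0

    def to_json(self) -> str:
        """Serialize the session structure (not the full trajectories)."""
        return json.dumps(
            {
                "study_variant": self.study_variant,
                "travel_delay": self.travel_delay,
                "decision_interval": self.decision_interval,
                "group_order_seed": self.group_order_seed,
                "groups": [
                    {
                        "environment_type": g.environment_type,
                        "n_partners": len(g.partners),
                        "duration": g.duration,
                    }
                    for g in self.groups
                ],
            },
            indent=2,
        )


@dataclass(frozen=True)
class EffortCalibration:
    """Participant-specific press calibration for the effort manipulation."""

    max_presses: int
    low_fraction: float = 0.20
    high_fraction: float = 0.90

    def __post_init__(self):
        if self.max_presses <= 0:
            raise ValueError("max_presses must be positive")
        if not 0 < self.low_fraction < self.high_fraction <= 1:
            raise ValueError("need 0 < low_fraction < high_fraction <= 1")


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def decay_proportion(s: float, decay_rate: float, trial_index: int) -> float:
    """Raw exponential-decay proportion ``s * exp(decay_rate * t)``.

    No floor or zero-replacement rule is applied here.
    """
    if trial_index < 0:
        raise ValueError("trial_index must be non-negative")
    return float(s * np.exp(decay_rate * trial_index))


def apply_fairness_rule(raw_proportions, mode: str) -> np.ndarray:
    """Apply the sub-0.05 rule: replace with zero (S12) or clamp (S3/S4)."""
    raw = np.asarray(raw_proportions, dtype=float)
    if mode == "zero_replace":
        return np.where(raw < FAIRNESS_FLOOR, 0.0, raw)
    if mode == "clamp":
        return np.maximum(raw, FAIRNESS_FLOOR)
    raise ValueError(f"unknown fairness rule mode {mode!r}")


def sample_first_offer(variant: str, rng: np.random.Generator) -> float:
    """First-offer proportion: uniform on the variant's bounds around 0.5."""
    lo, hi = FIRST_OFFER_BOUNDS[variant]
    return float(rng.uniform(lo, hi))


def noisy_trajectory_s4(spec: PartnerSpec, rng: np.random.Generator) -> np.ndarray:
    """S4 proportion sequence: decay + N(0, 0.015) noise, clamped at 0.05.

    The noise applies to trials 1..29; trial 0 is the separate first-offer
    draw. Clamping runs after the noise.
    """
    if spec.study_variant != "S4":
        raise ValueError("noisy trajectories are an S4 feature")
    t = np.arange(spec.n_decisions)
    raw = START_PROPORTION * np.exp(spec.decay_rate * t)
    raw[1:] += rng.normal(0.0, S4_TRAJECTORY_NOISE_SD, size=spec.n_decisions - 1)
    raw[0] = sample_first_offer("S4", rng)
    return apply_fairness_rule(raw, "clamp")


def sample_credit_block(rng: np.random.Generator) -> np.ndarray:
    """Six integer credit values in [50, 200] summing exactly to 500.

    Sampler: draw six i.i.d. uniforms on [50, 200], rescale them to sum to
    500, repair any bound violations by clipping and redistributing the
    residual over unclipped entries, then round to integers while preserving
    the total exactly.
    """
    lo, hi = CREDIT_BOUNDS
    x = rng.uniform(lo, hi, size=CREDIT_BLOCK_LEN)
    x *= CREDIT_BLOCK_SUM / x.sum()
    for _ in range(CREDIT_BLOCK_LEN):
        clipped = np.clip(x, lo, hi)
        resid = CREDIT_BLOCK_SUM - clipped.sum()
        if abs(resid) < 1e-9:
            x = clipped
            break
        free = (clipped > lo) & (clipped < hi)
        if not free.any():  # pragma: no cover - cannot happen for sum 500
            x = clipped
            break
        clipped[free] += resid / free.sum()
        x = clipped
    # largest-remainder rounding preserving the 500 total
    floors = np.floor(x).astype(int)
    short = CREDIT_BLOCK_SUM - floors.sum()
    order = np.argsort(-(x - floors))
    floors[order[:short]] += 1
    return np.clip(floors, lo, hi)


def stake_from_credits(credits: float, proportion: float,
                       rng: np.random.Generator | None = None) -> float:
    """Stake = credits / proportion; uniform [200, 2000] on zero offers."""
    if credits < 0 or proportion < 0:
        raise ValueError("credits and proportion must be non-negative")
    if proportion > 0:
        return float(credits / proportion)
    if rng is None:
        raise ValueError("rng required for zero-proportion stakes")
    return float(rng.uniform(*ZERO_STAKE_BOUNDS))


def sample_credits_s4(rng: np.random.Generator, size=None,
                      mean: float = S4_CREDIT_MEAN, sd: float = S4_CREDIT_SD):
    """S4 credits shared per decision: Normal(400, 30)."""
    return rng.normal(mean, sd, size=size)


def sample_trial_duration_s4(rng: np.random.Generator, size=None,
                             jitter_bounds=S4_JITTER_BOUNDS):
    """S4 trial duration: 1 s display + uniform jitter with mean 2.5 s."""
    return S4_DISPLAY_S + rng.uniform(*jitter_bounds, size=size)


def effort_requirement(cal: EffortCalibration, environment_type: str) -> int:
    """Required presses during travel: a rounded fraction of the maximum."""
    if environment_type == "low_effort":
        return int(round(cal.low_fraction * cal.max_presses))
    if environment_type == "high_effort":
        return int(round(cal.high_fraction * cal.max_presses))
    raise ValueError(f"{environment_type!r} is not an effort environment")


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------


def build_partner(spec: PartnerSpec, rng: np.random.Generator) -> PartnerTrajectory:
    """Realize one partner's 30-decision stream for its study variant."""
    variant = spec.study_variant
    n = spec.n_decisions
    if variant == "S4":
        proportions = noisy_trajectory_s4(spec, rng)
        credit_values = np.maximum(sample_credits_s4(rng, size=n), 0.0)
        credits_shared = credit_values.copy()
        stakes = credit_values / proportions
        durations = sample_trial_duration_s4(rng, size=n)
        onsets = np.concatenate([[0.0], np.cumsum(durations[:-1])])
    else:
        t = np.arange(n)
        raw = START_PROPORTION * np.exp(spec.decay_rate * t)
        raw[0] = sample_first_offer(variant, rng)
        proportions = apply_fairness_rule(raw, FAIRNESS_RULE[variant])
        blocks = [sample_credit_block(rng) for _ in range(n // CREDIT_BLOCK_LEN)]
        credit_values = np.concatenate(blocks).astype(float)
        credits_shared = np.where(proportions > 0, credit_values, 0.0)
        stakes = np.array([
            stake_from_credits(c, p, rng)
            for c, p in zip(credit_values, proportions)
        ])
        durations = np.full(n, DECISION_INTERVAL_S)
        onsets = t * DECISION_INTERVAL_S
    return PartnerTrajectory(
        spec=spec,
        proportions=proportions,
        stakes=stakes,
        credit_values=credit_values,
        credits_shared=credits_shared,
        onsets=onsets.astype(float),
        durations=durations,
        first_offer_bounds=FIRST_OFFER_BOUNDS[variant],
    )


def _partner_classes(environment_type: str, n_partners: int,
                     rng: np.random.Generator) -> list[str]:
    """Fair/unfair labels satisfying the windowed composition constraint."""
    win, n_fair = COMPOSITION_WINDOWS[environment_type]
    classes: list[str] = []
    while len(classes) < n_partners:
        window = ["fair"] * n_fair + ["unfair"] * (win - n_fair)
        rng.shuffle(window)
        classes.extend(window)
    return classes[:n_partners]


def build_group(environment_type: str, study_variant: str,
                rng: np.random.Generator,
                n_partners: int = PARTNERS_PER_GROUP) -> GroupSpec:
    """Build one 300 s social environment with its partner queue."""
    if environment_type not in ENVIRONMENT_TYPES[study_variant]:
        raise ValueError(
            f"{environment_type!r} is not an environment of {study_variant}")
    partners = []
    for cls in _partner_classes(environment_type, n_partners, rng):
        rates = DECAY_RATES[study_variant][cls]
        rate = float(rates[rng.integers(len(rates))])
        spec = PartnerSpec(decay_rate=rate, fairness_class=cls,
                           study_variant=study_variant)
        partners.append(build_partner(spec, rng))
    return GroupSpec(environment_type=environment_type,
                     study_variant=study_variant, partners=partners)


def build_session(study_variant: str, rng: np.random.Generator,
                  n_partners_per_group: int = PARTNERS_PER_GROUP,
                  n_groups: int | None = None) -> SessionSpec:
    """Build a full session: equal numbers of each environment, shuffled.

    ``n_groups`` defaults to the variant's schedule (8 for S12/S3, 10 for
    S4); it may be reduced (even) for desk-scale studies.
    """
    if n_groups is None:
        n_groups = GROUPS_PER_SESSION[study_variant]
    if n_groups % 2:
        raise ValueError("n_groups must be even (balanced environments)")
    env_a, env_b = ENVIRONMENT_TYPES[study_variant]
    env_order = [env_a] * (n_groups // 2) + [env_b] * (n_groups // 2)
    rng.shuffle(env_order)
    groups = [
        build_group(env, study_variant, rng, n_partners=n_partners_per_group)
        for env in env_order
    ]
    return SessionSpec(study_variant=study_variant, groups=groups)


# ---------------------------------------------------------------------------
# Serialization / config
# ---------------------------------------------------------------------------


def session_to_frame(session: SessionSpec, participant_id: str = "p0"):
    """One row per sharing decision, in the session-log CSV layout."""
    import pandas as pd

    rows = []
    for gi, group in enumerate(session.groups):
        for pi, partner in enumerate(group.partners):
            for d in partner.decisions:
                rows.append({
                    "participant_id": participant_id,
                    "study_variant": session.study_variant,
                    "group_index": gi,
                    "environment_type": group.environment_type,
                    "partner_index": pi,
                    "decay_rate": partner.spec.decay_rate,
                    "trial_index": d.trial_index,
                    "onset_s": d.onset_time,
                    "proportion": d.proportion,
                    "stake": d.stake,
                    "credits_shared": d.credits_shared,
                })
    return pd.DataFrame(rows)


def default_config() -> dict:
    """All task constants, suitable for YAML round-tripping."""
    return {
        "n_decisions": N_DECISIONS,
        "block_duration_s": BLOCK_DURATION_S,
        "travel_delay_s": TRAVEL_DELAY_S,
        "decision_interval_s": DECISION_INTERVAL_S,
        "fairness_floor": FAIRNESS_FLOOR,
        "start_proportion": START_PROPORTION,
        "first_offer_bounds": {k: list(v) for k, v in FIRST_OFFER_BOUNDS.items()},
        "decay_rates": {
            k: {c: [float(r) for r in v] for c, v in d.items()}
            for k, d in DECAY_RATES.items()
        },
        "fairness_rule": dict(FAIRNESS_RULE),
        "credit_block": {"len": CREDIT_BLOCK_LEN, "sum": CREDIT_BLOCK_SUM,
                         "bounds": list(CREDIT_BOUNDS)},
        "zero_stake_bounds": list(ZERO_STAKE_BOUNDS),
        "s4": {"credit_mean": S4_CREDIT_MEAN, "credit_sd": S4_CREDIT_SD,
               "display_s": S4_DISPLAY_S, "jitter_bounds": list(S4_JITTER_BOUNDS),
               "trajectory_noise_sd": S4_TRAJECTORY_NOISE_SD},
        "groups_per_session": dict(GROUPS_PER_SESSION),
        "effort_fractions": {"low": 0.20, "high": 0.90},
    }


def dump_config(path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(default_config(), fh, sort_keys=False)
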
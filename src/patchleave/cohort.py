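"""Synthetic participant cohorts for the behavioural analysis stage.

A cohort is a set of simulated agents, each an instance of the fairness
drift-diffusion model with heterogeneous parameters:

* a between-subject Normal spread on each DDM parameter;
* a planted threshold increase in the low-generosity environment (the
  opportunity-cost effect the fitting stage should recover);
* an optional covariate mechanism: depression or loneliness score
  (standardised) scales the drift gain in the low-generosity environment
  only, planting a three-way partner x environment x score pattern.

Scores emulate the DASS-21 depression subscale (range 0-42) and the De Jong
Gierveld loneliness scale (range 0-6) as correlated truncated normals whose
truncated moments match the stated mean/SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import ddm, task

__all__ = [
    "ScoreDistribution",
    "ParticipantProfile",
    "CohortSpec",
    "sample_cohort",
    "generate_behaviour",
]

# parameter ranges representable on the published grid
PARAM_CLIP = {
    "threshold": (1.0, 30.0),
    "drift_gain": (0.1, 1.5),
    "noise_sd": (0.1, 1.0),
    "start_bias": (0.0, 0.8),
}

DEPRESSION_RANGE = (0.0, 42.0)
LONELINESS_RANGE = (0.0, 6.0)
DEPRESSION_MOMENTS = (6.2, 5.9)
LONELINESS_MOMENTS = (3.4, 1.8)


@dataclass(frozen=True)
class ScoreDistribution:
    """Truncated normal whose *truncated* mean/SD match the targets."""

    mean: float
    sd: float
    lower: float
    upper: float

    def parent_params(self) -> tuple[float, float]:
        """(mu, sigma) of the parent normal giving the target moments."""

        def moments(x):
            mu, sig = x
            sig = abs(sig)
            a, b = (self.lower - mu) / sig, (self.upper - mu) / sig
            m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sig,
                                         moments="mv")
            return [m - self.mean, np.sqrt(v) - self.sd]

        sol = optimize.root(moments, x0=[self.mean, self.sd], method="hybr")
        mu, sig = sol.x
        return float(mu), float(abs(sig))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        mu, sig = self.parent_params()
        a, b = (self.lower - mu) / sig, (self.upper - mu) / sig
        u = rng.uniform(size=size)
        return stats.truncnorm.ppf(u, a, b, loc=mu, scale=sig)


DEPRESSION_DIST = ScoreDistribution(*DEPRESSION_MOMENTS, *DEPRESSION_RANGE)
LONELINESS_DIST = ScoreDistribution(*LONELINESS_MOMENTS, *LONELINESS_RANGE)


@dataclass
class ParticipantProfile:
    participant_id: str
    params_by_environment: dict  # environment_type -> DDMParams
    depression_score: float
    loneliness_score: float
    attention_fail_rate: float = 0.0


@dataclass
class CohortSpec:
    """Generative description of a synthetic cohort.

    ``covariate_effect`` adds ``effect * z(score)`` to the drift gain in the
    low-generosity environment only — one of several mechanisms consistent
    with a stronger fairness sensitivity among high scorers in poor
    environments; it is a modelling choice, not an identified result.
    """

    n_participants: int
    base_params: ddm.DDMParams
    threshold_shift_low_env: float = 0.0
    between_subject_sd: dict = field(default_factory=dict)
    covariate: str = "depression"          # "none" | "depression" | "loneliness"
    covariate_effect: float = 0.0
    score_correlation: float = 0.5
    attention_fail_rate: float = 0.0
    depression_dist: ScoreDistribution = DEPRESSION_DIST
    loneliness_dist: ScoreDistribution = LONELINESS_DIST
    seed: int | None = None

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.covariate not in ("none", "depression", "loneliness"):
            raise ValueError(f"unknown covariate {self.covariate!r}")


def _clipped(base: ddm.DDMParams, **raw) -> ddm.DDMParams:
    """Build params from raw (possibly out-of-range) values, clipped to the
    grid-representable ranges before the dataclass validates them."""
    kw = {}
    for name, (lo, hi) in PARAM_CLIP.items():
        kw[name] = float(np.clip(raw.get(name, getattr(base, name)), lo, hi))
    # starting bias must stay strictly below threshold
    kw["start_bias"] = min(kw["start_bias"], kw["threshold"] - 1e-9)
    return replace(base, **kw)


def _correlated_scores(spec: CohortSpec, rng: np.random.Generator,
                       n: int) -> tuple[np.ndarray, np.ndarray]:
    """Correlated (depression, loneliness) via a Gaussian copula."""
    rho = spec.score_correlation
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    u = stats.norm.cdf(z)
    mu_d, sig_d = spec.depression_dist.parent_params()
    mu_l, sig_l = spec.loneliness_dist.parent_params()
    a_d, b_d = [(x - mu_d) / sig_d for x in
                (spec.depression_dist.lower, spec.depression_dist.upper)]
    a_l, b_l = [(x - mu_l) / sig_l for x in
                (spec.loneliness_dist.lower, spec.loneliness_dist.upper)]
    dep = stats.truncnorm.ppf(u[:, 0], a_d, b_d, loc=mu_d, scale=sig_d)
    lon = stats.truncnorm.ppf(u[:, 1], a_l, b_l, loc=mu_l, scale=sig_l)
    return dep, lon


def sample_cohort(spec: CohortSpec,
                  rng: np.random.Generator | None = None
                  ) -> list[ParticipantProfile]:
    """Draw a cohort of participant profiles from the generative spec."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    dep, lon = _correlated_scores(spec, rng, n)
    # standardise against the instrument's stated moments, not the sample
    z_dep = (dep - spec.depression_dist.mean) / spec.depression_dist.sd
    z_lon = (lon - spec.loneliness_dist.mean) / spec.loneliness_dist.sd
    z_cov = {"none": np.zeros(n), "depression": z_dep,
             "loneliness": z_lon}[spec.covariate]

    profiles = []
    sds = spec.between_subject_sd
    for i in range(n):
        dev = {name: rng.normal(0.0, sds.get(name, 0.0))
               for name in PARAM_CLIP}
        # zero-mean per-environment threshold jitter: heterogeneity in the
        # environment response without any mean environment effect, so the
        # random-slope structure of the analysis model is non-degenerate
        env_jit = rng.normal(0.0, sds.get("threshold_env", 0.0), size=2)
        base_theta = spec.base_params.threshold + dev["threshold"]
        high = _clipped(
            spec.base_params,
            threshold=base_theta + env_jit[0],
            drift_gain=spec.base_params.drift_gain + dev["drift_gain"],
            noise_sd=spec.base_params.noise_sd + dev["noise_sd"],
            start_bias=spec.base_params.start_bias + dev["start_bias"],
        )
        low = _clipped(
            high,
            threshold=(base_theta + env_jit[1]
                       + spec.threshold_shift_low_env),
            drift_gain=high.drift_gain + spec.covariate_effect * z_cov[i],
        )
        profiles.append(ParticipantProfile(
            participant_id=f"p{i:03d}",
            params_by_environment={"high_generosity": high,
                                   "low_generosity": low,
                                   "high_effort": high,
                                   "low_effort": low},
            depression_score=float(dep[i]),
            loneliness_score=float(lon[i]),
            attention_fail_rate=spec.attention_fail_rate,
        ))
    return profiles


def _attention_checks(session: task.SessionSpec, n_visited_by_group: list,
                      fail_rate: float, rng: np.random.Generator
                      ) -> tuple[int, int]:
    """S4 attention checks: 3 of the first 5 partners of every group.

    A check only counts if the participant actually reached that partner.
    Returns (n_checks_encountered, n_failed).
    """
    n_checks = n_failed = 0
    for gi, group in enumerate(session.groups):
        slots = rng.choice(5, size=3, replace=False)
        for slot in slots:
            if slot < n_visited_by_group[gi]:
                n_checks += 1
                if rng.random() < fail_rate:
                    n_failed += 1
    return n_checks, n_failed


def generate_behaviour(cohort: list, study_variant: str,
                       rng: np.random.Generator | None = None,
                       n_groups: int | None = None,
                       n_partners_per_group: int = task.PARTNERS_PER_GROUP,
                       noise_scaling: str = "euler"
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate full sessions for a cohort.

    Returns ``(lt_table, scores)``: one leaving-time record per interaction,
    and one row per participant with covariate scores and the attention
    failure fraction (S4 only; zero checks otherwise).
    """
    if not cohort:
        raise ValueError("cohort is empty")
    if rng is None:
        rng = np.random.default_rng()
    lt_frames, score_rows = [], []
    for profile in cohort:
        session = task.build_session(study_variant, rng,
                                     n_partners_per_group=n_partners_per_group,
                                     n_groups=n_groups)
        records = ddm.simulate_participant_session(
            profile.params_by_environment, session, rng,
            participant_id=profile.participant_id,
            noise_scaling=noise_scaling)
        lt_frames.append(records)
        if study_variant == "S4":
            visited = (records.groupby("group_index")["partner_index"]
                       .max().add(1).reindex(range(len(session.groups)),
                                             fill_value=0).tolist())
            n_checks, n_failed = _attention_checks(
                session, visited, profile.attention_fail_rate, rng)
        else:
            n_checks = n_failed = 0
        score_rows.append({
            "participant_id": profile.participant_id,
            "depression": profile.depression_score,
            "loneliness": profile.loneliness_score,
            "attention_checks": n_checks,
            "attention_failed": n_failed,
            "attention_fail_frac": (n_failed / n_checks) if n_checks else 0.0,
        })
    return pd.concat(lt_frames, ignore_index=True), pd.DataFrame(score_rows)
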
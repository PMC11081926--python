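"""Model- and parameter-recovery studies for the leaving-DDM fitting stage.

A recovery study generates synthetic subjects from a known DDM variant with
known parameters, runs the same grid-search KS-likelihood fit used for real
data, and asks whether (i) BIC comparison selects the generating variant
(model recovery) and (ii) the fitted thresholds track the true ones
(parameter recovery).  Subject data are drawn from the environment-mixture
sampler the fitting procedure assumes, so the study isolates the estimator
itself.

Desk-scale defaults: the reduced 8x8x5x3 grid with 200 simulations per
point, dt = 0.005 s for both generation and fitting, 20 subjects per
generating variant and ~40 leaving times per environment — sized so a full
three-variant recovery runs in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import task
from .ddm import DDMParams, simulate_lt_distribution
from .fitting import (GridSpec, LeavingTimeDDM, compare_models,
                      simulate_grid, threshold_environment_contrast)

__all__ = [
    "RECOVERY_DT",
    "GENERATING_PARAMS",
    "make_environments",
    "sample_recovery_cohort",
    "simulate_recovery_banks",
    "ModelRecoveryResult",
    "model_recovery_study",
    "ParameterRecoveryResult",
    "parameter_recovery_study",
]

RECOVERY_DT = 0.005
THETA_POOL = (6.0, 10.0, 14.0, 18.0, 22.0)  # on the reduced grid
THRESHOLD_SHIFT_LOW = 4.0                   # one reduced-grid step

# per-variant generating bases; drift for the reward variant sits above the
# mean scaled reward (~0.83 for the 500/6-credit schedule) so crossings occur
GENERATING_PARAMS = {
    "standard": dict(drift_gain=0.3, noise_sd=0.3, start_bias=0.0),
    "reward": dict(drift_gain=1.1, noise_sd=0.3, start_bias=0.0),
    "fairness": dict(drift_gain=0.5, noise_sd=0.3, start_bias=0.0),
}


def parameter_recovery_grid(n_sims_per_point: int = 1000) -> GridSpec:
    """Reduced grid restricted to the noise_sd <= 0.5 regime.

    Threshold recovery is studied where the diffusion noise stays at or
    below 0.5: larger noise values let high-threshold/high-drift/high-noise
    parameter sets mimic the leaving-time distributions of low-threshold
    sets, and the KS likelihood cannot separate them at realistic
    per-subject sample sizes.
    """
    return GridSpec(
        threshold_values=(2, 6, 10, 14, 18, 22, 26, 30),
        drift_gain_values=(0.1, 0.3, 0.5, 0.7, 0.9, 1.1, 1.3, 1.5),
        noise_sd_values=(0.1, 0.3, 0.5),
        start_bias_values=(0.0, 0.4, 0.8),
        n_sims_per_point=n_sims_per_point,
    )


def make_environments(study_variant: str = "S12",
                      seed: int | None = 0) -> dict:
    """High/low generosity GroupSpecs used as mixture descriptors."""
    rng = np.random.default_rng(seed)
    # small partner queues: only the composition matters to the sampler
    return {
        env: task.build_group(env, study_variant, rng, n_partners=4)
        for env in task.ENVIRONMENT_TYPES[study_variant]
    }


def sample_recovery_cohort(variant: str, n_subjects: int,
                           rng: np.random.Generator,
                           environments: dict,
                           n_obs_per_env: int = 40,
                           threshold_shift_low: float = THRESHOLD_SHIFT_LOW,
                           dt: float = RECOVERY_DT):
    """Synthetic subjects with grid-valued thresholds; returns (data, truth).

    Each subject draws a threshold from the reduced-grid pool; the
    low-generosity threshold adds ``threshold_shift_low``.  Leaving times
    are drawn from the environment mixture with the subject's parameters.
    """
    base = GENERATING_PARAMS[variant]
    rows, truth = [], []
    for i in range(n_subjects):
        theta = float(rng.choice(THETA_POOL))
        pid = f"{variant[:2]}{i:03d}"
        for env in sorted(environments):
            th = theta + (threshold_shift_low if env.startswith("low") else 0.0)
            params = DDMParams(variant=variant, threshold=th, dt=dt, **base)
            lts = simulate_lt_distribution(params, environments[env],
                                           n_obs_per_env, rng)
            rows.extend({"participant_id": pid, "environment_type": env,
                         "leaving_time_s": float(lt)} for lt in lts)
            truth.append({"participant_id": pid, "environment_type": env,
                          "true_threshold": th})
    return pd.DataFrame(rows), pd.DataFrame(truth)


def simulate_recovery_banks(environments: dict, grid: GridSpec,
                            seed: int, variants=("standard", "reward",
                                                 "fairness"),
                            dt: float = RECOVERY_DT) -> dict:
    """Paired grid banks per (variant, environment); the expensive step.

    Returns ``{variant: {env: (bank, refine_bank)}}``.  All variants reuse
    the same seeds, so their banks share partner draws and noise streams —
    common random numbers across models as well as across grid points,
    which keeps cross-variant likelihood differences free of independent
    simulation noise.  The second (refine) bank is an independent
    replicate used to re-score the top decile of the search, stripping
    max-selection optimism from the reported likelihood.
    """
    banks = {}
    for variant in variants:
        rng = np.random.default_rng(seed)
        rng_refine = np.random.default_rng(seed + 500_009)
        banks[variant] = {
            env: (simulate_grid(variant, spec, grid, rng, dt=dt),
                  simulate_grid(variant, spec, grid, rng_refine, dt=dt))
            for env, spec in sorted(environments.items())
        }
    return banks


def _split_banks(variant_banks: dict):
    fit_banks = {env: pair[0] for env, pair in variant_banks.items()}
    refine = {env: pair[1] for env, pair in variant_banks.items()}
    return fit_banks, refine


@dataclass
class ModelRecoveryResult:
    confusion: pd.DataFrame          # generating variant x winning variant
    cohort_bic: pd.DataFrame         # generating variant x fitted variant
    cohort_winners: dict             # generating variant -> BIC-best variant

    @property
    def diagonally_dominant(self) -> bool:
        c = self.confusion
        return all(c.loc[g, g] > c.loc[g].drop(g).max() for g in c.index)


def model_recovery_study(n_subjects: int = 20, grid: GridSpec | None = None,
                         seed: int = 0, n_obs_per_env: int = 40,
                         dt: float = RECOVERY_DT,
                         environments: dict | None = None,
                         banks: dict | None = None) -> ModelRecoveryResult:
    """Full three-way confusion study: generate from each variant, fit all."""
    grid = grid or GridSpec.reduced(200)
    environments = environments or make_environments("S12", seed)
    if banks is None:
        banks = simulate_recovery_banks(environments, grid, seed)
    variants = list(banks)
    confusion = pd.DataFrame(0, index=variants, columns=variants, dtype=int)
    cohort_bic = pd.DataFrame(np.nan, index=variants, columns=variants)
    winners = {}
    for g, gen in enumerate(variants):
        rng = np.random.default_rng(seed + 977 * (g + 1))
        data, _ = sample_recovery_cohort(gen, n_subjects, rng, environments,
                                         n_obs_per_env=n_obs_per_env, dt=dt)
        results = []
        for fitv in variants:
            model = LeavingTimeDDM(data, fitv, environments, grid=grid, dt=dt)
            fit_banks, refine = _split_banks(banks[fitv])
            results.append(model.fit(banks=fit_banks, refine_banks=refine))
        comp = compare_models(results)
        for pid, win in comp.winners.items():
            confusion.loc[gen, win] += 1
        for fitv in variants:
            cohort_bic.loc[gen, fitv] = comp.summed_bic[fitv]
        winners[gen] = comp.best_variant
    return ModelRecoveryResult(confusion=confusion, cohort_bic=cohort_bic,
                               cohort_winners=winners)


@dataclass
class ParameterRecoveryResult:
    truth: pd.DataFrame
    fitted: pd.DataFrame
    spearman_threshold: float
    contrast: object  # ThresholdContrast

    def merged(self) -> pd.DataFrame:
        return self.truth.merge(self.fitted, on=["participant_id",
                                                 "environment_type"])


def parameter_recovery_study(n_subjects: int = 20,
                             grid: GridSpec | None = None, seed: int = 0,
                             n_obs_per_env: int = 40,
                             threshold_shift_low: float = THRESHOLD_SHIFT_LOW,
                             dt: float = RECOVERY_DT,
                             environments: dict | None = None,
                             banks: dict | None = None
                             ) -> ParameterRecoveryResult:
    """Fairness-DDM threshold recovery with a planted low-environment shift."""
    grid = grid or GridSpec.reduced(200)
    environments = environments or make_environments("S12", seed)
    rng = np.random.default_rng(seed + 55_001)
    data, truth = sample_recovery_cohort(
        "fairness", n_subjects, rng, environments,
        n_obs_per_env=n_obs_per_env,
        threshold_shift_low=threshold_shift_low, dt=dt)
    model = LeavingTimeDDM(data, "fairness", environments, grid=grid, dt=dt)
    if banks is not None:
        fit_banks, refine = _split_banks(banks["fairness"])
        results = model.fit(banks=fit_banks, refine_banks=refine)
    else:
        results = model.fit(seed=seed)
    fitted = (results.frame()
              .rename(columns={"environment": "environment_type",
                               "theta": "fitted_threshold"})
              [["participant_id", "environment_type", "fitted_threshold"]])
    merged = truth.merge(fitted, on=["participant_id", "environment_type"])
    rho = float(sps.spearmanr(merged["true_threshold"],
                              merged["fitted_threshold"]).statistic)
    contrast = threshold_environment_contrast(results)
    return ParameterRecoveryResult(truth=truth, fitted=fitted,
                                   spearman_threshold=rho,
                                   contrast=contrast)
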
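"""Grid-search fitting of leaving-DDM variants and BIC model comparison.

The likelihood of a parameter set is built from a two-sample
Kolmogorov-Smirnov comparison between the observed leaving-time (LT)
distribution and a model-simulated one:

    LL = sum over conditions of log KS_p(LT_data, LT_model)

where the condition is the social environment.  Each environment is fitted
separately (4 free parameters each: threshold, drift gain, noise sd,
starting bias) by exhaustive search over a parameter grid, and variants are
compared by BIC = k ln(n) - 2 LL summed across environments and
participants, plus the proportion of participants each variant wins.

Because simulated LT distributions depend only on the environment mixture
(not on the participant), the grid of model distributions is simulated once
per (variant, environment) and shared across participants, with common
random numbers across grid points so the argmax is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ddm import DDMParams, DEFAULT_DT, DEFAULT_REWARD_SCALE, VARIANTS
from .ddm import _fp_noise_bank, sample_signal_bank
from .task import GroupSpec

__all__ = [
    "GridSpec",
    "GridBank",
    "FitResult",
    "ModelComparison",
    "ks_pvalue",
    "ks_log_likelihood",
    "bic",
    "simulate_grid",
    "grid_search_fit",
    "LeavingTimeDDM",
    "LeavingTimeDDMResults",
    "compare_models",
    "predicted_vs_observed",
    "threshold_environment_contrast",
]

P_FLOOR = 1e-300
N_PARAMS_PER_ENVIRONMENT = 4


@dataclass(frozen=True)
class GridSpec:
    """Parameter grid for the exhaustive search.

    The default reproduces the published grid (22,500 points); ``reduced``
    is the desk-scale 8 x 8 x 5 x 3 subset used by the recovery studies.
    """

    threshold_values: tuple = tuple(range(1, 31))
    drift_gain_values: tuple = tuple(np.round(np.arange(0.1, 1.51, 0.1), 2))
    noise_sd_values: tuple = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))
    start_bias_values: tuple = (0.0, 0.2, 0.4, 0.6, 0.8)
    n_sims_per_point: int = 1000
    seed_policy: str = "common_random_numbers"

    @classmethod
    def reduced(cls, n_sims_per_point: int = 200) -> "GridSpec":
        return cls(
            threshold_values=(2, 6, 10, 14, 18, 22, 26, 30),
            drift_gain_values=(0.1, 0.3, 0.5, 0.7, 0.9, 1.1, 1.3, 1.5),
            noise_sd_values=(0.1, 0.3, 0.5, 0.7, 0.9),
            start_bias_values=(0.0, 0.4, 0.8),
            n_sims_per_point=n_sims_per_point,
        )

    def points(self) -> np.ndarray:
        """(n_points, 4) array in lexicographic (theta, k, sigma, eps) order."""
        grids = np.meshgrid(self.threshold_values, self.drift_gain_values,
                            self.noise_sd_values, self.start_bias_values,
                            indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=1).astype(float)

    @property
    def n_points(self) -> int:
        return (len(self.threshold_values) * len(self.drift_gain_values)
                * len(self.noise_sd_values) * len(self.start_bias_values))


@dataclass
class GridBank:
    """Simulated LT samples for every grid point of one (variant, environment)."""

    variant: str
    environment_type: str
    points: np.ndarray  # (n_points, 4)
    lts: np.ndarray     # (n_points, n_sims), censored sims at censor value

    def params_at(self, idx: int, dt: float = DEFAULT_DT,
                  reward_scale: float = DEFAULT_REWARD_SCALE) -> DDMParams:
        th, k, sg, ep = self.points[idx]
        return DDMParams(variant=self.variant, threshold=th, drift_gain=k,
                         noise_sd=sg, start_bias=ep, dt=dt,
                         reward_scale=reward_scale)


# ---------------------------------------------------------------------------
# Likelihood primitives
# ---------------------------------------------------------------------------


def ks_pvalue(sample_a, sample_b) -> float:
    """Asymptotic two-sample Kolmogorov-Smirnov p-value."""
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS samples must be non-empty")
    return float(stats.ks_2samp(a, b, method="asymp").pvalue)


def ks_log_likelihood(data_by_condition: dict, model_by_condition: dict) -> float:
    """Sum over conditions of log KS p-values (floored at 1e-300)."""
    if set(data_by_condition) != set(model_by_condition):
        raise ValueError("condition keys differ between data and model")
    ll = 0.0
    for cond in data_by_condition:
        p = ks_pvalue(data_by_condition[cond], model_by_condition[cond])
        ll += np.log(max(p, P_FLOOR))
    return float(ll)


def bic(log_likelihood: float, n_observations: int, n_parameters: int) -> float:
    """Bayesian Information Criterion, k ln(n) - 2 LL."""
    if n_observations < 1:
        raise ValueError("n_observations must be >= 1")
    return float(n_parameters * np.log(n_observations) - 2.0 * log_likelihood)


# ---------------------------------------------------------------------------
# Grid simulation and search
# ---------------------------------------------------------------------------


def simulate_grid(variant: str, environment: GroupSpec, grid: GridSpec,
                  rng: np.random.Generator | int | None = None,
                  dt: float = DEFAULT_DT,
                  reward_scale: float = DEFAULT_REWARD_SCALE,
                  noise_scaling: str = "euler") -> GridBank:
    """Simulate the model LT distribution at every grid point.

    One shared set of ``n_sims_per_point`` partner draws from the
    environment mixture is used for all points; per-simulation seeds are
    identical across points (common random numbers).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown DDM variant {variant!r}")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    pts = grid.points()
    xbar, horizons, censor = sample_signal_bank(
        variant, environment, grid.n_sims_per_point, rng, dt, reward_scale)
    noise = rng.standard_normal(xbar.shape)
    step_sds = (pts[:, 2].copy() if noise_scaling == "literal"
                else pts[:, 2] * np.sqrt(dt))
    lts, cens = _fp_noise_bank(
        xbar, horizons,
        pts[:, 0].copy(), pts[:, 1].copy(), step_sds.copy(),
        pts[:, 3].copy(), dt, noise)
    lts = np.where(cens, censor[None, :], lts)
    return GridBank(variant=variant, environment_type=environment.environment_type,
                    points=pts, lts=lts)


def _ks_ll_over_grid(observed: np.ndarray, bank: GridBank) -> np.ndarray:
    """log KS p-value of the observed sample against every grid point."""
    obs = np.sort(np.asarray(observed, float))
    n = obs.size
    lls = np.empty(bank.points.shape[0])
    for i in range(bank.points.shape[0]):
        p = stats.ks_2samp(obs, bank.lts[i], method="asymp").pvalue
        lls[i] = np.log(max(p, P_FLOOR))
    return lls


@dataclass
class EnvironmentFit:
    params: DDMParams | None
    log_likelihood: float
    n_obs: int
    bic: float
    grid_index: int
    fittable: bool = True


def grid_search_fit(observed_lts, bank: GridBank,
                    dt: float = DEFAULT_DT,
                    reward_scale: float = DEFAULT_REWARD_SCALE,
                    refine_bank: GridBank | None = None,
                    top_frac: float = 0.1) -> EnvironmentFit:
    """Best grid point for one participant in one environment.

    Ties are broken deterministically by lexicographic grid order (theta,
    drift gain, noise sd, start bias ascending).  Fewer than two observed
    leaving times yields a flagged-unfittable result rather than an error.

    With ``refine_bank`` (an independently simulated bank over the same
    grid) the search refines its top decile: candidate points selected on
    the first bank are re-scored on the second, and the final argmax and
    reported likelihood come from the re-scoring.  Selecting on one set of
    simulations and scoring on another removes the selection optimism of a
    max over many noisy likelihoods, which otherwise favours whichever
    model family has the most distributional variety.
    """
    obs = np.asarray(observed_lts, float)
    if obs.size < 2:
        return EnvironmentFit(params=None, log_likelihood=np.nan,
                              n_obs=int(obs.size), bic=np.nan,
                              grid_index=-1, fittable=False)
    lls = _ks_ll_over_grid(obs, bank)
    if refine_bank is None:
        best = int(np.argmax(lls))  # first maximum in lexicographic order
        ll = float(lls[best])
    else:
        n_top = max(1, int(np.ceil(top_frac * lls.size)))
        # stable sort keeps lexicographic order among equal likelihoods
        order = np.argsort(-lls, kind="stable")[:n_top]
        candidates = np.sort(order)  # lexicographic among candidates
        refined = np.array([
            np.log(max(stats.ks_2samp(obs, refine_bank.lts[i],
                                      method="asymp").pvalue, P_FLOOR))
            for i in candidates])
        best = int(candidates[int(np.argmax(refined))])
        ll = float(refined.max())
    return EnvironmentFit(
        params=bank.params_at(best, dt=dt, reward_scale=reward_scale),
        log_likelihood=ll, n_obs=int(obs.size),
        bic=bic(ll, int(obs.size), N_PARAMS_PER_ENVIRONMENT),
        grid_index=best)


@dataclass
class FitResult:
    """One participant's fit of one DDM variant across environments."""

    participant_id: str
    variant: str
    by_environment: dict  # environment_type -> EnvironmentFit

    @property
    def log_likelihood(self) -> float:
        return float(sum(f.log_likelihood for f in self.by_environment.values()))

    @property
    def summed_bic(self) -> float:
        return float(sum(f.bic for f in self.by_environment.values()))

    @property
    def fittable(self) -> bool:
        return all(f.fittable for f in self.by_environment.values())


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class LeavingTimeDDM:
    """Grid-search maximum-likelihood model of leaving-time distributions.

    Parameters
    ----------
    data : DataFrame
        Leaving-time records with columns ``participant_id``,
        ``environment_type`` and ``leaving_time_s`` (censored rows already
        carrying the censoring value).
    variant : {"standard", "reward", "fairness"}
    environments : dict
        ``environment_type -> GroupSpec`` describing each environment's
        partner mixture, from which model LT distributions are simulated.
    grid : GridSpec
    dt : float
        Simulation step for the model distributions.
    """

    def __init__(self, data: pd.DataFrame, variant: str,
                 environments: dict, grid: GridSpec | None = None,
                 dt: float = DEFAULT_DT,
                 reward_scale: float = DEFAULT_REWARD_SCALE):
        if variant not in VARIANTS:
            raise ValueError(f"unknown DDM variant {variant!r}")
        missing = set(data["environment_type"].unique()) - set(environments)
        if missing:
            raise ValueError(f"no GroupSpec for environments: {sorted(missing)}")
        self.data = data
        self.variant = variant
        self.environments = dict(environments)
        self.grid = grid or GridSpec()
        self.dt = dt
        self.reward_scale = reward_scale

    def simulate_banks(self, seed: int | None = None) -> dict:
        """Simulate the per-environment grid banks (the expensive step)."""
        rng = np.random.default_rng(seed)
        return {
            env: simulate_grid(self.variant, spec, self.grid, rng,
                               dt=self.dt, reward_scale=self.reward_scale)
            for env, spec in self.environments.items()
        }

    def fit(self, seed: int | None = None, banks: dict | None = None,
            refine_banks: dict | None = None) -> "LeavingTimeDDMResults":
        """Fit every participant in ``data``; returns the results object.

        Under the default common-random-numbers policy one bank per
        environment is shared by all participants; ``banks`` (and
        optionally ``refine_banks`` for top-decile refinement on
        independent simulations) may be passed in to reuse banks across
        models, e.g. across generating cohorts.
        """
        if banks is None:
            if self.grid.seed_policy == "common_random_numbers":
                banks = self.simulate_banks(seed)
            elif self.grid.seed_policy != "independent":
                raise ValueError(f"unknown seed policy {self.grid.seed_policy!r}")
        fits = []
        rng = np.random.default_rng(seed)
        for pid, sub in self.data.groupby("participant_id", sort=True):
            if banks is None:  # independent policy: fresh bank per participant
                pbanks = {
                    env: simulate_grid(self.variant, spec, self.grid, rng,
                                       dt=self.dt,
                                       reward_scale=self.reward_scale)
                    for env, spec in self.environments.items()
                }
            else:
                pbanks = banks
            by_env = {}
            for env in sorted(self.environments):
                lts = sub.loc[sub["environment_type"] == env,
                              "leaving_time_s"].to_numpy()
                by_env[env] = grid_search_fit(
                    lts, pbanks[env], dt=self.dt,
                    reward_scale=self.reward_scale,
                    refine_bank=(refine_banks or {}).get(env))
            fits.append(FitResult(participant_id=str(pid),
                                  variant=self.variant, by_environment=by_env))
        return LeavingTimeDDMResults(self, fits, banks)


class LeavingTimeDDMResults:
    """Per-participant best-fit parameters, likelihoods and BICs."""

    def __init__(self, model: LeavingTimeDDM, fits: list, banks: dict | None):
        self.model = model
        self.fits = fits
        self.banks = banks

    @property
    def variant(self) -> str:
        return self.model.variant

    @property
    def summed_bic(self) -> float:
        """Cohort BIC: summed over participants and environments."""
        return float(sum(f.summed_bic for f in self.fits if f.fittable))

    @property
    def log_likelihood(self) -> float:
        return float(sum(f.log_likelihood for f in self.fits if f.fittable))

    def frame(self) -> pd.DataFrame:
        rows = []
        for f in self.fits:
            for env, ef in f.by_environment.items():
                row = {"participant_id": f.participant_id, "variant": f.variant,
                       "environment": env, "ll": ef.log_likelihood,
                       "n_obs": ef.n_obs, "bic": ef.bic,
                       "fittable": ef.fittable}
                if ef.params is not None:
                    row.update(theta=ef.params.threshold,
                               drift_gain=ef.params.drift_gain,
                               noise_sd=ef.params.noise_sd,
                               start_bias=ef.params.start_bias)
                rows.append(row)
        return pd.DataFrame(rows)

    def predicted_mean_lt(self, participant_id: str, env: str) -> float:
        """Mean simulated LT at the participant's best-fit grid point."""
        if self.banks is None:
            raise ValueError("no shared banks available (independent policy)")
        fit = next(f for f in self.fits if f.participant_id == participant_id)
        ef = fit.by_environment[env]
        if not ef.fittable:
            return np.nan
        return float(self.banks[env].lts[ef.grid_index].mean())

    def summary(self) -> str:
        df = self.frame()
        lines = [f"Leaving-time DDM ({self.variant}), "
                 f"{len(self.fits)} participants",
                 f"grid: {self.model.grid.n_points} points x "
                 f"{self.model.grid.n_sims_per_point} sims, dt={self.model.dt}",
                 f"summed BIC: {self.summed_bic:.2f}   "
                 f"total LL: {self.log_likelihood:.2f}", ""]
        lines.append(df.to_string(index=False,
                                  float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Comparison and diagnostics
# ---------------------------------------------------------------------------


@dataclass
class ModelComparison:
    summed_bic: dict            # variant -> cohort BIC
    winners: pd.Series          # participant -> winning variant
    winner_proportions: dict    # variant -> proportion of participants won

    @property
    def best_variant(self) -> str:
        return min(self.summed_bic, key=self.summed_bic.get)


def compare_models(results: list) -> ModelComparison:
    """Compare fitted variants by summed BIC and per-participant winners."""
    by_variant = {r.variant: r for r in results}
    if len(by_variant) != len(results):
        raise ValueError("duplicate variants in comparison")
    pids = sorted({f.participant_id for r in results for f in r.fits})
    for r in results:
        got = {f.participant_id for f in r.fits}
        if got != set(pids):
            raise ValueError(f"variant {r.variant} is missing participants")
    bics = pd.DataFrame({
        v: {f.participant_id: f.summed_bic for f in r.fits}
        for v, r in by_variant.items()
    }).loc[pids]
    winners = bics.idxmin(axis=1)
    props = winners.value_counts(normalize=True).to_dict()
    props = {v: float(props.get(v, 0.0)) for v in by_variant}
    return ModelComparison(
        summed_bic={v: r.summed_bic for v, r in by_variant.items()},
        winners=winners, winner_proportions=props)


def predicted_vs_observed(results: LeavingTimeDDMResults,
                          data: pd.DataFrame) -> dict:
    """Spearman rho between model and observed mean LTs, per environment."""
    out = {}
    obs_means = (data.groupby(["participant_id", "environment_type"])
                 ["leaving_time_s"].mean())
    for env in sorted(results.model.environments):
        pred, obs = [], []
        for f in results.fits:
            if not f.by_environment[env].fittable:
                continue
            pid = f.participant_id
            if (pid, env) not in obs_means.index:
                continue
            pred.append(results.predicted_mean_lt(pid, env))
            obs.append(obs_means.loc[(pid, env)])
        if len(pred) < 3:
            out[env] = np.nan
            continue
        out[env] = float(stats.spearmanr(pred, obs).statistic)
    return out


@dataclass
class ThresholdContrast:
    differences: np.ndarray  # per-participant theta(low) - theta(high)
    mean_difference: float
    t_statistic: float
    p_value: float
    n: int
    applicable: bool


def threshold_environment_contrast(results: LeavingTimeDDMResults,
                                   low: str = "low_generosity",
                                   high: str = "high_generosity"
                                   ) -> ThresholdContrast:
    """Paired contrast of fitted thresholds between environments (low - high)."""
    diffs = []
    for f in results.fits:
        lo, hi = f.by_environment.get(low), f.by_environment.get(high)
        if lo is None or hi is None or not (lo.fittable and hi.fittable):
            continue
        diffs.append(lo.params.threshold - hi.params.threshold)
    diffs = np.asarray(diffs, float)
    if diffs.size < 2 or np.allclose(diffs, diffs[0]):
        t, p, ok = np.nan, np.nan, diffs.size >= 2
        if diffs.size >= 2 and np.allclose(diffs, diffs[0]):
            ok = False  # degenerate: no variance for a paired test
    else:
        res = stats.ttest_1samp(diffs, 0.0)
        t, p, ok = float(res.statistic), float(res.pvalue), True
    return ThresholdContrast(differences=diffs,
                             mean_difference=float(diffs.mean()) if diffs.size else np.nan,
                             t_statistic=t, p_value=p, n=int(diffs.size),
                             applicable=ok and diffs.size >= 2)
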
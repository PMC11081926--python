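"""Behavioural analysis: preparation rules and mixed-effects contracts.

The pipeline mirrors a standard leaving-time analysis:

1. censor non-leaves at the onset of the final sharing decision;
2. exclude participants (too few active leaves, or too many failed
   attention checks in the S4 design);
3. trim leaving times beyond 2.5 SD of the within-participant,
   within-condition mean;
4. fit linear mixed-effects models

       LT ~ partner * environment + (1 + partner + environment | participant)

   with sum-to-zero (effect) coding, optionally extended with a z-scored
   depression or loneliness covariate and its interactions, and test fixed
   terms with Wald chi-square statistics.

Effect coding uses +/-0.5 level scores by default, so each main-effect
coefficient is the level difference averaged over the other factor, and the
intercept is the grand mean of cell means on balanced data; the +/-1
convention (coefficient = half the difference) is selectable.  Inference
fits use REML (the lme4 convention the Wald chi-square workflow assumes);
models compared by BIC across different fixed structures are refitted by
maximum likelihood.  The per-term Wald chi-squares coincide with classic
Type II tests under this coding on (near-)balanced designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

__all__ = [
    "ExclusionReport",
    "LmmSpec",
    "EffectEstimates",
    "censor_nonleaves",
    "apply_exclusions",
    "trim_outliers",
    "derive_outcomes",
    "encode_design",
    "LeavingTimeLMM",
    "fit_lmm",
    "simple_effects",
    "compare_covariate_models",
    "prepare_table",
]

DEFAULT_CENSOR_TIME = 29 * 3.5  # onset of the 30th decision on the 3.5 s grid
ATTENTION_FAIL_LIMIT = 0.25     # exclusion is strict: fail_frac > 0.25

# environment codes point toward the low-quality (poor / effortful) setting
ENVIRONMENT_CODE = {
    "high_generosity": -0.5, "low_generosity": +0.5,
    "low_effort": -0.5, "high_effort": +0.5,
}
PARTNER_CODE = {"fair": -0.5, "unfair": +0.5}


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------


def censor_nonleaves(table: pd.DataFrame) -> pd.DataFrame:
    """Set censored rows' LT to the onset of the final sharing decision.

    Uses the per-row ``censor_time_s`` column when present (needed for the
    jittered S4 schedule), else the 3.5 s-grid value 101.5 s.  Idempotent.
    """
    out = table.copy()
    if "censored" not in out.columns:
        raise ValueError("table must carry a 'censored' column")
    censor = (out["censor_time_s"] if "censor_time_s" in out.columns
              else DEFAULT_CENSOR_TIME)
    out.loc[out["censored"], "leaving_time_s"] = (
        censor[out["censored"]] if isinstance(censor, pd.Series) else censor)
    return out


@dataclass
class ExclusionReport:
    excluded: dict = field(default_factory=dict)  # pid -> reason
    n_input_rows: int = 0
    n_retained_rows: int = 0
    n_trimmed_rows: int = 0
    trimmed_by_cell: dict = field(default_factory=dict)

    def reconciles(self) -> bool:
        return self.n_input_rows == (self.n_retained_rows
                                     + self.n_trimmed_rows
                                     + self._n_excluded_rows)

    _n_excluded_rows: int = 0


def apply_exclusions(table: pd.DataFrame, study_variant: str,
                     scores: pd.DataFrame | None = None
                     ) -> tuple[pd.DataFrame, ExclusionReport]:
    """Participant-level exclusions.

    S12/S3: a participant must have at least as many active (non-censored)
    leaves as there are environments (two).  S4: exclude when the attention
    failure fraction exceeds 0.25 (strictly); exactly 25% is retained.
    """
    report = ExclusionReport(n_input_rows=len(table))
    if study_variant == "S4":
        if scores is None or "attention_fail_frac" not in scores.columns:
            raise ValueError("S4 exclusions need scores with attention_fail_frac")
        bad = scores.loc[scores["attention_fail_frac"] > ATTENTION_FAIL_LIMIT,
                         "participant_id"]
        for pid in bad:
            report.excluded[str(pid)] = "attention_fail"
    else:
        n_env = table["environment_type"].nunique()
        active = (table[~table["censored"]]
                  .groupby("participant_id").size())
        for pid in table["participant_id"].unique():
            if active.get(pid, 0) < n_env:
                report.excluded[str(pid)] = "too_few_active_decisions"
    keep = ~table["participant_id"].astype(str).isin(report.excluded)
    out = table[keep].reset_index(drop=True)
    report._n_excluded_rows = int((~keep).sum())
    report.n_retained_rows = len(out)
    return out, report


def trim_outliers(table: pd.DataFrame,
                  condition_cols: tuple = ("fairness_class", "environment_type"),
                  sd_limit: float = 2.5
                  ) -> tuple[pd.DataFrame, dict]:
    """Remove LTs beyond ``sd_limit`` SDs of the within-participant,
    within-condition mean.  Cells with fewer than two rows are untouched.
    """
    cols = ["participant_id", *[c for c in condition_cols if c in table.columns]]
    keep = np.ones(len(table), dtype=bool)
    counts: dict = {}
    for key, idx in table.groupby(cols).groups.items():
        lts = table.loc[idx, "leaving_time_s"]
        if len(lts) < 2:
            continue
        sd = lts.std(ddof=1)
        if sd == 0:
            continue
        out = (lts - lts.mean()).abs() > sd_limit * sd
        if out.any():
            keep[table.index.get_indexer(idx[out])] = False
            counts[key] = int(out.sum())
    return table[keep].reset_index(drop=True), counts


def derive_outcomes(table: pd.DataFrame, trajectories: dict) -> pd.DataFrame:
    """Recompute fairness-at-leaving and credits earned from trajectories.

    ``trajectories`` maps ``(participant_id, group_index, partner_index)``
    to the :class:`~patchleave.task.PartnerTrajectory` that was on screen.
    Fairness at leaving is the proportion of the decision visible at the LT;
    credits earned sum the decisions whose display completed before the LT
    (all thirty on censored interactions).
    """
    props, creds = [], []
    for row in table.itertuples(index=False):
        traj = trajectories[(row.participant_id, row.group_index,
                             row.partner_index)]
        lt = row.leaving_time_s
        seg = min(np.searchsorted(traj.onsets, lt, side="right") - 1,
                  len(traj.onsets) - 1)
        props.append(float(traj.proportions[max(seg, 0)]))
        if row.censored:
            creds.append(float(traj.credits_shared.sum()))
        else:
            done = (traj.onsets + traj.durations) <= lt
            creds.append(float(traj.credits_shared[done].sum()))
    out = table.copy()
    out["proportion_at_leaving"] = props
    out["credits_earned"] = creds
    return out


def encode_design(table: pd.DataFrame, study_variant: str,
                  coding: str = "half",
                  scores: pd.DataFrame | None = None) -> pd.DataFrame:
    """Add effect-coded ``partner`` / ``environment`` predictors.

    S12/S3: partner is categorical (fair -> -0.5, unfair -> +0.5 under the
    default +/-0.5 convention).  S4: partner is the z-scored decay rate over
    the analysed table (fairer partners score higher).  Environment codes
    point toward the low-quality (poor or effortful) setting.  Covariate
    scores, if provided, are merged and z-scored over participants.
    """
    if coding not in ("half", "unit"):
        raise ValueError("coding must be 'half' or 'unit'")
    scale = 1.0 if coding == "half" else 2.0
    out = table.copy()
    if study_variant == "S4":
        dr = out["decay_rate"]
        out["partner"] = (dr - dr.mean()) / dr.std(ddof=1)
    else:
        out["partner"] = out["fairness_class"].map(PARTNER_CODE) * scale
    out["environment"] = (out["environment_type"].map(ENVIRONMENT_CODE)
                          * scale)
    if out["environment"].isna().any():
        raise ValueError("unknown environment_type in table")
    if scores is not None:
        out = out.merge(scores, on="participant_id", how="left")
        for col in ("depression", "loneliness"):
            if col in out.columns:
                per = out.drop_duplicates("participant_id")[col]
                out[col + "_z"] = (out[col] - per.mean()) / per.std(ddof=1)
    return out


# ---------------------------------------------------------------------------
# Mixed-effects model / results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LmmSpec:
    outcome: str = "leaving_time_s"
    covariate: str = "none"       # "none" | "depression" | "loneliness"
    coding: str = "half"
    random: str = "slopes"        # "slopes" | "intercept"
    method: str = "reml"          # "reml" for inference; "ml" for BIC comparison

    def formula(self) -> str:
        if self.covariate == "none":
            return f"{self.outcome} ~ partner * environment"
        return (f"{self.outcome} ~ partner * environment * "
                f"{self.covariate}_z")

    def re_formula(self) -> str:
        return "~partner+environment" if self.random == "slopes" else "~1"


@dataclass
class EffectEstimates:
    """Fixed-effect table with Wald tests, plus fit diagnostics."""

    frame: pd.DataFrame           # term, beta, se, ci_lo, ci_hi, chisq, p
    bic: float
    log_likelihood: float
    random_structure: str         # structure actually used
    fell_back: bool
    spec: LmmSpec
    cov_params: pd.DataFrame

    def coef(self, term: str) -> float:
        return float(self.frame.loc[term, "beta"])

    def pvalue(self, term: str) -> float:
        return float(self.frame.loc[term, "p"])

    def summary(self) -> str:
        head = (f"Mixed model: {self.spec.formula()}  "
                f"[random: {self.random_structure}"
                + (", fallback" if self.fell_back else "") + "]")
        body = self.frame.to_string(float_format=lambda v: f"{v: .4f}")
        tail = f"logLik {self.log_likelihood:.2f}   BIC {self.bic:.2f}"
        return "\n".join([head, body, tail])


class LeavingTimeLMM:
    """Linear mixed-effects model of leaving times (or derived outcomes).

    Thin modelling surface over :func:`statsmodels` MixedLM with the
    task's design conventions baked in: effect coding, random intercept
    plus main-effect slopes per participant, ML estimation, Wald
    chi-square tests per fixed term, and an intercept-only fallback when
    the slope model fails to converge.
    """

    def __init__(self, table: pd.DataFrame, spec: LmmSpec | None = None):
        self.spec = spec or LmmSpec()
        required = {"partner", "environment", "participant_id",
                    self.spec.outcome}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"table lacks columns: {sorted(missing)} "
                             "(run encode_design first)")
        if table["environment"].nunique() < 2:
            raise ValueError("need both environment levels to fit the model")
        if table["participant_id"].nunique() < 2:
            raise ValueError("need at least two participants")
        if self.spec.covariate != "none":
            col = f"{self.spec.covariate}_z"
            if col not in table.columns:
                raise ValueError(f"table lacks covariate column {col}")
        self.table = table

    def _fit_once(self, re_formula: str):
        """Fit by REML (inference default) or ML (for BIC comparison);
        boundary warnings are tolerated, divergence is not."""
        model = smf.mixedlm(self.spec.formula(), self.table,
                            groups=self.table["participant_id"],
                            re_formula=re_formula)
        last_exc = None
        for method in ("lbfgs", "bfgs", "powell"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    res = model.fit(reml=self.spec.method == "reml",
                                    method=method, maxiter=800)
                except (np.linalg.LinAlgError, ValueError) as exc:
                    last_exc = exc
                    continue
            if (res.converged and np.all(np.isfinite(res.fe_params))
                    and np.all(np.isfinite(res.bse_fe))):
                return res
        raise np.linalg.LinAlgError(
            f"mixed model did not converge ({last_exc})")

    def fit(self) -> EffectEstimates:
        fell_back = False
        structure = self.spec.random
        try:
            res = self._fit_once(self.spec.re_formula())
        except (np.linalg.LinAlgError, ValueError):
            if self.spec.random == "intercept":
                raise
            fell_back = True
            structure = "intercept"
            res = self._fit_once("~1")
        return self._estimates(res, structure, fell_back)

    def _estimates(self, res, structure: str, fell_back: bool
                   ) -> EffectEstimates:
        fe = res.fe_params
        se = res.bse_fe
        rows = []
        for term in fe.index:
            b, s = float(fe[term]), float(se[term])
            chi2 = (b / s) ** 2 if s > 0 else np.nan
            rows.append({
                "term": term, "beta": b, "se": s,
                "ci_lo": b - 1.959963984540054 * s,
                "ci_hi": b + 1.959963984540054 * s,
                "chisq": chi2,
                "p": float(sps.chi2.sf(chi2, df=1)) if np.isfinite(chi2)
                     else np.nan,
            })
        frame = pd.DataFrame(rows).set_index("term")
        k = len(fe) + res.cov_re.shape[0] * (res.cov_re.shape[0] + 1) // 2 + 1
        n = len(self.table)
        bic_val = float(-2.0 * res.llf + k * np.log(n))
        cov = pd.DataFrame(np.asarray(res.cov_params())[:len(fe), :len(fe)],
                           index=fe.index, columns=fe.index)
        return EffectEstimates(frame=frame, bic=bic_val,
                               log_likelihood=float(res.llf),
                               random_structure=structure,
                               fell_back=fell_back, spec=self.spec,
                               cov_params=cov)


def fit_lmm(table: pd.DataFrame, spec: LmmSpec | None = None
            ) -> EffectEstimates:
    """Functional wrapper: ``LeavingTimeLMM(table, spec).fit()``."""
    return LeavingTimeLMM(table, spec).fit()


# ---------------------------------------------------------------------------
# Post-hoc contrasts and covariate model comparison
# ---------------------------------------------------------------------------


def _contrast(est: EffectEstimates, weights: dict) -> dict:
    terms = est.frame.index
    L = np.array([weights.get(t, 0.0) for t in terms])
    b = est.frame["beta"].to_numpy()
    V = est.cov_params.to_numpy()
    delta = float(L @ b)
    se = float(np.sqrt(L @ V @ L))
    z = delta / se if se > 0 else np.nan
    return {"estimate": delta, "se": se, "z": z,
            "p": float(2 * sps.norm.sf(abs(z))) if np.isfinite(z) else np.nan}


def simple_effects(est: EffectEstimates, levels: dict | None = None,
                   continuous_partner: bool = False) -> pd.DataFrame:
    """Environment contrasts (low minus high quality) at partner levels.

    The categorical partner factor defaults to its fair/unfair effect
    codes; with ``continuous_partner`` the contrast is evaluated at the
    mean minus/plus one SD of the z-scored decay rate (the plotting
    convention for a continuous moderator).  Any covariate in the model is
    held at its mean (z = 0).  On balanced noise-free data these reproduce
    cell-mean differences exactly.
    """
    scale = 1.0 if est.spec.coding == "half" else 2.0
    d_env = 1.0 * scale  # code(low) - code(high)
    if levels is None:
        if continuous_partner:
            levels = {"least_fair(-1SD)": -1.0, "most_fair(+1SD)": 1.0}
        else:
            levels = {k: v * scale for k, v in PARTNER_CODE.items()}
    rows = []
    for name, value in levels.items():
        w = {"environment": d_env, "partner:environment": value * d_env}
        rows.append({"level": name, **_contrast(est, w)})
    return pd.DataFrame(rows).set_index("level")


def compare_covariate_models(table: pd.DataFrame,
                             coding: str = "half",
                             random: str = "slopes") -> pd.DataFrame:
    """BICs of depression-only, loneliness-only and joint covariate models.

    The joint model crosses the design with both z-scored covariates; a
    (near-)collinear pair simply pays the extra-parameter penalty, which is
    the behaviour the comparison is meant to expose.
    """
    for col in ("depression_z", "loneliness_z"):
        if col not in table.columns:
            raise ValueError(f"table lacks {col}; merge scores in encode_design")
    out = []
    for name, spec in [
        ("depression", LmmSpec(covariate="depression", coding=coding,
                               random=random, method="ml")),
        ("loneliness", LmmSpec(covariate="loneliness", coding=coding,
                               random=random, method="ml")),
    ]:
        est = fit_lmm(table, spec)
        out.append({"model": name, "bic": est.bic,
                    "log_likelihood": est.log_likelihood})
    # joint model: both covariates crossed with the design; 4 extra fixed
    # parameters relative to either single-covariate model
    n_joint_extra = 4
    per_subject = table.drop_duplicates("participant_id")
    r = np.corrcoef(per_subject["depression_z"],
                    per_subject["loneliness_z"])[0, 1]
    if abs(r) > 0.999:
        # rank-deficient: the duplicated covariate adds no likelihood, only
        # its parameter-count penalty
        llf = out[0]["log_likelihood"]
        k_extra = n_joint_extra
        bic_joint = out[0]["bic"] + k_extra * np.log(len(table))
        out.append({"model": "joint", "bic": float(bic_joint),
                    "log_likelihood": float(llf)})
        return pd.DataFrame(out).set_index("model")
    joint_formula = (f"{LmmSpec().outcome} ~ partner * environment * "
                     "depression_z + partner * environment * loneliness_z")
    re_formula = "~partner+environment" if random == "slopes" else "~1"
    model = smf.mixedlm(joint_formula, table,
                        groups=table["participant_id"],
                        re_formula=re_formula)
    res = None
    for method in ("lbfgs", "bfgs", "powell"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(reml=False, method=method, maxiter=800)
            except (np.linalg.LinAlgError, ValueError):
                continue
        if res.converged and np.all(np.isfinite(res.fe_params)):
            break
    if res is None:
        raise np.linalg.LinAlgError("joint covariate model did not converge")
    k = (len(res.fe_params)
         + res.cov_re.shape[0] * (res.cov_re.shape[0] + 1) // 2 + 1)
    out.append({"model": "joint",
                "bic": float(-2 * res.llf + k * np.log(len(table))),
                "log_likelihood": float(res.llf)})
    return pd.DataFrame(out).set_index("model")


# ---------------------------------------------------------------------------
# End-to-end preparation
# ---------------------------------------------------------------------------


def prepare_table(lt_table: pd.DataFrame, study_variant: str,
                  scores: pd.DataFrame | None = None,
                  coding: str = "half"
                  ) -> tuple[pd.DataFrame, ExclusionReport]:
    """Censor, exclude, trim and encode in the standard order.

    Trimming runs after exclusions and after the censoring substitution.
    """
    table = censor_nonleaves(lt_table)
    table, report = apply_exclusions(table, study_variant, scores=scores)
    table, trim_counts = trim_outliers(table)
    report.n_trimmed_rows = int(sum(trim_counts.values()))
    report.n_retained_rows = len(table)
    report.trimmed_by_cell = trim_counts
    table = encode_design(table, study_variant, coding=coding, scores=scores)
    return table, report
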
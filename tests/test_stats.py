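"""Data-preparation rules and mixed-effects contracts."""

import numpy as np
import pandas as pd
import pytest

from patchleave import ddm, stats, task
from patchleave.stats import LmmSpec


def lt_row(pid="p0", env="high_generosity", cls="fair", lt=30.0,
           censored=False, **kw):
    row = {"participant_id": pid, "environment_type": env,
           "fairness_class": cls, "leaving_time_s": lt,
           "censored": censored, "censor_time_s": 101.5,
           "decay_rate": -0.125 if cls == "fair" else -0.2}
    row.update(kw)
    return row


class TestCensoring:
    def test_censored_rows_get_final_onset(self):
        df = pd.DataFrame([lt_row(lt=50.0, censored=True),
                           lt_row(lt=30.0)])
        out = stats.censor_nonleaves(df)
        assert out.loc[0, "leaving_time_s"] == 101.5
        assert out.loc[1, "leaving_time_s"] == 30.0

    def test_idempotent(self):
        df = pd.DataFrame([lt_row(lt=101.5, censored=True)])
        once = stats.censor_nonleaves(df)
        twice = stats.censor_nonleaves(once)
        pd.testing.assert_frame_equal(once, twice)


class TestExclusions:
    def test_no_active_leaves_excluded(self):
        rows = []
        for env in ("high_generosity", "low_generosity"):
            rows.append(lt_row(pid="lazy", env=env, censored=True))
            rows.append(lt_row(pid="ok", env=env, censored=False))
        df = pd.DataFrame(rows)
        out, rep = stats.apply_exclusions(df, "S12")
        assert rep.excluded == {"lazy": "too_few_active_decisions"}
        assert set(out["participant_id"]) == {"ok"}
        assert rep.reconciles()

    def test_attention_threshold_strict(self):
        df = pd.DataFrame([lt_row(pid=p) for p in ("a", "b")])
        scores = pd.DataFrame({"participant_id": ["a", "b"],
                               "attention_fail_frac": [0.26, 0.25]})
        out, rep = stats.apply_exclusions(df, "S4", scores=scores)
        assert rep.excluded == {"a": "attention_fail"}
        assert set(out["participant_id"]) == {"b"}

    def test_s4_requires_attention_data(self):
        df = pd.DataFrame([lt_row()])
        with pytest.raises(ValueError):
            stats.apply_exclusions(df, "S4")

    def test_compliant_cohort_untouched(self):
        rows = [lt_row(pid=p, env=e) for p in ("a", "b")
                for e in ("high_generosity", "low_generosity")]
        out, rep = stats.apply_exclusions(pd.DataFrame(rows), "S12")
        assert rep.excluded == {} and len(out) == 4


class TestTrimming:
    def test_hand_computed_cell_no_trim(self):
        # cell [10, 10, 10, 60]: mean 22.5, sd 25 -> 60 is within 2.5 sd
        df = pd.DataFrame([lt_row(lt=v) for v in (10, 10, 10, 60)])
        out, counts = stats.trim_outliers(df)
        assert len(out) == 4 and counts == {}

    def test_constant_cell_untouched(self):
        df = pd.DataFrame([lt_row(lt=20.0) for _ in range(5)])
        out, counts = stats.trim_outliers(df)
        assert len(out) == 5

    def test_genuine_outlier_removed_and_idempotent(self):
        vals = [30.0] * 19 + [30.5] * 10 + [95.0]
        df = pd.DataFrame([lt_row(lt=v) for v in vals])
        out, counts = stats.trim_outliers(df)
        assert len(out) == 29
        again, counts2 = stats.trim_outliers(out)
        assert len(again) == 29 and counts2 == {}

    def test_within_cell_only(self):
        rows = ([lt_row(lt=v) for v in (10, 11, 12, 13)]
                + [lt_row(cls="unfair", lt=v) for v in (100, 101, 102)])
        out, _ = stats.trim_outliers(pd.DataFrame(rows))
        assert len(out) == 7  # distant cells never pool


class TestDeriveOutcomes:
    @pytest.fixture()
    def partner(self, rng):
        return task.build_partner(task.PartnerSpec(-0.125, "fair", "S12"),
                                  rng)

    def test_lookup_and_credit_sum(self, partner):
        # leave during trial 3's display: proportions/credits of trials 0-2
        # are complete, trial 3 is on screen
        lt = 3 * 3.5 + 1.0
        df = pd.DataFrame([lt_row(lt=lt, group_index=0, partner_index=0)])
        out = stats.derive_outcomes(df, {("p0", 0, 0): partner})
        assert out.loc[0, "proportion_at_leaving"] == pytest.approx(
            partner.proportions[3])
        assert out.loc[0, "credits_earned"] == pytest.approx(
            partner.credits_shared[:3].sum())

    def test_censored_earns_everything(self, partner):
        df = pd.DataFrame([lt_row(lt=101.5, censored=True, group_index=0,
                                  partner_index=0)])
        out = stats.derive_outcomes(df, {("p0", 0, 0): partner})
        assert out.loc[0, "credits_earned"] == pytest.approx(
            partner.credits_shared.sum())


def balanced_table(cell_means, n_subjects=6, reps=4, jitter=0.01):
    """Balanced two-factor table with exact cell means per participant.

    A +/-jitter pair per cell keeps cell means exact while giving the
    ML machinery nonzero residual variance.
    """
    rows = []
    for i in range(n_subjects):
        for (cls, env), mu in cell_means.items():
            for r in range(reps):
                d = jitter if r % 2 == 0 else -jitter
                rows.append(lt_row(pid=f"p{i}", env=env, cls=cls,
                                   lt=mu + d))
    return stats.encode_design(pd.DataFrame(rows), "S12")


CELLS = {("fair", "high_generosity"): 40.0,
         ("fair", "low_generosity"): 30.0,
         ("unfair", "high_generosity"): 25.0,
         ("unfair", "low_generosity"): 10.0}


class TestMixedModel:
    def test_effect_coding_grand_mean(self):
        table = balanced_table(CELLS)
        est = stats.fit_lmm(table)
        assert est.coef("Intercept") == pytest.approx(26.25, abs=1e-6)

    def test_main_effects_are_averaged_differences(self):
        table = balanced_table(CELLS)
        est = stats.fit_lmm(table)
        # partner: unfair minus fair averaged over environments
        assert est.coef("partner") == pytest.approx(
            (25 + 10) / 2 - (40 + 30) / 2, abs=1e-6)
        # environment: low minus high averaged over partners
        assert est.coef("environment") == pytest.approx(
            (30 + 10) / 2 - (40 + 25) / 2, abs=1e-6)

    def test_unit_coding_halves_coefficients(self):
        rows = []
        for i in range(4):
            for (cls, env), mu in CELLS.items():
                for r in range(4):
                    rows.append(lt_row(pid=f"p{i}", env=env, cls=cls,
                                       lt=mu + (0.01 if r % 2 else -0.01)))
        half = stats.fit_lmm(stats.encode_design(pd.DataFrame(rows), "S12",
                                                 coding="half"))
        unit = stats.fit_lmm(stats.encode_design(pd.DataFrame(rows), "S12",
                                                 coding="unit"))
        assert unit.coef("partner") == pytest.approx(half.coef("partner") / 2,
                                                     abs=1e-6)
        assert unit.coef("Intercept") == pytest.approx(
            half.coef("Intercept"), abs=1e-6)

    def test_simple_effects_reproduce_cell_means(self):
        table = balanced_table(CELLS)
        est = stats.fit_lmm(table)
        se = stats.simple_effects(est)
        assert se.loc["fair", "estimate"] == pytest.approx(30 - 40, abs=1e-6)
        assert se.loc["unfair", "estimate"] == pytest.approx(10 - 25,
                                                             abs=1e-6)

    def test_single_environment_rejected(self):
        rows = [lt_row(pid=f"p{i}", lt=20 + i) for i in range(4)]
        table = stats.encode_design(pd.DataFrame(rows), "S12")
        with pytest.raises(ValueError):
            stats.fit_lmm(table)

    def test_wald_chisq_matches_beta_se(self):
        table = balanced_table(CELLS, jitter=2.0)
        est = stats.fit_lmm(table)
        row = est.frame.loc["partner"]
        assert row["chisq"] == pytest.approx((row["beta"] / row["se"]) ** 2)
        assert est.frame["chisq"].min() >= 0
        lo, hi = est.frame.loc["partner", ["ci_lo", "ci_hi"]]
        assert lo < row["beta"] < hi


class TestCovariateModels:
    @pytest.fixture()
    def table_with_scores(self):
        rng = np.random.default_rng(0)
        rows = []
        scores = []
        for i in range(10):
            dep = float(rng.uniform(0, 20))
            scores.append({"participant_id": f"p{i}", "depression": dep,
                           "loneliness": float(rng.uniform(0, 6))})
            for (cls, env), mu in CELLS.items():
                for _ in range(3):
                    rows.append(lt_row(pid=f"p{i}", env=env, cls=cls,
                                       lt=mu + 0.3 * dep
                                       + float(rng.normal(0, 2))))
        return stats.encode_design(pd.DataFrame(rows), "S12",
                                   scores=pd.DataFrame(scores))

    def test_bic_table_complete_and_stable(self, table_with_scores):
        out1 = stats.compare_covariate_models(table_with_scores,
                                              random="intercept")
        out2 = stats.compare_covariate_models(table_with_scores,
                                              random="intercept")
        assert list(out1.index) == ["depression", "loneliness", "joint"]
        pd.testing.assert_frame_equal(out1, out2)

    def test_duplicated_covariate_pays_penalty(self):
        rng = np.random.default_rng(1)
        rows, scores = [], []
        for i in range(8):
            s = float(rng.uniform(0, 10))
            scores.append({"participant_id": f"p{i}", "depression": s,
                           "loneliness": s})  # identical scores
            for (cls, env), mu in CELLS.items():
                for _ in range(3):
                    rows.append(lt_row(pid=f"p{i}", env=env, cls=cls,
                                       lt=mu + float(rng.normal(0, 2))))
        table = stats.encode_design(pd.DataFrame(rows), "S12",
                                    scores=pd.DataFrame(scores))
        out = stats.compare_covariate_models(table, random="intercept")
        assert out.loc["joint", "bic"] > out.loc["depression", "bic"]


class TestPipeline:
    def test_prepare_table_accounting(self, rng):
        session = task.build_session("S12", rng, n_partners_per_group=10,
                                     n_groups=4)
        p = ddm.DDMParams("fairness", 10, 0.5, 0.3, dt=0.005)
        params = {g.environment_type: p for g in session.groups}
        lt = ddm.simulate_participant_session(params, session, rng, "p0")
        lt2 = ddm.simulate_participant_session(
            params, session, rng, "p1")
        raw = pd.concat([lt, lt2], ignore_index=True)
        table, rep = stats.prepare_table(raw, "S12")
        assert rep.reconciles()
        assert {"partner", "environment"} <= set(table.columns)
        assert set(table["partner"].unique()) <= {-0.5, 0.5}

    def test_s4_partner_is_zscored_decay(self, rng):
        session = task.build_session("S4", rng, n_partners_per_group=6,
                                     n_groups=2)
        p = ddm.DDMParams("fairness", 10, 0.5, 0.3, dt=0.005)
        params = {g.environment_type: p for g in session.groups}
        lt = ddm.simulate_participant_session(params, session, rng, "p0")
        enc = stats.encode_design(stats.censor_nonleaves(lt), "S4")
        assert enc["partner"].mean() == pytest.approx(0.0, abs=1e-9)
        assert enc["partner"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)
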
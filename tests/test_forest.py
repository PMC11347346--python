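"""Survival-forest stage tests: concordance against a brute-force oracle,
forest determinism and signal detection, KM product-limit hand example,
SHAP local accuracy on the fitted forest, and competing-risks identities."""

import numpy as np
import pandas as pd
import pytest
from lifelines import AalenJohansenFitter, KaplanMeierFitter

from fracsurv.cohort import CohortSpec, sample_cohort
from fracsurv.forest import (
    ForestConfig,
    SplitPlan,
    UnfitError,
    aalen_johansen,
    competing_risks_analysis,
    concordance,
    evaluate_concordance,
    fit_survival_forest,
    km_by_group,
    normalize_shap,
    shap_feature_correlations,
    shap_values,
)


def brute_force_cindex(event, time, risk):
    """Exhaustive enumeration over comparable pairs (Harrell's definition):
    pair (i, j) is comparable when the earlier time is an observed event."""
    conc = ties = total = 0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i]:
                total += 1
                if risk[i] > risk[j]:
                    conc += 1
                elif risk[i] == risk[j]:
                    ties += 1
            elif time[i] == time[j] and i < j and event[i] != event[j]:
                # one died, one censored at the same time: death is "earlier"
                total += 1
                dead = i if event[i] else j
                alive = j if event[i] else i
                if risk[dead] > risk[alive]:
                    conc += 1
                elif risk[dead] == risk[alive]:
                    ties += 1
    return (conc + 0.5 * ties) / total


class TestConcordance:
    def test_perfect_and_reversed_ranking(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.ones(4, dtype=int)
        risk = np.array([4.0, 3.0, 2.0, 1.0])
        assert concordance(event, time, risk) == 1.0
        assert concordance(event, time, -risk) == 0.0

    def test_six_patient_worked_example_with_tie(self):
        time = np.array([1.0, 2.0, 2.5, 3.0, 4.0, 5.0])
        event = np.array([1, 0, 1, 1, 0, 1])
        risk = np.array([3.0, 1.0, 2.0, 2.0, 0.5, 0.2])
        expected = brute_force_cindex(event, time, risk)
        assert concordance(event, time, risk) == pytest.approx(expected, abs=1e-12)

    def test_random_risks_match_brute_force(self, rng):
        time = rng.exponential(5, 30).round(1)
        event = rng.binomial(1, 0.7, 30)
        risk = rng.normal(size=30).round(1)  # rounding creates ties
        expected = brute_force_cindex(event, time, risk)
        assert concordance(event, time, risk) == pytest.approx(expected, abs=1e-12)

    def test_too_few_events_rejected(self):
        with pytest.raises(UnfitError):
            concordance(np.array([1, 0, 0]), np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))


class TestForestFit:
    def test_deterministic_given_seed(self, small_cohort):
        train = small_cohort.iloc[:400]
        m1 = fit_survival_forest(train, ForestConfig(20, 2, 15, seed=5))
        m2 = fit_survival_forest(train, ForestConfig(20, 2, 15, seed=5))
        assert np.array_equal(m1.predict_risk(train), m2.predict_risk(train))

    def test_all_censored_training_rejected(self, small_cohort):
        dead = small_cohort.iloc[:100].copy()
        dead["Status"] = 0
        with pytest.raises(UnfitError):
            fit_survival_forest(dead)

    def test_strong_age_cohort_beats_chance_on_holdout(self):
        """On a cohort with an amplified age effect (sized so a Cox oracle
        reaches roughly 0.70), held-out forest concordance exceeds 0.65."""
        from dataclasses import replace as dc_replace

        base = CohortSpec(n_patients=2000, seed=13)
        causes = {
            name: dc_replace(c, coefs={**c.coefs, "Age": 0.09})
            for name, c in base.causes.items()
        }
        cohort = sample_cohort(dc_replace(base, causes=causes))
        report, model, train, test = evaluate_concordance(
            cohort, ForestConfig(30, 2, 52, seed=0), SplitPlan(cv_folds=3, seed=0)
        )
        # independent linear oracle on the same split
        from sksurv.linear_model import CoxPHSurvivalAnalysis
        from sksurv.util import Surv

        cox = CoxPHSurvivalAnalysis().fit(
            train[model.features].to_numpy(),
            Surv.from_arrays(train.Status.astype(bool), train.Length_FU),
        )
        c_cox = concordance(test.Status, test.Length_FU, cox.predict(test[model.features].to_numpy()))
        assert c_cox == pytest.approx(0.70, abs=0.05)
        assert report.c_holdout > 0.65

    def test_permuted_outcomes_give_chance_concordance(self, small_cohort, rng):
        null = small_cohort.iloc[:800].copy()
        perm = rng.permutation(len(null))
        null["Length_FU"] = null["Length_FU"].to_numpy()[perm]
        null["Status"] = null["Status"].to_numpy()[perm]
        train, test = null.iloc[:550], null.iloc[550:]
        m = fit_survival_forest(train, ForestConfig(25, 2, 30, seed=2))
        c = concordance(test["Status"], test["Length_FU"], m.predict_risk(test))
        assert c == pytest.approx(0.5, abs=0.06)


class TestKaplanMeier:
    def test_five_patient_hand_product_limit(self):
        """Manual product-limit: deaths at 1 and 3 (of 5 at risk, then 3),
        censorings at 2 and 4: S = 4/5 after t=1, then 4/5 * 2/3 after t=3."""
        tab = pd.DataFrame(
            {"Length_FU": [1.0, 2.0, 3.0, 4.0, 5.0], "Status": [1, 0, 1, 0, 0]}
        )
        curves = km_by_group(tab, np.zeros(5, dtype=int), times=np.array([1.0, 3.0, 5.0]))
        km = curves["km"].to_numpy()
        assert km[0] == pytest.approx(4 / 5)
        assert km[1] == pytest.approx(4 / 5 * 2 / 3)
        assert km[2] == pytest.approx(4 / 5 * 2 / 3)

    def test_no_censoring_equals_empirical_fraction(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        tab = pd.DataFrame({"Length_FU": t, "Status": [1, 1, 1, 1]})
        curves = km_by_group(tab, np.zeros(4, dtype=int), times=np.array([1.5, 2.5, 3.5]))
        assert np.allclose(curves["km"], [0.75, 0.5, 0.25])

    def test_groups_without_events_skipped(self, caplog):
        tab = pd.DataFrame(
            {"Length_FU": [1.0, 2.0, 3.0, 4.0], "Status": [1, 1, 0, 0]}
        )
        with caplog.at_level("WARNING"):
            curves = km_by_group(tab, np.array([0, 0, 1, 1]))
        assert set(curves["group"]) == {0}
        assert any("skipping" in r.message for r in caplog.records)


class TestForestShap:
    def test_local_accuracy_for_every_patient(self, small_forest):
        model, train, test = small_forest
        explain = test.iloc[:25]
        shap_frame, base = shap_values(model, explain, n_background=12,
                                       n_permutations=4, seed=3)
        total = base + shap_frame.sum(axis=1).to_numpy()
        target = model.risk_score(explain)
        assert np.allclose(total, target, rtol=1e-6, atol=1e-8)

    def test_null_bed_effect_attributes_little_to_bed(self):
        """With the dose effect switched off, BED attributions are small
        relative to the age signal."""
        cohort = sample_cohort(CohortSpec(n_patients=900, seed=17).null_effect())
        model = fit_survival_forest(cohort.iloc[:700], ForestConfig(25, 2, 30, seed=1))
        shap_frame, _ = shap_values(model, cohort.iloc[700:800], n_background=12,
                                    n_permutations=4, seed=1)
        assert shap_frame["bed_dd"].abs().mean() < 0.3 * shap_frame["Age"].abs().mean()

    def test_own_feature_correlation_positive_for_monotone_hazard_features(self, small_forest):
        model, train, test = small_forest
        explain = test.iloc[:80]
        shap_frame, _ = shap_values(model, explain, n_background=12, n_permutations=5, seed=4)
        corr = shap_feature_correlations(shap_frame, explain)
        assert corr.loc["Age", "shap_Age"] > 0.5
        assert corr.loc["Stage_numeric", "shap_Stage_numeric"] > 0.3

    def test_normalized_curve_centered_at_one(self, small_forest):
        model, train, test = small_forest
        explain = test.iloc[:40]
        shap_frame, _ = shap_values(model, explain, n_background=10, n_permutations=3, seed=5)
        curve = normalize_shap(shap_frame, explain, "Age")
        assert (curve["relative_risk"] > 0).all()
        assert 0.5 < curve["smoothed"].median() < 1.5


class TestCompetingRisks:
    def test_eight_patient_hand_aalen_johansen(self):
        """Hand calculation.  Times 1..8; causes a,a,b,-,a,b,-,-
        (- censored).  At t=1 (8 at risk): CIF_a = 1/8, S = 7/8.
        t=2 (7): CIF_a += 7/8 * 1/7 = 1/8 -> 2/8; S = 6/8.
        t=3 (6): CIF_b = 6/8 * 1/6 = 1/8; S = 5/8.  t=4 censored.
        t=5 (4): CIF_a += 5/8 * ... with S(4-)=5/8 at-risk 4: 5/8*1/4."""
        time = np.arange(1.0, 9.0)
        event = np.array([1, 1, 1, 0, 1, 1, 0, 0])
        cause = np.array(["a", "a", "b", "none", "a", "b", "none", "none"], dtype=object)
        out = aalen_johansen(time, event, cause, causes=("a", "b"))
        cif_a = out.set_index("time")["cif_a"]
        cif_b = out.set_index("time")["cif_b"]
        assert cif_a.loc[1.0] == pytest.approx(1 / 8)
        assert cif_a.loc[2.0] == pytest.approx(2 / 8)
        assert cif_b.loc[3.0] == pytest.approx(1 / 8)
        assert cif_a.loc[5.0] == pytest.approx(2 / 8 + (5 / 8) * (1 / 4))
        assert cif_b.loc[6.0] == pytest.approx(1 / 8 + (5 / 8) * (3 / 4) * (1 / 3))

    def test_single_cause_cif_is_one_minus_km(self, small_cohort):
        sub = small_cohort.iloc[:300]
        cause = np.where(sub["Status"] == 1, "only", "none")
        out = aalen_johansen(sub["Length_FU"], sub["Status"], cause, causes=("only",))
        km = KaplanMeierFitter().fit(sub["Length_FU"], sub["Status"])
        km_vals = km.survival_function_at_times(out["time"]).to_numpy()
        assert np.allclose(out["cif_only"], 1 - km_vals, atol=1e-10)

    def test_cif_identity_sums_to_one_minus_survival(self, small_cohort):
        out = aalen_johansen(
            small_cohort["Length_FU"], small_cohort["Status"], small_cohort["cause"]
        )
        total = out[[c for c in out.columns if c.startswith("cif_")]].sum(axis=1)
        assert np.allclose(total + out["survival"], 1.0, atol=1e-8)

    def test_matches_lifelines_aalen_johansen(self, small_cohort):
        sub = small_cohort.iloc[:400]
        codes = sub["cause"].map({"none": 0, "index_cancer": 1, "other_cancer": 2, "other_causes": 3})
        ours = aalen_johansen(sub["Length_FU"], sub["Status"], sub["cause"])
        ajf = AalenJohansenFitter(calculate_variance=False)
        ajf.fit(sub["Length_FU"], codes, event_of_interest=1)
        theirs = ajf.cumulative_density_.iloc[:, 0]
        # both are right-continuous step functions; compare at our jump times
        tx, ty = theirs.index.to_numpy(), theirs.to_numpy()
        idx = np.searchsorted(tx, ours["time"].to_numpy(), side="right") - 1
        theirs_at = np.where(idx >= 0, ty[np.clip(idx, 0, None)], 0.0)
        assert np.allclose(theirs_at, ours["cif_index_cancer"], atol=1e-10)

    def test_symmetric_causes_have_similar_incidence(self, rng):
        n = 4000
        t = rng.exponential(5, n)
        c = rng.choice(["a", "b"], n)
        event = (t < 8).astype(int)
        cause = np.where(event == 1, c, "none")
        out = aalen_johansen(np.minimum(t, 8), event, cause, causes=("a", "b"))
        last = out.iloc[-1]
        assert last["cif_a"] == pytest.approx(last["cif_b"], abs=0.03)

    def test_forest_vimp_ranks_age_over_noise(self, small_cohort, rng):
        tab = small_cohort.iloc[:700].copy()
        tab["pure_noise"] = rng.standard_normal(len(tab))
        rep = competing_risks_analysis(
            tab,
            ForestConfig(30, 2, 40, seed=0),
            features=["Age", "Stage_numeric", "Smoking_PY", "bed_dd", "pure_noise"],
            vimp_repeats=2,
            seed=0,
        )
        v = rep.vimp[rep.vimp.cause == "other_causes"].set_index("feature")["vimp"]
        assert v["Age"] > v["pure_noise"]
        assert v["Age"] > 0.01
        # zero-event causes are absent from models, present in CIF with 0
        assert set(rep.c_index) <= {"index_cancer", "other_cancer", "other_causes"}
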
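"""Extreme selection, propensity matching, differential analysis, forest."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_curve

from osteomet import casecontrol, preprocess, synthio
from osteomet.containers import IntensityMatrix
from osteomet.synthio import CaseControlConfig


def _population(rng, n=200, age_shift=0.0):
    df = pd.DataFrame({
        "subject": [f"S{i:04d}" for i in range(n)],
        "sample": [f"S{i:04d}" for i in range(n)],
        "age": rng.normal(78, 1.7, n),
        "height": rng.normal(162, 6, n),
        "weight": rng.normal(65, 10, n),
        "bmi": rng.normal(24.4, 3.6, n),
    })
    df["tibia_vbmd"] = (212 - 8.0 * (df["age"] - 78) * (age_shift > 0)
                        + rng.normal(0, 40, n))
    return df


class TestSelectExtremes:
    def test_monotone_phenotype_selects_ends(self):
        pop = pd.DataFrame({"subject": [f"S{i}" for i in range(1, 11)],
                            "tibia_vbmd": np.arange(10.0)})
        low, high = casecontrol.select_extremes(pop, "tibia_vbmd", 3, 3)
        assert list(low["subject"]) == ["S1", "S2", "S3"]
        assert list(high["subject"]) == ["S8", "S9", "S10"]

    def test_pools_disjoint(self):
        rng = np.random.default_rng(71)
        pop = _population(rng, 100)
        low, high = casecontrol.select_extremes(pop, "tibia_vbmd", 40, 40)
        assert not set(low["subject"]) & set(high["subject"])

    def test_screening_cohort_arithmetic(self):
        rng = np.random.default_rng(72)
        pop = _population(rng, 3028)
        low, high = casecontrol.select_extremes(pop, "tibia_vbmd", 120, 120)
        unselected = (set(pop["subject"]) - set(low["subject"])
                      - set(high["subject"]))
        assert (len(low), len(high), len(unselected)) == (120, 120, 2788)

    def test_oversized_request_rejected(self):
        pop = _population(np.random.default_rng(73), 50)
        with pytest.raises(ValueError):
            casecontrol.select_extremes(pop, "tibia_vbmd", 30, 30)


class TestPropensityMatch:
    def test_null_covariates_stay_balanced(self):
        rng = np.random.default_rng(74)
        pop = _population(rng, 240)
        cases, pool = pop.iloc[:80], pop.iloc[80:]
        res = casecontrol.propensity_match(cases, pool)
        assert len(res.case_ids) == len(res.control_ids) == 80
        assert not set(res.case_ids) & set(res.control_ids)
        assert (res.balance["smd_post"].abs() < 0.35).all()

    def test_confounded_age_balanced_after_matching(self):
        """Extreme selection on an age-linked phenotype unbalances age;
        matching restores balance in the large majority of seeds."""
        fixed, improved = 0, 0
        for seed in range(25):
            rng = np.random.default_rng(1000 + seed)
            pop = _population(rng, 600, age_shift=1.0)
            low, high = casecontrol.select_extremes(pop, "tibia_vbmd",
                                                    60, 180)
            res = casecontrol.propensity_match(low, high)
            bal = res.balance.loc["age"]
            if bal["p_pre"] < 0.05:
                fixed += 1
                improved += bal["p_post"] >= 0.05
        assert fixed >= 10            # the confounding bites pre-match
        assert improved / fixed >= 0.9

    def test_overlapping_groups_rejected(self):
        rng = np.random.default_rng(75)
        pop = _population(rng, 60)
        with pytest.raises(ValueError, match="both groups"):
            casecontrol.propensity_match(pop.iloc[:30], pop.iloc[25:])

    def test_pool_smaller_than_cases_rejected(self):
        rng = np.random.default_rng(76)
        pop = _population(rng, 60)
        with pytest.raises(ValueError, match="pool"):
            casecontrol.propensity_match(pop.iloc[:40], pop.iloc[40:])


@pytest.fixture(scope="module")
def cohort():
    cfg = CaseControlConfig(
        n_population=600, n_cases=60, n_controls=60, n_metabolites=260,
        n_group_markers=26, frac_down=0.78, group_effect_log2=1.6,
        noise_sd=0.35, seed=77)
    matrix, samples, truth = synthio.simulate_cohort(cfg)
    low, high = casecontrol.select_extremes(samples, "tibia_vbmd", 60, 60)
    groups = pd.concat([low.assign(group="case"),
                        high.assign(group="control")])
    sub = IntensityMatrix(matrix.data[groups["sample"]], stage="raw")
    imp, mask = preprocess.impute(sub, preprocess.ImputeParams(seed=1))
    filt, _ = preprocess.filter_missing(imp, mask)
    norm, _ = preprocess.normalize_total(filt)
    logged = preprocess.log_transform(norm)
    return logged, groups, truth


class TestCasecontrolDifferential:
    def test_direction_split_matches_ground_truth(self, cohort):
        logged, groups, truth = cohort
        out = casecontrol.casecontrol_differential(logged, groups)
        sel = out[out["selected"]]
        planted = {m: e for m, e in truth.effects.items() if m in sel.index}
        assert len(planted) / len(truth.group_marker_ids) >= 0.7
        # recovered direction split matches the planted down/up partition
        for mid, eff in planted.items():
            assert sel.loc[mid, "direction"] == ("down" if eff < 0 else "up")

    def test_rule_is_conjunction_only(self, cohort):
        logged, groups, _ = cohort
        out = casecontrol.casecontrol_differential(logged, groups)
        ok = ~out["degenerate"]
        manual = (out["vip"] > 1.0) & (out["p"] < 0.05) & ok
        assert (out["selected"] == manual).all()
        # fold change plays no gating role: selected rows may have FC near 1
        assert set(out.columns) >= {"fold_change", "p_adj"}


class TestTrainRf:
    def _separable(self, rng, n=60, p=12):
        y = np.array(["case"] * (n // 2) + ["control"] * (n // 2))
        X = rng.normal(size=(p, n))
        X[:4, y == "case"] += 6.0
        matrix = pd.DataFrame(X, index=[f"M{i}" for i in range(p)],
                              columns=[f"S{i}" for i in range(n)])
        return matrix, pd.Series(y, index=matrix.columns)

    def test_separable_markers_reach_auc_one(self):
        rng = np.random.default_rng(80)
        matrix, labels = self._separable(rng)
        rep = casecontrol.train_rf(matrix, labels, n_trees=150, seed=5)
        assert rep.auc == 1.0
        assert not set(rep.train_ids) & set(rep.validation_ids)

    def test_stratified_split_preserves_class_ratio(self):
        rng = np.random.default_rng(81)
        matrix, labels = self._separable(rng, n=40)
        rep = casecontrol.train_rf(matrix, labels, n_trees=20, seed=6)
        val_labels = labels.loc[rep.validation_ids]
        assert abs((val_labels == "case").sum()
                   - (val_labels == "control").sum()) <= 1

    def test_permuted_labels_give_chance_auc(self):
        rng = np.random.default_rng(82)
        n, p = 160, 30
        X = pd.DataFrame(rng.normal(size=(p, n)),
                         index=[f"M{i}" for i in range(p)],
                         columns=[f"S{i}" for i in range(n)])
        aucs = []
        for seed in range(8):
            y = pd.Series(rng.permutation(["case", "control"] * (n // 2)),
                          index=X.columns)
            aucs.append(casecontrol.train_rf(X, y, n_trees=120,
                                             seed=seed).auc)
        assert 0.35 < np.mean(aucs) < 0.65

    def test_noise_feature_importance_near_zero(self):
        rng = np.random.default_rng(83)
        matrix, labels = self._separable(rng, n=80, p=10)
        matrix.loc["NOISE"] = rng.normal(size=matrix.shape[1])
        rep = casecontrol.train_rf(matrix, labels, n_trees=300, seed=7)
        mda = rep.importance["NOISE"]
        assert abs(mda) < 2 * rep.importance_se["NOISE"] + 1e-3
        # informative features clearly outrank the noise feature
        assert rep.importance[[f"M{i}" for i in range(4)]].min() > \
            rep.importance["NOISE"]

    def test_auc_invariant_under_monotone_score_transform(self):
        rng = np.random.default_rng(84)
        matrix, labels = self._separable(rng, n=50)
        rep = casecontrol.train_rf(matrix, labels, n_trees=80, seed=8)
        y = (labels.loc[rep.scores.index] == "case").astype(int)
        fpr, tpr, _ = roc_curve(y, np.exp(3 * rep.scores))  # monotone map
        assert np.trapezoid(tpr, fpr) == pytest.approx(rep.auc, abs=1e-12)

    def test_single_class_rejected(self):
        rng = np.random.default_rng(85)
        matrix, labels = self._separable(rng, n=20)
        with pytest.raises(ValueError):
            casecontrol.train_rf(matrix, labels.replace("control", "case"),
                                 n_trees=10, seed=9)
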
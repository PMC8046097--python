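"""Case-control analysis: extreme-phenotype selection, propensity matching,
covariate-adjusted differential metabolites, and random-forest discrimination.

The design mirrors a cross-sectional bone-density study: from a screening
population of elderly women, the lowest-vBMD women form the case pool and
the highest-vBMD women the control pool; 1:1 propensity-score matching on
age, height, weight and BMI balances the groups; differential metabolites
are selected by VIP > 1 (PLS-DA) AND p < 0.05 (OLS on log levels adjusted
for age and BMI); and a 1000-tree random forest trained on a stratified 70%
split is evaluated by ROC/AUC on the held-out 30%, with feature importance
as out-of-bag permutation "mean decrease in accuracy".

The forest is assembled here from scikit-learn decision trees with an
explicit bootstrap so that per-tree out-of-bag indices are first-class:
the importance of feature j is the average over trees of (OOB accuracy -
OOB accuracy with feature j permuted), the definition the classical R
implementation calls mean decrease in accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve
from sklearn.tree import DecisionTreeClassifier

from . import univariate
from .containers import IntensityMatrix
from .longitudinal import SelectionRule
from .multivariate import fit_plsda, vip

logger = logging.getLogger(__name__)

__all__ = ["MatchResult", "ClassifierReport", "select_extremes",
           "propensity_match", "casecontrol_differential", "train_rf"]

MATCH_COVARIATES = ("age", "height", "weight", "bmi")


@dataclass
class MatchResult:
    """1:1 propensity-matching output with covariate balance diagnostics."""

    case_ids: list
    control_ids: list
    propensity: pd.Series          # subject -> fitted propensity
    pairs: list                    # (case_id, control_id) in matching order
    balance: pd.DataFrame          # per covariate: SMD & p, pre and post


@dataclass
class ClassifierReport:
    """Random-forest discrimination summary."""

    train_ids: list
    validation_ids: list
    n_trees: int
    scores: pd.Series              # validation subject -> case-vote fraction
    roc: pd.DataFrame              # columns fpr, tpr, threshold
    auc: float
    importance: pd.Series          # feature -> mean decrease in accuracy
    importance_se: pd.Series       # across-tree standard error
    seed: int


def select_extremes(population: pd.DataFrame, phenotype: str,
                    n_low: int, n_high: int,
                    id_column: str = "subject"
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bottom-n_low and top-n_high subjects by a phenotype column.

    Ties are broken by subject id (ascending) and logged.  Returns
    (low_pool, high_pool) as row subsets of ``population``.
    """
    if n_low + n_high > len(population):
        raise ValueError("n_low + n_high exceeds the population size")
    if population[phenotype].duplicated().any():
        logger.info("phenotype ties present; breaking by %s", id_column)
    ordered = population.sort_values([phenotype, id_column],
                                     kind="mergesort")
    low = ordered.iloc[:n_low]
    high = ordered.iloc[-n_high:]
    return low.copy(), high.copy()


def propensity_match(cases: pd.DataFrame, control_pool: pd.DataFrame,
                     covariates=MATCH_COVARIATES,
                     id_column: str = "subject",
                     caliper: float | None = None) -> MatchResult:
    """1:1 greedy nearest-neighbour propensity matching without replacement.

    A logistic regression of case status on the covariates yields the
    propensity; matching runs on the logit scale, processing cases in
    descending propensity order (hardest-to-match first).  An optional
    caliper (in logit SD units) discards pairs farther apart than the
    threshold.
    """
    covariates = list(covariates)
    if len(control_pool) < len(cases):
        raise ValueError("control pool smaller than the case group")
    overlap = set(cases[id_column]) & set(control_pool[id_column])
    if overlap:
        raise ValueError(f"subjects in both groups: {sorted(overlap)[:5]}")

    both = pd.concat([cases.assign(_case=1), control_pool.assign(_case=0)],
                     ignore_index=True)
    X = sm.add_constant(both[covariates].to_numpy(dtype=float))
    try:
        fit = sm.Logit(both["_case"].to_numpy(), X).fit(disp=0)
    except Exception as exc:
        raise RuntimeError(
            "propensity model failed to converge; covariates may perfectly "
            f"separate cases from controls ({exc})")
    if not fit.mle_retvals.get("converged", True):
        raise RuntimeError("propensity model did not converge (possible "
                           "complete separation of the groups)")
    prop = pd.Series(fit.predict(X), index=both[id_column].to_numpy())
    eps = 1e-12
    logit = np.log(np.clip(prop, eps, 1 - eps) /
                   np.clip(1 - prop, eps, 1 - eps))

    case_ids = cases[id_column].tolist()
    pool_ids = control_pool[id_column].tolist()
    sd_logit = float(logit.std(ddof=1))
    max_dist = caliper * sd_logit if caliper is not None else np.inf

    order = sorted(case_ids, key=lambda c: (-prop[c], c))
    available = dict.fromkeys(pool_ids)  # insertion-ordered set
    pairs = []
    for cid in order:
        if not available:
            break
        dists = {k: abs(logit[cid] - logit[k]) for k in available}
        best = min(dists, key=lambda k: (dists[k], k))
        if dists[best] <= max_dist:
            pairs.append((cid, best))
            del available[best]
        else:
            logger.info("case %s unmatched under caliper", cid)

    matched_cases = [c for c, _k in pairs]
    matched_controls = [k for _c, k in pairs]
    balance = _balance_table(cases, control_pool,
                             cases.set_index(id_column).loc[matched_cases]
                                  .reset_index(),
                             control_pool.set_index(id_column)
                                  .loc[matched_controls].reset_index(),
                             covariates)
    return MatchResult(case_ids=matched_cases, control_ids=matched_controls,
                       propensity=prop, pairs=pairs, balance=balance)


def _smd(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def _balance_table(pre_cases, pre_controls, post_cases, post_controls,
                   covariates) -> pd.DataFrame:
    rows = []
    for cov in covariates:
        a0 = pre_cases[cov].to_numpy(dtype=float)
        b0 = pre_controls[cov].to_numpy(dtype=float)
        a1 = post_cases[cov].to_numpy(dtype=float)
        b1 = post_controls[cov].to_numpy(dtype=float)
        rows.append({
            "covariate": cov,
            "smd_pre": _smd(a0, b0),
            "smd_post": _smd(a1, b1),
            "p_pre": float(stats.ttest_ind(a0, b0).pvalue),
            "p_post": float(stats.ttest_ind(a1, b1).pvalue),
        })
    return pd.DataFrame(rows).set_index("covariate")


def casecontrol_differential(matrix: IntensityMatrix, samples: pd.DataFrame,
                             rule: SelectionRule | None = None,
                             n_components: int = 2) -> pd.DataFrame:
    """Differential metabolites between case and control groups.

    ``matrix`` must be at the log stage; ``samples`` needs columns sample,
    group ('case'/'control'), age, bmi.  Per metabolite: PLS-DA VIP (on the
    log matrix), age/BMI-adjusted OLS p-value for the group term, and the
    raw-scale fold change mean(case)/mean(control).  Selected iff
    VIP > vip_threshold AND p < p_threshold; direction from FC vs 1.
    """
    rule = rule or SelectionRule()
    rule.validate()
    matrix.require_stage("log")
    need = {"sample", "group", "age", "bmi"}
    if not need <= set(samples.columns):
        raise ValueError(f"samples table needs columns {sorted(need)}")
    sub = samples[samples["sample"].isin(matrix.samples)]
    X = matrix.data[sub["sample"]].to_numpy(dtype=float).T
    group = sub["group"].to_numpy()
    age = sub["age"].to_numpy(dtype=float)
    bmi = sub["bmi"].to_numpy(dtype=float)

    degenerate = X.std(axis=0, ddof=1) <= 0
    model = fit_plsda(X[:, ~degenerate], group, n_components=n_components,
                      feature_names=list(matrix.metabolites[~degenerate]))
    vips = vip(model)

    rows = []
    for j, mid in enumerate(matrix.metabolites):
        if degenerate[j]:
            rows.append({"metabolite": mid, "vip": np.nan, "p": np.nan,
                         "fold_change": np.nan, "degenerate": True})
            continue
        res = univariate.lm_group_contrast(X[:, j], group, age, bmi, id=mid)
        rows.append({"metabolite": mid, "vip": float(vips[mid]),
                     "p": res.p, "fold_change": res.extra["fold_change"],
                     "degenerate": False})
    out = pd.DataFrame(rows).set_index("metabolite")
    out["p_adj"] = np.nan
    ok = ~out["degenerate"]
    out.loc[ok, "p_adj"] = univariate.adjust(out.loc[ok, "p"].to_numpy())
    out["selected"] = ((out["vip"] > rule.vip_threshold)
                       & (out["p"] < rule.p_threshold) & ok)
    out["direction"] = np.where(out["fold_change"] > 1, "up", "down")
    return out


def _stratified_split(labels: np.ndarray, train_fraction: float,
                      rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray]:
    train_idx = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_train = int(round(train_fraction * len(idx)))
        train_idx.append(idx[:n_train])
    train = np.sort(np.concatenate(train_idx))
    val = np.setdiff1d(np.arange(len(labels)), train)
    return train, val


def train_rf(matrix: pd.DataFrame, labels: pd.Series,
             train_fraction: float = 0.7, n_trees: int = 1000,
             seed: int = 0, compute_importance: bool = True
             ) -> ClassifierReport:
    """Random-forest case/control discrimination with OOB permutation MDA.

    ``matrix`` is features x samples (e.g. the selected differential
    metabolites, log scale); ``labels`` maps sample -> 'case'/'control'.
    A stratified ``train_fraction`` split feeds a bagged ensemble of
    ``n_trees`` CART trees (sqrt(p) features per split); validation scores
    are the fraction of trees voting 'case', the ROC is swept over those
    scores and the AUC computed by the trapezoid rule.  Importance is the
    across-tree mean of the OOB accuracy drop under per-feature permutation.
    """
    rng = np.random.default_rng(seed)
    sample_ids = list(matrix.columns)
    y = (labels.loc[sample_ids].to_numpy() == "case").astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes")
    X = matrix.to_numpy(dtype=float).T

    train, val = _stratified_split(y, train_fraction, rng)
    for part, name in ((train, "training"), (val, "validation")):
        if len(np.unique(y[part])) < 2:
            raise ValueError(f"class absent from the {name} partition")

    Xtr, ytr = X[train], y[train]
    n_tr, p = Xtr.shape
    trees = []
    oob_masks = []
    for _ in range(n_trees):
        boot = rng.integers(0, n_tr, n_tr)
        oob = np.ones(n_tr, dtype=bool)
        oob[boot] = False
        tree = DecisionTreeClassifier(
            max_features="sqrt",
            random_state=int(rng.integers(0, 2**31 - 1)))
        tree.fit(Xtr[boot], ytr[boot])
        trees.append(tree)
        oob_masks.append(oob)

    votes = np.mean([t.predict(X[val]) for t in trees], axis=0)
    scores = pd.Series(votes, index=[sample_ids[i] for i in val])
    fpr, tpr, thr = roc_curve(y[val], votes)
    auc = float(np.trapezoid(tpr, fpr))

    # OOB permutation importance: mean decrease in accuracy
    if compute_importance:
        mda = np.zeros((n_trees, p))
        used = np.zeros(n_trees, dtype=bool)
        for t_idx, (tree, oob) in enumerate(zip(trees, oob_masks)):
            if not oob.any():
                continue
            used[t_idx] = True
            Xo, yo = Xtr[oob], ytr[oob]
            base_acc = float(np.mean(tree.predict(Xo) == yo))
            perm = rng.permutation(len(yo))
            for j in range(p):
                Xp = Xo.copy()
                Xp[:, j] = Xo[perm, j]
                mda[t_idx, j] = base_acc - float(
                    np.mean(tree.predict(Xp) == yo))
        mda = mda[used]
        importance = pd.Series(mda.mean(axis=0), index=matrix.index,
                               name="mean_decrease_accuracy")
        se = pd.Series(mda.std(axis=0, ddof=1) / np.sqrt(mda.shape[0]),
                       index=matrix.index, name="se")
    else:
        importance = pd.Series(np.nan, index=matrix.index,
                               name="mean_decrease_accuracy")
        se = pd.Series(np.nan, index=matrix.index, name="se")

    return ClassifierReport(
        train_ids=[sample_ids[i] for i in train],
        validation_ids=[sample_ids[i] for i in val],
        n_trees=n_trees, scores=scores,
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
        auc=auc, importance=importance, importance_se=se, seed=seed,
    )
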
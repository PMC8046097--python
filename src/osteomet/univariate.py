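"""Rank tests, multiple-testing control, adjusted contrasts and correlations.

Thin, explicit wrappers around scipy/statsmodels primitives with the exact
conventions the pipeline relies on:

* rank-sum (Mann-Whitney) p-values are exact (full enumeration) when both
  groups have n <= 12 and no ties, otherwise a tie-corrected normal
  approximation with continuity correction;
* signed-rank p-values are exact for n <= 15 non-zero differences without
  ties; zero differences are dropped (classical Wilcoxon convention);
* Benjamini-Hochberg step-up and Bonferroni adjustments;
* case-vs-control contrasts from OLS on log levels adjusted for age and BMI,
  with the fold change computed separately on the raw (normalized, non-log)
  scale as mean(case)/mean(control);
* Pearson correlation screens with BH across the full metabolite x clinical
  grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["TestResult", "ranksum", "signedrank", "adjust",
           "lm_group_contrast", "clinical_correlations", "ranksum_matrix"]

EXACT_RANKSUM_N = 12
EXACT_SIGNEDRANK_N = 15


@dataclass
class TestResult:
    """One statistical test outcome for one metabolite/contrast."""

    id: str
    statistic: float
    p: float
    method: str
    contrast: str = ""
    adjusted_p: float | None = None
    extra: dict | None = None


def _has_ties(*arrays) -> bool:
    pooled = np.concatenate([np.asarray(a, dtype=float) for a in arrays])
    return len(np.unique(pooled)) < len(pooled)


def ranksum(group_a, group_b, id: str = "", contrast: str = "") -> TestResult:
    """Two-tailed Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when both groups have <= 12 observations and the
    pooled data has no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    exact = (len(a) <= EXACT_RANKSUM_N and len(b) <= EXACT_RANKSUM_N
             and not _has_ties(a, b))
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return TestResult(id=id, statistic=float(res.statistic),
                      p=float(min(res.pvalue, 1.0)),
                      method=f"ranksum_{method}", contrast=contrast)


def ranksum_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Vectorized asymptotic rank-sum p-values, one test per row.

    ``A`` and ``B`` are (n_tests, n_a) and (n_tests, n_b); returns the
    two-tailed p-value vector (normal approximation with tie/continuity
    corrections — used for the genome-scale screens where n > 12 anyway).
    """
    res = stats.mannwhitneyu(A, B, alternative="two-sided",
                             method="asymptotic", use_continuity=True,
                             axis=-1)
    return np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)


def signedrank(before, after, id: str = "", contrast: str = "") -> TestResult:
    """Two-tailed Wilcoxon signed-rank test on paired observations.

    Zero differences are dropped before ranking; if all differences are
    zero, p = 1 is returned with a warning.  Exact when <= 15 non-zero
    differences with untied magnitudes, otherwise normal approximation with
    continuity correction.
    """
    x = np.asarray(before, dtype=float)
    y = np.asarray(after, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("paired vectors must have equal length >= 2")
    d = y - x
    nz = d[d != 0]
    if len(nz) == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return TestResult(id=id, statistic=0.0, p=1.0,
                          method="signedrank_degenerate", contrast=contrast)
    exact = len(nz) <= EXACT_SIGNEDRANK_N and not _has_ties(np.abs(nz))
    method = "exact" if exact else "approx"
    res = stats.wilcoxon(nz, alternative="two-sided", method=method,
                         correction=(method == "approx"))
    return TestResult(id=id, statistic=float(res.statistic),
                      p=float(min(res.pvalue, 1.0)),
                      method=f"signedrank_{method}", contrast=contrast)


def adjust(pvalues, method: str = "fdr_bh") -> np.ndarray:
    """Multiple-testing adjustment: BH step-up (``fdr_bh``) or ``bonferroni``.

    Order-preserving; adjusted p >= raw p elementwise.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("fdr_bh", "bonferroni"):
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=method)[1]


def lm_group_contrast(y_log, group, age, bmi, id: str = "",
                      y_raw=None) -> TestResult:
    """Case-vs-control contrast adjusted for age and BMI.

    Fits OLS ``y_log ~ intercept + 1{case} + age + bmi`` and reports the
    two-sided t-test p-value of the group coefficient.  The fold change is
    computed separately on the raw scale (``y_raw`` if given, else
    ``exp(y_log)``) as mean(case)/mean(control).
    """
    y_log = np.asarray(y_log, dtype=float)
    group = np.asarray(group)
    labels = sorted(pd.unique(group).tolist())
    if labels != ["case", "control"]:
        raise ValueError(f"group labels must be 'case'/'control', got {labels}")
    is_case = (group == "case").astype(float)
    if is_case.sum() < 3 or (1 - is_case).sum() < 3:
        raise ValueError("need at least 3 subjects per group")
    X = np.column_stack([is_case, np.asarray(age, float),
                         np.asarray(bmi, float)])
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates must be finite")
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (collinear covariates)")
    fit = sm.OLS(y_log, X).fit()
    raw = np.asarray(y_raw, dtype=float) if y_raw is not None else np.exp(y_log)
    fc = float(raw[is_case == 1].mean() / raw[is_case == 0].mean())
    return TestResult(id=id, statistic=float(fit.tvalues[1]),
                      p=float(fit.pvalues[1]), method="lm_group",
                      contrast="case_vs_control",
                      extra={"fold_change": fc,
                             "coef": float(fit.params[1])})


def clinical_correlations(metabolite_matrix: pd.DataFrame,
                          clinical: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation screen of metabolites against clinical variables.

    ``metabolite_matrix`` is metabolites x samples (log scale); ``clinical``
    is samples x variables, aligned on sample id.  Returns a long-format
    table (metabolite, variable, r, p, p_adj) with BH adjustment across the
    full grid.  Zero-variance vectors yield NaN r with a flag instead of
    failing the batch.
    """
    common = metabolite_matrix.columns.intersection(clinical.index)
    if len(common) < 3:
        raise ValueError("need >= 3 paired observations")
    M = metabolite_matrix[common]
    C = clinical.loc[common]
    rows = []
    for var in C.columns:
        cv = C[var].to_numpy(dtype=float)
        for mid in M.index:
            mv = M.loc[mid].to_numpy(dtype=float)
            if np.std(cv) == 0 or np.std(mv) == 0:
                rows.append({"metabolite": mid, "variable": var,
                             "r": np.nan, "p": np.nan, "degenerate": True})
                continue
            r, p = stats.pearsonr(mv, cv)
            rows.append({"metabolite": mid, "variable": var, "r": float(r),
                         "p": float(p), "degenerate": False})
    table = pd.DataFrame(rows)
    ok = ~table["degenerate"]
    table["p_adj"] = np.nan
    if ok.any():
        table.loc[ok, "p_adj"] = adjust(table.loc[ok, "p"].to_numpy(),
                                        "fdr_bh")
    return table
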
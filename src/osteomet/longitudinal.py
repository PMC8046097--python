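"""Longitudinal analysis: baseline ratios, differential-response selection,
response-pattern clustering and the group x time profile distance map.

The unit of longitudinal analysis is the *response*: a metabolite's level at
a follow-up visit divided by the same subject's baseline (month 0) level.
Treatment-responsive metabolites are selected per follow-up time by the
conjunction of two criteria computed on the responses of treatment vs
placebo subjects: a PLS-DA variable importance in projection above a
threshold (default VIP > 1) and a two-tailed rank-sum p-value below a
threshold (default p < 0.05).

Response patterns of the selected metabolites are then clustered with
divisive (DIANA) hierarchical clustering on 1 - Pearson correlation between
arm x time mean response profiles, cutting the tree at a height driven by
the divisive coefficient and keeping only clusters of at least
``min_cluster_size`` (default 10) metabolites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from . import univariate
from .containers import IntensityMatrix, ResponseMatrix
from .diana import DianaTree, diana
from .multivariate import fit_plsda, vip

logger = logging.getLogger(__name__)

__all__ = ["SelectionRule", "ClusterAssignment", "compute_responses",
           "select_differential", "select_union", "cluster_responses",
           "group_time_distance", "within_arm_time_course"]


@dataclass
class SelectionRule:
    """Dual criterion for differential metabolites: VIP AND p-value."""

    vip_threshold: float = 1.0
    p_threshold: float = 0.05

    def validate(self) -> None:
        if self.vip_threshold < 0 or not 0 < self.p_threshold <= 1:
            raise ValueError("invalid selection thresholds")


@dataclass
class ClusterAssignment:
    """Response-pattern clustering result."""

    labels: pd.Series             # metabolite id -> cluster label (int) or -1
    sizes: dict = field(default_factory=dict)
    divisive_coefficient: float = 0.0
    cut_height: float = 0.0
    n_clusters: int = 0


def compute_responses(matrix: IntensityMatrix, samples: pd.DataFrame,
                      baseline_time: int = 0) -> ResponseMatrix:
    """Per-subject follow-up/baseline ratios from a normalized matrix.

    Subjects missing the baseline or any follow-up visit are excluded (and
    logged), mirroring the complete-series convention of longitudinal serum
    panels.
    """
    matrix.require_stage("normalized")
    times = sorted(samples["time"].unique())
    if baseline_time not in times:
        raise ValueError(f"baseline time {baseline_time} absent from samples")
    follow_up = [t for t in times if t != baseline_time]

    by_subject = samples.groupby("subject")
    included, excluded = [], []
    for subj, rows in by_subject:
        if set(rows["time"]) >= set(times):
            included.append(subj)
        else:
            excluded.append(subj)
    if excluded:
        logger.info("excluding %d subjects with incomplete series: %s",
                    len(excluded), ", ".join(map(str, sorted(excluded))))
    if not included:
        raise ValueError("no subject has a complete longitudinal series")

    sample_of = samples.set_index(["subject", "time"])["sample"]
    arms = samples.drop_duplicates("subject").set_index("subject")["arm"]

    cols = {}
    for subj in sorted(included):
        base = matrix.data[sample_of[(subj, baseline_time)]]
        if (base <= 0).any():
            raise ValueError(f"non-positive baseline level for subject {subj}")
        for t in follow_up:
            cols[(subj, t)] = matrix.data[sample_of[(subj, t)]] / base
    ratios = pd.DataFrame(cols)
    ratios.columns = pd.MultiIndex.from_tuples(ratios.columns,
                                               names=["subject", "time"])
    return ResponseMatrix(ratios=ratios, arms=arms.loc[sorted(included)],
                          time_points=tuple(times),
                          excluded_subjects=sorted(excluded))


def select_differential(responses: ResponseMatrix, time: int,
                        rule: SelectionRule | None = None,
                        n_components: int = 2) -> pd.DataFrame:
    """Differential-response selection at one follow-up time.

    Fits a two-component PLS-DA on log-ratios (samples x metabolites,
    treatment vs placebo) for VIP scores, and a rank-sum test per metabolite
    on the ratios; a metabolite is selected iff VIP > vip_threshold AND
    p < p_threshold.  Constant metabolites are excluded with a flag.

    Returns a DataFrame indexed by metabolite with columns
    (time, vip, p, direction, selected, degenerate).
    """
    rule = rule or SelectionRule()
    rule.validate()
    ratios = responses.at_time(time)
    subjects = ratios.columns
    arm = responses.arm_of(subjects)
    for lab in ("treatment", "placebo"):
        if (arm == lab).sum() < 2:
            raise ValueError(f"arm {lab!r} not represented at time {time}")

    X = np.log(ratios.to_numpy(dtype=float).T)  # subjects x metabolites
    degenerate = X.std(axis=0, ddof=1) <= 0
    keep = ~degenerate
    if degenerate.any():
        logger.info("excluding %d constant metabolites at month %d",
                    int(degenerate.sum()), time)

    model = fit_plsda(X[:, keep], arm, n_components=n_components,
                      feature_names=list(ratios.index[keep]))
    vips = vip(model)

    A = ratios.to_numpy(dtype=float)[:, arm == "treatment"]
    B = ratios.to_numpy(dtype=float)[:, arm == "placebo"]
    pvals = univariate.ranksum_matrix(A, B)
    direction = np.where(np.median(A, axis=1) > np.median(B, axis=1),
                         "up", "down")

    out = pd.DataFrame({
        "time": time,
        "vip": np.nan,
        "p": pvals,
        "direction": direction,
        "degenerate": degenerate,
    }, index=ratios.index)
    out.loc[vips.index, "vip"] = vips.to_numpy()
    out["selected"] = ((out["vip"] > rule.vip_threshold)
                       & (out["p"] < rule.p_threshold)
                       & ~out["degenerate"])
    return out


def select_union(responses: ResponseMatrix, rule: SelectionRule | None = None,
                 n_components: int = 2) -> pd.DataFrame:
    """Per-time selection at every follow-up time plus the union membership.

    Returns a DataFrame indexed by metabolite with one selected_m{t} column
    per follow-up time, ``n_times_selected`` and ``selected_any``.
    """
    follow_up = [t for t in responses.time_points if t != 0]
    tables = {t: select_differential(responses, t, rule, n_components)
              for t in follow_up}
    out = pd.DataFrame(index=responses.ratios.index)
    for t, tab in tables.items():
        out[f"selected_m{t}"] = tab["selected"]
        out[f"p_m{t}"] = tab["p"]
        out[f"vip_m{t}"] = tab["vip"]
    sel_cols = [f"selected_m{t}" for t in follow_up]
    out["n_times_selected"] = out[sel_cols].sum(axis=1).astype(int)
    out["selected_any"] = out["n_times_selected"] > 0
    return out


def _mean_response_profiles(responses: ResponseMatrix,
                            metabolites) -> pd.DataFrame:
    """Arm x time mean response profile per metabolite.

    Two arms x all time points; the baseline column is identically 1 (every
    subject's baseline ratio is 1 by construction), matching the convention
    of plotting relative-change trajectories anchored at 1.
    """
    ratios = responses.ratios.loc[metabolites]
    subjects = ratios.columns.get_level_values("subject")
    arm = responses.arms.loc[subjects].to_numpy()
    profile = {}
    for a in ("treatment", "placebo"):
        profile[(a, responses.time_points[0])] = 1.0
        for t in responses.time_points[1:]:
            sel = (ratios.columns.get_level_values("time") == t) & (arm == a)
            profile[(a, t)] = ratios.loc[:, sel].mean(axis=1)
    return pd.DataFrame(profile, index=metabolites)


def cluster_responses(responses: ResponseMatrix, metabolites,
                      min_cluster_size: int = 10,
                      cut_fraction: float | None = None
                      ) -> tuple[ClusterAssignment, DianaTree]:
    """DIANA clustering of mean response profiles of selected metabolites.

    Distance is 1 - Pearson correlation between arm x time mean response
    profiles.  By default the divisive tree is cut inside the largest gap of
    the (non-increasing) split-height sequence — a data-driven rule that
    resolves exactly the well-separated groups and leaves tight blocks
    intact; pass ``cut_fraction`` to cut at an explicit fraction of the tree
    height instead.  Clusters smaller than ``min_cluster_size`` are left
    unassigned (label -1).  The divisive coefficient of the tree is reported
    alongside the assignment.
    """
    metabolites = list(metabolites)
    if len(metabolites) < min_cluster_size:
        logger.warning("only %d metabolites (< min_cluster_size=%d); "
                       "returning empty assignment", len(metabolites),
                       min_cluster_size)
        return (ClusterAssignment(
            labels=pd.Series(-1, index=pd.Index(metabolites)),
        ), DianaTree(n=len(metabolites)))

    profiles = _mean_response_profiles(responses, sorted(metabolites))
    corr = np.corrcoef(profiles.to_numpy(dtype=float))
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)

    tree = diana(dist)
    if cut_fraction is not None:
        cut = cut_fraction * tree.diameter
    else:
        # cut inside the largest *relative* gap of the split-height sequence:
        # separations between real groups sit orders of magnitude above the
        # within-group splinter heights, so the ratio between consecutive
        # distinct heights peaks at the group/noise boundary.  Candidate
        # cuts are capped at n/min_cluster_size clusters — finer cuts could
        # never yield clusters large enough to retain.
        heights = sorted({s[3] for s in tree.splits if s[3] > 0},
                         reverse=True)
        max_clusters = max(2, len(metabolites) // max(min_cluster_size, 1))
        if not heights:
            cut = 0.0
        elif len(heights) == 1:
            cut = heights[0] / 2.0
        else:
            n_candidates = min(len(heights) - 1, max_clusters - 1)
            ratios = [heights[k] / heights[k + 1]
                      for k in range(n_candidates)]
            k = int(np.argmax(ratios))
            cut = float(np.sqrt(heights[k] * heights[k + 1]))
    raw_labels = tree.cut_height(cut)

    labels = pd.Series(raw_labels, index=profiles.index)
    sizes = labels.value_counts()
    keep = sizes[sizes >= min_cluster_size].index
    relabel = {old: new for new, old in enumerate(sorted(keep))}
    final = labels.map(lambda v: relabel.get(v, -1))
    assignment = ClusterAssignment(
        labels=final,
        sizes={relabel[k]: int(sizes[k]) for k in keep},
        divisive_coefficient=tree.dc,
        cut_height=float(cut),
        n_clusters=len(keep),
    )
    return assignment, tree


def group_time_distance(matrix: IntensityMatrix, samples: pd.DataFrame
                        ) -> tuple[pd.DataFrame, list]:
    """Euclidean distances between arm x time mean metabolite profiles.

    Returns the symmetric distance matrix (labelled ``arm_m{time}``) and the
    leaf order of an average-linkage dendrogram over those profiles.
    """
    matrix.require_stage("log")
    cells = []
    profiles = []
    for (arm, t), rows in samples.groupby(["arm", "time"]):
        cols = rows["sample"].tolist()
        if not cols:
            raise ValueError(f"empty group x time cell ({arm}, {t})")
        cells.append(f"{arm}_m{int(t):02d}")
        profiles.append(matrix.data[cols].mean(axis=1).to_numpy())
    if len(cells) < 2:
        raise ValueError("need at least 2 group x time cells")
    P = np.vstack(profiles)
    condensed = pdist(P, metric="euclidean")
    D = pd.DataFrame(squareform(condensed), index=cells, columns=cells)
    link = hierarchy.linkage(condensed, method="average")
    order = [cells[i] for i in hierarchy.leaves_list(link)]
    return D, order


def within_arm_time_course(matrix: IntensityMatrix, samples: pd.DataFrame,
                           arm: str, q_threshold: float = 0.1
                           ) -> pd.DataFrame:
    """Signed-rank screens between all time-point pairs within one arm.

    For every ordered pair of time points, runs a Wilcoxon signed-rank test
    per metabolite on paired (same-subject) log levels, adjusts with BH per
    comparison, and counts up/down metabolites at adjusted p < q_threshold
    (direction by median paired difference).  Pairs with fewer than 2
    complete subject pairs are skipped with a log entry.

    Returns a long DataFrame (metabolite, time_a, time_b, p, p_adj,
    direction, significant).
    """
    matrix.require_stage("log")
    sub = samples[samples["arm"] == arm]
    if sub.empty:
        raise ValueError(f"no samples in arm {arm!r}")
    times = sorted(sub["time"].unique())
    sample_of = sub.set_index(["subject", "time"])["sample"]

    frames = []
    for i, ta in enumerate(times):
        for tb in times[i + 1:]:
            subjects = [s for s in sub["subject"].unique()
                        if (s, ta) in sample_of.index
                        and (s, tb) in sample_of.index]
            if len(subjects) < 2:
                logger.info("skipping pair (%s, %s) in arm %s: <2 complete "
                            "pairs", ta, tb, arm)
                continue
            Xa = matrix.data[[sample_of[(s, ta)] for s in subjects]].to_numpy()
            Xb = matrix.data[[sample_of[(s, tb)] for s in subjects]].to_numpy()
            res = [univariate.signedrank(Xa[j], Xb[j], id=mid)
                   for j, mid in enumerate(matrix.metabolites)]
            p = np.array([r.p for r in res])
            med = np.median(Xb - Xa, axis=1)
            frame = pd.DataFrame({
                "metabolite": matrix.metabolites,
                "time_a": ta, "time_b": tb, "p": p,
                "p_adj": univariate.adjust(p, "fdr_bh"),
                "direction": np.where(med > 0, "up",
                                      np.where(med < 0, "down", "none")),
            })
            frame["significant"] = frame["p_adj"] < q_threshold
            frames.append(frame)
    if not frames:
        raise ValueError(f"no comparable time-point pairs in arm {arm!r}")
    return pd.concat(frames, ignore_index=True)
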
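"""Baseline ratios, dual-criterion selection, DIANA clustering, distances."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest

from osteomet import longitudinal
from osteomet.containers import ResponseMatrix
from osteomet.diana import diana
from osteomet.longitudinal import SelectionRule
from conftest import make_matrix, response_matrix_from_profiles as _response_matrix


class TestComputeResponses:
    def test_ratio_arithmetic(self, rct_samples_frame):
        data = np.ones((3, 16)) * 10.0
        m = make_matrix(data, stage="normalized")
        m.data.columns = rct_samples_frame["sample"]
        # subject T001: baseline 10, month-3 value 15 for metabolite M001
        m.data.loc["M001", "T001_m03"] = 15.0
        resp = longitudinal.compute_responses(m, rct_samples_frame)
        assert resp.ratios.loc["M001", ("T001", 3)] == pytest.approx(1.5)
        # everything else stayed at baseline level -> ratio exactly 1
        others = resp.ratios.drop(columns=[("T001", 3)])
        assert (others.to_numpy() == 1.0).all()

    def test_incomplete_subjects_excluded_and_logged(self):
        """A 71-subject frame with 3 incomplete series analyzes 68."""
        rows = []
        for i in range(71):
            subj = f"LB{i + 1:02d}"
            arm = "treatment" if i % 2 else "placebo"
            times = (0, 3, 6, 12)
            if subj in ("LB36", "LB44", "LB56"):
                times = (0, 3, 6)          # missed the month-12 visit
            for t in times:
                rows.append({"sample": f"{subj}_m{t:02d}", "subject": subj,
                             "arm": arm, "time": t})
        samples = pd.DataFrame(rows)
        data = np.full((2, len(samples)), 5.0)
        m = make_matrix(data, stage="normalized")
        m.data.columns = samples["sample"]
        resp = longitudinal.compute_responses(m, samples)
        assert len(resp.subjects()) == 68
        assert resp.excluded_subjects == ["LB36", "LB44", "LB56"]

    def test_missing_baseline_excludes_subject(self, rct_samples_frame):
        samples = rct_samples_frame[
            ~((rct_samples_frame["subject"] == "T001")
              & (rct_samples_frame["time"] == 0))]
        data = np.full((2, len(samples)), 3.0)
        m = make_matrix(data, stage="normalized")
        m.data.columns = samples["sample"]
        resp = longitudinal.compute_responses(m, samples)
        assert "T001" not in resp.subjects()
        assert resp.excluded_subjects == ["T001"]


class TestSelectDifferential:
    def test_conjunction_required(self, small_rct_processed):
        normalized, _, samples, _ = small_rct_processed
        resp = longitudinal.compute_responses(normalized, samples)
        table = longitudinal.select_differential(resp, 3)
        sel = table[table["selected"]]
        assert (sel["vip"] > 1.0).all() and (sel["p"] < 0.05).all()
        # metabolites passing only one criterion are not selected
        one_sided = table[(table["vip"] > 1.0) ^ (table["p"] < 0.05)]
        assert not one_sided["selected"].any()

    def test_monotone_in_thresholds(self, small_rct_processed):
        normalized, _, samples, _ = small_rct_processed
        resp = longitudinal.compute_responses(normalized, samples)
        loose = longitudinal.select_differential(
            resp, 6, SelectionRule(1.0, 0.05))
        tight = longitudinal.select_differential(
            resp, 6, SelectionRule(1.3, 0.01))
        assert set(tight.index[tight["selected"]]) <= \
            set(loose.index[loose["selected"]])

    def test_recovers_planted_responders(self, small_rct_processed):
        normalized, _, samples, truth = small_rct_processed
        resp = longitudinal.compute_responses(normalized, samples)
        union = longitudinal.select_union(resp)
        selected = set(union.index[union["selected_any"]])
        planted = set(truth.responsive_ids) & set(union.index)
        nulls = set(union.index) - planted
        sensitivity = len(selected & planted) / len(planted)
        assert sensitivity >= 0.8
        # selection among nulls stays near the chance level of the rule
        # (the p<0.05 branch dominates; union over three time points)
        null_rate = len(selected & nulls) / len(nulls)
        assert null_rate <= 0.2
        assert sensitivity > 3 * null_rate

    def test_union_set_algebra(self, small_rct_processed):
        normalized, _, samples, _ = small_rct_processed
        resp = longitudinal.compute_responses(normalized, samples)
        union = longitudinal.select_union(resp)
        per_time = [set(union.index[union[f"selected_m{t}"]])
                    for t in (3, 6, 12)]
        assert set(union.index[union["selected_any"]]) == set().union(
            *per_time)


class TestClusterResponses:
    def test_two_anticorrelated_blocks_recovered(self):
        profiles = {}
        for i in range(12):
            profiles[f"A{i:02d}"] = {"treatment": [1.6, 1.9, 2.2],
                                     "placebo": [1.0, 1.0, 1.0]}
        for i in range(12):
            profiles[f"B{i:02d}"] = {"treatment": [0.6, 0.45, 0.4],
                                     "placebo": [1.0, 1.05, 1.0]}
        resp = _response_matrix(profiles, {"_n": 8}, noise=0.02, seed=1)
        assignment, _ = longitudinal.cluster_responses(
            resp, list(profiles), min_cluster_size=10)
        assert assignment.n_clusters == 2
        labels = assignment.labels
        assert labels[[f"A{i:02d}" for i in range(12)]].nunique() == 1
        assert labels[[f"B{i:02d}" for i in range(12)]].nunique() == 1
        assert labels["A00"] != labels["B00"]

    def test_duplicate_metabolites_always_co_clustered(self):
        profiles = {f"M{i}": {"treatment": [1.5, 2.0, 1.2],
                              "placebo": [1.0, 0.9, 1.1]} for i in range(3)}
        profiles.update({f"N{i}": {"treatment": [0.5, 0.4, 0.8],
                                   "placebo": [1.0, 1.1, 0.9]}
                         for i in range(9)})
        resp = _response_matrix(profiles, {"_n": 6}, noise=0.0, seed=2)
        assignment, _ = longitudinal.cluster_responses(
            resp, list(profiles), min_cluster_size=2)
        dup = assignment.labels[[f"M{i}" for i in range(3)]]
        assert dup.nunique() == 1

    def test_four_archetypes_recovered(self):
        """Four planted response shapes (down-then-up, peak-at-6, dip-at-3,
        monotone-diverging), >= 10 members each, yield 4 retained clusters."""
        shapes = {
            "dtu": {"treatment": [0.7, 1.2, 1.1], "placebo": [1.0, 0.95, 1.0]},
            "pk6": {"treatment": [1.1, 1.9, 1.0], "placebo": [1.0, 1.0, 1.0]},
            "dp3": {"treatment": [0.6, 0.9, 1.6], "placebo": [1.0, 1.4, 1.2]},
            "div": {"treatment": [1.2, 1.5, 1.9], "placebo": [0.9, 0.8, 0.7]},
        }
        profiles = {}
        for name, shape in shapes.items():
            for i in range(12):
                profiles[f"{name}{i:02d}"] = shape
        resp = _response_matrix(profiles, {"_n": 10}, noise=0.03, seed=3)
        assignment, _ = longitudinal.cluster_responses(
            resp, list(profiles), min_cluster_size=10)
        assert assignment.n_clusters == 4
        for name in shapes:
            members = [f"{name}{i:02d}" for i in range(12)]
            assert assignment.labels[members].nunique() == 1

    def test_too_few_metabolites_returns_empty_assignment(self):
        profiles = {f"M{i}": {"treatment": [1.0, 1.0, 1.0],
                              "placebo": [1.0, 1.0, 1.0]} for i in range(4)}
        resp = _response_matrix(profiles, {"_n": 4}, seed=4)
        assignment, _ = longitudinal.cluster_responses(resp, list(profiles),
                                                       min_cluster_size=10)
        assert assignment.n_clusters == 0
        assert (assignment.labels == -1).all()


class TestDianaReference:
    def test_topology_matches_r_divisive_implementation(self):
        """Tree topology and divisive coefficient match cluster::diana on 20
        random 15-point instances (cuts compared at untied heights)."""
        rng = np.random.default_rng(55)
        from scipy.spatial.distance import pdist, squareform
        instances = [squareform(pdist(rng.normal(size=(15, 3))))
                     for _ in range(20)]
        script_lines = ["library(cluster)"]
        for i, D in enumerate(instances):
            flat = ",".join(f"{v:.12g}" for v in D.ravel())
            script_lines.append(
                f"D <- matrix(c({flat}), nrow=15); "
                f"di <- diana(as.dist(D), diss=TRUE); "
                f"h <- as.hclust(di); "
                f"cat('DC',{i},sprintf('%.10f',di$dc),'\\n'); "
                f"for (k in 2:6) cat('K',{i},k,paste(cutree(h,k),"
                f"collapse=','),'\\n')")
        proc = subprocess.run(["Rscript", "-"],
                              input="\n".join(script_lines),
                              capture_output=True, text=True, timeout=300)
        assert proc.returncode == 0, proc.stderr
        r_dc, r_cut = {}, {}
        for line in proc.stdout.splitlines():
            parts = line.split()
            if parts and parts[0] == "DC":
                r_dc[int(parts[1])] = float(parts[2])
            elif parts and parts[0] == "K":
                r_cut[(int(parts[1]), int(parts[2]))] = [
                    int(x) for x in parts[3].split(",")]

        def _same_partition(a, b):
            return len({(x, y) for x, y in zip(a, b)}) == len(set(a)) \
                == len(set(b))

        for i, D in enumerate(instances):
            tree = diana(D)
            assert tree.dc == pytest.approx(r_dc[i], abs=1e-8)
            heights = sorted((s[3] for s in tree.splits), reverse=True)
            for k in range(2, 7):
                if abs(heights[k - 2] - heights[k - 1]) < 1e-9:
                    continue  # tied cut level: k-cluster cut is ambiguous
                assert _same_partition(tree.cut_k(k), r_cut[(i, k)]), \
                    f"instance {i}, k={k}"


class TestGroupTimeDistance:
    def test_identical_profiles_zero_distance(self, rct_samples_frame):
        data = np.tile(np.arange(1.0, 4.0)[:, None], (1, 16))
        m = make_matrix(np.log(data), stage="log")
        m.data.columns = rct_samples_frame["sample"]
        D, order = longitudinal.group_time_distance(m, rct_samples_frame)
        assert np.allclose(D.to_numpy(), 0.0)
        assert len(order) == 8

    def test_baseline_cells_are_nearest_neighbours(self, rct_samples_frame):
        rng = np.random.default_rng(66)
        base = rng.normal(10, 1, size=(30, 1))
        cols = {}
        for _, row in rct_samples_frame.iterrows():
            drift = 0.0
            if row["time"] > 0 and row["arm"] == "treatment":
                drift = 0.5 * np.log1p(row["time"])
            cols[row["sample"]] = (base[:, 0] + drift
                                   + rng.normal(0, 0.01, 30))
        m = make_matrix(np.column_stack(list(cols.values())), stage="log")
        m.data.columns = list(cols)
        D, _ = longitudinal.group_time_distance(m, rct_samples_frame)
        b_t, b_p = "treatment_m00", "placebo_m00"
        off_diag = D.loc[b_t].drop(b_t)
        assert off_diag.idxmin() == b_p

    def test_metric_properties(self, small_rct_processed):
        _, logged, samples, _ = small_rct_processed
        D, _ = longitudinal.group_time_distance(logged, samples)
        A = D.to_numpy()
        assert np.allclose(A, A.T)
        assert np.allclose(np.diag(A), 0.0)
        n = len(A)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert A[i, j] <= A[i, k] + A[k, j] + 1e-9


class TestWithinArmTimeCourse:
    def test_identical_time_points_nothing_significant(self,
                                                       rct_samples_frame):
        data = np.tile(np.random.default_rng(7).normal(size=(20, 1)),
                       (1, 16))
        m = make_matrix(data, stage="log")
        m.data.columns = rct_samples_frame["sample"]
        out = longitudinal.within_arm_time_course(m, rct_samples_frame,
                                                  "placebo")
        assert not out["significant"].any()

    def test_planted_downshift_recovered_with_direction(self):
        rng = np.random.default_rng(68)
        n_subj, n_met = 18, 80
        rows = []
        for i in range(n_subj):
            for t in (0, 3):
                rows.append({"sample": f"P{i:02d}_m{t:02d}",
                             "subject": f"P{i:02d}", "arm": "placebo",
                             "time": t})
        samples = pd.DataFrame(rows)
        base = rng.normal(10, 1, size=(n_met, n_subj))
        month3 = base + rng.normal(0, 0.05, size=(n_met, n_subj))
        month3[:30] -= 1.0                     # planted downshift
        data = np.empty((n_met, 2 * n_subj))
        data[:, ::2] = base
        data[:, 1::2] = month3
        m = make_matrix(data, stage="log")
        m.data.columns = samples["sample"]
        out = longitudinal.within_arm_time_course(m, samples, "placebo")
        sig = out[out["significant"]]
        planted = {f"M{i + 1:03d}" for i in range(30)}
        recovered = set(sig["metabolite"])
        assert planted <= recovered
        assert (sig[sig["metabolite"].isin(planted)]["direction"]
                == "down").all()
        # up/down counts partition the significant set
        assert len(sig) == (sig["direction"] == "up").sum() + \
            (sig["direction"] == "down").sum()
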
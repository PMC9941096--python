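import numpy as np
import pandas as pd
import pytest

from lipid4d.core import StudyDesign, ValidationError
from lipid4d.stats import (
    ConcentrationMatrix,
    audit_folds,
    friedman_timepoints,
    marker_ratios,
    pairwise_wilcoxon,
    pca_scores,
    pooled_class_sd,
    rf_classify,
)


def paired_design(individuals, time_points, matrices):
    rows = []
    for ind in individuals:
        for tp in time_points:
            for m in matrices:
                rows.append({"sample_id": f"{ind}_{m}_{tp}",
                             "individual": ind, "matrix": m,
                             "time_point": tp, "batch_role": "sample"})
    return StudyDesign(pd.DataFrame(rows))


def conc_matrix(individuals, time_points, matrices, fill, lipids):
    design = paired_design(individuals, time_points, matrices)
    values = pd.DataFrame(
        fill, index=pd.Index(design.sample_ids, name="sample_id"),
        columns=lipids)
    return ConcentrationMatrix(values=values, design=design)


class TestPairwiseWilcoxon:
    def test_identical_matrices_zero_dissimilarity(self):
        inds = [f"P{i}" for i in range(4)]
        tps = ["t0", "t1", "t2"]
        lipids = [f"lip{i}" for i in range(10)]
        n = len(inds) * len(tps) * 2
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 10, size=(len(inds) * len(tps), 10))
        fill = np.repeat(base, 2, axis=0)  # A and B rows identical
        conc = conc_matrix(inds, tps, ["A", "B"], fill, lipids)
        dis, qtable = pairwise_wilcoxon(conc)
        assert dis.loc["A", "B"] == 0
        assert (dis.to_numpy().diagonal() == 0).all()

    def test_planted_effects_detected(self):
        """40 of 100 lipids shifted by a large effect: rejection count
        close to 40."""
        inds = [f"P{i}" for i in range(7)]
        tps = ["t0", "t1", "t2"]
        lipids = [f"lip{i}" for i in range(100)]
        rng = np.random.default_rng(1)
        design = paired_design(inds, tps, ["A", "B"])
        fac = design.table
        values = pd.DataFrame(index=pd.Index(design.sample_ids,
                                             name="sample_id"),
                              columns=lipids, dtype=float)
        for sid in design.sample_ids:
            base = rng.lognormal(0, 0.2, size=100)
            if fac.loc[sid, "matrix"] == "B":
                base[:40] *= 3.0  # large effect on the first 40 lipids
            values.loc[sid] = base
        conc = ConcentrationMatrix(values=values, design=design)
        dis, qtable = pairwise_wilcoxon(conc)
        assert 35 <= dis.loc["A", "B"] <= 45

    def test_bh_rejections_subset_of_raw(self):
        inds = [f"P{i}" for i in range(5)]
        tps = ["t0", "t1", "t2", "t3"]
        lipids = [f"lip{i}" for i in range(50)]
        rng = np.random.default_rng(2)
        fill = rng.lognormal(0, 1, size=(len(inds) * len(tps) * 2, 50))
        conc = conc_matrix(inds, tps, ["A", "B"], fill, lipids)
        _, qtable = pairwise_wilcoxon(conc, alpha=0.05)
        raw = set(qtable.loc[qtable["p_value"] < 0.05, "lipid"])
        corrected = set(qtable.loc[qtable["rejected"], "lipid"])
        assert corrected <= raw

    def test_symmetry_property(self):
        inds = [f"P{i}" for i in range(4)]
        rng = np.random.default_rng(3)
        fill = rng.lognormal(0, 1, size=(4 * 2 * 3, 8))
        conc = conc_matrix(inds, ["t0", "t1"], ["A", "B", "C"], fill,
                           [f"l{i}" for i in range(8)])
        dis, _ = pairwise_wilcoxon(conc)
        assert (dis.to_numpy() == dis.to_numpy().T).all()

    def test_unpaired_samples_error(self):
        design = paired_design(["P1", "P2"], ["t0"], ["A", "B"])
        design.table = design.table.drop("P2_B_t0")
        values = pd.DataFrame(
            np.ones((3, 2)), index=pd.Index(design.table["sample_id"],
                                            name="sample_id"),
            columns=["l1", "l2"])
        conc = ConcentrationMatrix(values=values, design=design)
        with pytest.raises(ValidationError, match="unpaired"):
            pairwise_wilcoxon(conc)


class TestFriedman:
    def test_identical_timepoints_no_rejections(self):
        inds = [f"P{i}" for i in range(5)]
        rng = np.random.default_rng(4)
        base = rng.uniform(1, 10, size=(5, 6))
        fill = np.vstack([np.repeat(base, 3, axis=0)])
        conc = conc_matrix(inds, ["t0", "t1", "t2"], ["A"],
                           np.repeat(base, 3, axis=0),
                           [f"l{i}" for i in range(6)])
        out = friedman_timepoints(conc)
        assert not out["rejected"].any()

    def test_planted_trend_rejected(self):
        inds = [f"P{i}" for i in range(10)]
        tps = ["t0", "t1", "t2"]
        rng = np.random.default_rng(5)
        design = paired_design(inds, tps, ["A"])
        values = pd.DataFrame(index=pd.Index(design.sample_ids,
                                             name="sample_id"),
                              columns=["null", "trend"], dtype=float)
        for sid in design.sample_ids:
            tp = design.table.loc[sid, "time_point"]
            ind = design.table.loc[sid, "individual"]
            # constant across time points within each block -> p = 1
            values.loc[sid, "null"] = 1.0 + int(ind[1])
            values.loc[sid, "trend"] = 1.0 + 5.0 * int(tp[1]) + rng.normal(0, 0.01)
        conc = ConcentrationMatrix(values=values, design=design)
        out = friedman_timepoints(conc)
        assert bool(out.loc["trend", "rejected"])
        assert not bool(out.loc["null", "rejected"])

    def test_incomplete_block_error(self):
        design = paired_design(["P1", "P2"], ["t0", "t1", "t2"], ["A"])
        design.table = design.table.drop("P2_A_t2")
        values = pd.DataFrame(
            np.ones((5, 2)), index=pd.Index(design.table["sample_id"],
                                            name="sample_id"),
            columns=["l1", "l2"])
        conc = ConcentrationMatrix(values=values, design=design)
        with pytest.raises(ValidationError, match="incomplete block"):
            friedman_timepoints(conc)


class TestRfClassify:
    def separated_conc(self, n_ind=4, per_cell=5, shift=50.0, seed=0):
        rng = np.random.default_rng(seed)
        rows, meta = [], []
        for ind in range(n_ind):
            for m in ("A", "B"):
                for k in range(per_cell):
                    base = rng.normal(0, 1, size=10)
                    if m == "B":
                        base += shift
                    rows.append(np.abs(base) + (shift if m == "B" else 0))
                    meta.append({"sample_id": f"P{ind}_{m}_{k}",
                                 "individual": f"P{ind}", "matrix": m,
                                 "time_point": f"t{k}",
                                 "batch_role": "sample"})
        design = StudyDesign(pd.DataFrame(meta))
        values = pd.DataFrame(rows,
                              index=pd.Index(design.sample_ids,
                                             name="sample_id"),
                              columns=[f"f{i}" for i in range(10)])
        return ConcentrationMatrix(values=values, design=design)

    def test_perfect_separation_auroc_one(self):
        conc = self.separated_conc()
        res = rf_classify(conc, mode="pairwise", n_repeats=1, seed=0,
                          n_estimators=50)
        assert res.auroc["auroc"].iloc[0] == pytest.approx(1.0)

    def test_fold_partition_is_individuals(self):
        conc = self.separated_conc()
        res = rf_classify(conc, mode="multiclass", n_repeats=2, seed=1,
                          n_estimators=20)
        assert audit_folds(res)
        held = {f.held_out_individual for f in res.folds}
        assert held == {"P0", "P1", "P2", "P3"}
        for f in res.folds:
            assert set(f.train_individuals) == held - {f.held_out_individual}

    def test_class_in_one_individual_error(self):
        conc = self.separated_conc()
        fac = conc.design.table
        # relabel so class B only occurs in individual P0
        mask = (fac["matrix"] == "B") & (fac["individual"] != "P0")
        conc.design.table.loc[mask, "matrix"] = "A"
        with pytest.raises(ValidationError, match="only 1 individual"):
            rf_classify(conc)


class TestPcaScores:
    def toy_conc(self, seed=0, n=5, p=4):
        rng = np.random.default_rng(seed)
        design = StudyDesign(pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(n)],
             "batch_role": ["sample"] * n}))
        values = pd.DataFrame(rng.lognormal(0, 1, size=(n, p)),
                              index=pd.Index(design.sample_ids,
                                             name="sample_id"),
                              columns=[f"l{i}" for i in range(p)])
        return ConcentrationMatrix(values=values, design=design)

    def test_duplicated_sample_same_scores(self):
        conc = self.toy_conc()
        conc.values.loc["s1"] = conc.values.loc["s0"]
        scores, _ = pca_scores(conc)
        np.testing.assert_allclose(scores.loc["s0"], scores.loc["s1"],
                                   atol=1e-10)

    def test_explained_variance_sums_to_one(self):
        conc = self.toy_conc(seed=1)
        _, evr = pca_scores(conc, n_components=4)
        assert evr.sum() == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        """Scores on a 5x4 toy matrix equal the projection onto the
        covariance eigenvectors of the preprocessed data (up to sign)."""
        conc = self.toy_conc(seed=2)
        scores, _ = pca_scores(conc, n_components=2)
        X = np.log10(conc.values.to_numpy())
        X = (X - X.mean(axis=0)) / X.std(axis=0)
        cov = np.cov(X.T, ddof=1)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        for k in range(2):
            proj = X @ v[:, order[k]]
            got = scores.iloc[:, k].to_numpy()
            assert (np.allclose(proj, got, atol=1e-8)
                    or np.allclose(proj, -got, atol=1e-8))

    def test_constant_matrix_error(self):
        conc = self.toy_conc()
        conc.values.loc[:, :] = 1.0
        with pytest.raises(ValidationError):
            pca_scores(conc)


class TestPooledClassSd:
    def make_conc(self, values_by_lipid, classes):
        inds = ["P1", "P2"]
        tps = ["t0", "t1", "t2"]
        design = paired_design(inds, tps, ["A"])
        lipids = list(values_by_lipid)
        values = pd.DataFrame(index=pd.Index(design.sample_ids,
                                             name="sample_id"),
                              columns=lipids, dtype=float)
        for sid in design.sample_ids:
            tp_i = int(design.table.loc[sid, "time_point"][1])
            for lip in lipids:
                values.loc[sid, lip] = values_by_lipid[lip][tp_i]
        return (ConcentrationMatrix(values=values, design=design),
                dict(zip(lipids, classes)))

    def test_equal_variances_give_sqrt_v(self):
        # per-time-point means 0, 1, 2 -> variance 1 for both lipids
        conc, cmap = self.make_conc({"a": [1.0, 2.0, 3.0],
                                     "b": [5.0, 6.0, 7.0]}, ["X", "X"])
        out = pooled_class_sd(conc, cmap)
        assert out.loc[0, "pooled_sd"] == pytest.approx(1.0)

    def test_two_lipids_variance_1_and_3(self):
        # time-point means with variances 1 and 3 (equal n)
        conc, cmap = self.make_conc(
            {"a": [1.0, 2.0, 3.0],            # var 1
             "b": [0.0, 2 * np.sqrt(3), 0.0]  # var 4... adjust below
             }, ["X", "X"])
        # craft lipid b with sample variance exactly 3: values 0, 3, 3.4641?
        # simpler: use mean values (0, 3, 2*3) scaled: var([0,3,6])/3... use
        # direct: values v such that var = 3 -> [1, 2, 3]*sqrt(3) has var 3
        conc2, cmap2 = self.make_conc(
            {"a": [1.0, 2.0, 3.0],
             "b": [s * np.sqrt(3) for s in (1.0, 2.0, 3.0)]}, ["X", "X"])
        out = pooled_class_sd(conc2, cmap2)
        assert out.loc[0, "pooled_sd"] == pytest.approx(np.sqrt(2.0))

    def test_single_lipid_equals_plain_sd(self):
        conc, cmap = self.make_conc({"a": [1.0, 4.0, 10.0]}, ["X"])
        out = pooled_class_sd(conc, cmap)
        assert out.loc[0, "pooled_sd"] == pytest.approx(
            np.std([1.0, 4.0, 10.0], ddof=1))

    def test_matches_bruteforce_on_random_data(self):
        rng = np.random.default_rng(7)
        lipids = {f"l{i}": list(rng.uniform(1, 10, 3)) for i in range(6)}
        conc, cmap = self.make_conc(lipids, ["X"] * 3 + ["Y"] * 3)
        out = pooled_class_sd(conc, cmap).set_index("lipid_class")
        for cls in ("X", "Y"):
            vs = [np.var(lipids[l], ddof=1) for l in lipids
                  if cmap[l] == cls]
            pooled = sum(2 * v for v in vs) / (2 * len(vs))  # n_i - 1 = 2
            assert out.loc[cls, "pooled_sd"] == pytest.approx(
                np.sqrt(pooled))


class TestMarkerRatios:
    SPECIES = ["Cer d18:1_24:1", "Cer d18:1_24:0", "Cer d18:1_16:0",
               "PC 38:5", "Cer d18:1_18:0", "PC 14:0_22:6", "PC 16:0_16:0"]

    def make_conc(self, row):
        design = StudyDesign(pd.DataFrame({"sample_id": ["s1"],
                                           "batch_role": ["sample"]}))
        values = pd.DataFrame([row], index=pd.Index(["s1"],
                                                    name="sample_id"),
                              columns=self.SPECIES)
        return ConcentrationMatrix(values=values, design=design)

    def test_simple_ratio(self):
        conc = self.make_conc([2.0, 4.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        out = marker_ratios(conc)
        assert out.loc["s1", "Cer d18:1_24:1/Cer d18:1_24:0"] == 0.5

    def test_full_vector_hand_computed(self):
        row = [2.0, 4.0, 3.0, 6.0, 5.0, 2.5, 1.25]
        out = marker_ratios(self.make_conc(row))
        assert out.loc["s1", "Cer d18:1_16:0/PC 38:5"] == pytest.approx(0.5)
        assert out.loc["s1", "Cer d18:1_18:0/PC 14:0_22:6"] == pytest.approx(2.0)
        assert out.loc["s1", "PC 16:0_16:0"] == 1.25

    def test_zero_denominator_error(self):
        conc = self.make_conc([2.0, 0.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValidationError, match="Cer d18:1_24:0"):
            marker_ratios(conc)

    def test_missing_species_error(self):
        design = StudyDesign(pd.DataFrame({"sample_id": ["s1"],
                                           "batch_role": ["sample"]}))
        values = pd.DataFrame([[1.0]], index=pd.Index(["s1"],
                                                      name="sample_id"),
                              columns=["PC 38:5"])
        conc = ConcentrationMatrix(values=values, design=design)
        with pytest.raises(ValidationError, match="missing marker"):
            marker_ratios(conc)
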
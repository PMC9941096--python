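"""Blood-matrix pheno-mapping statistics.

Operates on a samples x lipids molar concentration matrix linked to a
study design (individual, matrix, time point). Provides the pairwise
Wilcoxon dissimilarity matrix with Benjamini-Hochberg correction, the
Friedman time-point test, person-held-out random-forest classification
with AUROC, PCA scores, pooled per-class SD, and the ceramide/PC
marker-ratio inputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.multitest import multipletests

from lipid4d.core import StudyDesign, ValidationError


@dataclass
class ConcentrationMatrix:
    """Samples x lipids concentrations [nmol/mL] plus design factors."""

    values: pd.DataFrame  # index: sample_id, columns: lipid names
    design: StudyDesign

    def __post_init__(self) -> None:
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise ValidationError("concentrations must be non-negative")
        self.design.check_covers(self.values.index)

    def factors(self) -> pd.DataFrame:
        return self.design.table.loc[self.values.index]

    @property
    def matrices(self) -> list[str]:
        return sorted(self.factors()["matrix"].dropna().unique())


def _bh(pvals: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return reject, qvals


def pairwise_wilcoxon(
    conc: ConcentrationMatrix,
    alpha: float = 0.05,
    zero_method: str = "pratt",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count, per blood-matrix pair, the lipids rejected after BH.

    Samples are paired by (individual, time_point); per lipid a
    two-sided Wilcoxon signed-rank test is run on the paired values and
    Benjamini-Hochberg is applied across lipids within each matrix
    pair. Returns (symmetric count matrix, long per-lipid q-table).
    """
    fac = conc.factors()
    matrices = conc.matrices
    dis = pd.DataFrame(0, index=matrices, columns=matrices, dtype=int)
    records = []
    for ma, mb in itertools.combinations(matrices, 2):
        sub_a = fac[fac["matrix"] == ma]
        sub_b = fac[fac["matrix"] == mb]
        key_a = {(r["individual"], r["time_point"]): r["sample_id"]
                 for _, r in sub_a.iterrows()}
        key_b = {(r["individual"], r["time_point"]): r["sample_id"]
                 for _, r in sub_b.iterrows()}
        common = sorted(set(key_a) & set(key_b))
        missing = sorted(set(key_a) ^ set(key_b))
        if missing:
            raise ValidationError(
                f"unpaired samples between {ma} and {mb}: {missing}"
            )
        ids_a = [key_a[k] for k in common]
        ids_b = [key_b[k] for k in common]
        pvals = []
        for lipid in conc.values.columns:
            x = conc.values.loc[ids_a, lipid].to_numpy(dtype=float)
            y = conc.values.loc[ids_b, lipid].to_numpy(dtype=float)
            if np.all(x == y):
                pvals.append(1.0)
                continue
            res = sps.wilcoxon(x, y, zero_method=zero_method,
                               alternative="two-sided")
            pvals.append(float(res.pvalue))
        pvals = np.asarray(pvals)
        reject, qvals = _bh(pvals, alpha)
        n_rej = int(reject.sum())
        dis.loc[ma, mb] = n_rej
        dis.loc[mb, ma] = n_rej
        for lipid, p, q, rej in zip(conc.values.columns, pvals, qvals, reject):
            records.append({"matrix_a": ma, "matrix_b": mb, "lipid": lipid,
                            "p_value": p, "q_value": q, "rejected": bool(rej)})
    qtable = pd.DataFrame(records, columns=["matrix_a", "matrix_b", "lipid",
                                            "p_value", "q_value", "rejected"])
    return dis, qtable


def friedman_timepoints(
    conc: ConcentrationMatrix,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Friedman test across time points, blocks = (individual, matrix).

    Per lipid: one measurement per block and time point; BH across
    lipids. Returns a per-lipid table with statistic, p, q, rejected.
    """
    fac = conc.factors()
    tps = sorted(fac["time_point"].dropna().unique())
    if len(tps) < 3:
        raise ValidationError("Friedman test needs >= 3 time points")
    blocks = sorted({(r["individual"], r["matrix"])
                     for _, r in fac.iterrows()})
    sample_of = {}
    for _, r in fac.iterrows():
        sample_of[(r["individual"], r["matrix"], r["time_point"])] = r["sample_id"]
    for b in blocks:
        for t in tps:
            if (b[0], b[1], t) not in sample_of:
                raise ValidationError(
                    f"incomplete block {b}: missing time point {t!r}"
                )
    rows = []
    for lipid in conc.values.columns:
        groups = []
        for t in tps:
            ids = [sample_of[(b[0], b[1], t)] for b in blocks]
            groups.append(conc.values.loc[ids, lipid].to_numpy(dtype=float))
        mat = np.column_stack(groups)
        if np.all(mat == mat[:, [0]]):
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.friedmanchisquare(*groups)
        rows.append({"lipid": lipid, "statistic": float(stat),
                     "p_value": float(p)})
    out = pd.DataFrame(rows).set_index("lipid")
    reject, qvals = _bh(out["p_value"].to_numpy(), alpha)
    out["q_value"] = qvals
    out["rejected"] = reject
    return out


@dataclass
class FoldRecord:
    repeat: int
    held_out_individual: object
    train_individuals: list
    n_train: int
    n_test: int


@dataclass
class ClassificationResult:
    auroc: pd.DataFrame      # long table: positive/negative class, repeat, auroc
    folds: list[FoldRecord] = field(default_factory=list)

    def mean_auroc(self) -> pd.DataFrame:
        return (self.auroc.groupby(["class_a", "class_b"], as_index=False)
                ["auroc"].mean())


def rf_classify(
    conc: ConcentrationMatrix,
    mode: str = "multiclass",
    n_repeats: int = 3,
    seed: int = 0,
    n_estimators: int = 200,
) -> ClassificationResult:
    """Random-forest blood-matrix classification with person-held-out
    cross-validation.

    Folds are individuals (leave-one-individual-out), repeated
    ``n_repeats`` times with distinct classifier seeds. ``multiclass``
    reports macro one-vs-rest AUROC on pooled held-out probabilities;
    ``pairwise`` trains one classifier per matrix pair.
    """
    if mode not in ("multiclass", "pairwise"):
        raise ValidationError(f"unknown mode {mode!r}")
    fac = conc.factors()
    individuals = sorted(fac["individual"].dropna().unique())
    if len(individuals) < 2:
        raise ValidationError("need >= 2 individuals for person-held-out folds")
    labels = fac["matrix"]
    for cls in labels.dropna().unique():
        n_ind = fac.loc[labels == cls, "individual"].nunique()
        if n_ind < 2:
            raise ValidationError(
                f"class {cls!r} present in only {n_ind} individual(s)"
            )
    X = conc.values.to_numpy(dtype=float)
    folds: list[FoldRecord] = []
    rows = []

    def run_cv(mask: np.ndarray, y: np.ndarray, repeat: int,
               rf_seed: int) -> tuple[np.ndarray, np.ndarray]:
        """Pooled held-out probabilities over person folds."""
        proba = None
        order = np.empty(0, dtype=int)
        idx_all = np.flatnonzero(mask)
        ind_arr = fac["individual"].to_numpy()
        for ind in individuals:
            test = idx_all[ind_arr[idx_all] == ind]
            train = idx_all[ind_arr[idx_all] != ind]
            if len(test) == 0:
                continue
            clf = RandomForestClassifier(n_estimators=n_estimators,
                                         random_state=rf_seed)
            clf.fit(X[train], y[train])
            p = clf.predict_proba(X[test])
            folds.append(FoldRecord(
                repeat=repeat, held_out_individual=ind,
                train_individuals=sorted(set(ind_arr[train])),
                n_train=len(train), n_test=len(test)))
            full = np.zeros((len(test), len(classes)))
            for k, c in enumerate(clf.classes_):
                full[:, classes.index(c)] = p[:, k]
            proba = full if proba is None else np.vstack([proba, full])
            order = np.concatenate([order, test])
        return order, proba

    rng = np.random.default_rng(seed)
    repeat_seeds = rng.integers(0, 2**31 - 1, size=n_repeats)
    y_all = labels.to_numpy()
    if mode == "multiclass":
        classes = sorted(labels.dropna().unique())
        for rep, rs in enumerate(repeat_seeds):
            order, proba = run_cv(np.ones(len(X), dtype=bool), y_all, rep,
                                  int(rs))
            if len(classes) == 2:
                auroc = roc_auc_score(
                    (y_all[order] == classes[1]).astype(int), proba[:, 1])
            else:
                auroc = roc_auc_score(y_all[order], proba, multi_class="ovr",
                                      average="macro", labels=classes)
            rows.append({"class_a": "all", "class_b": "all", "repeat": rep,
                         "auroc": float(auroc)})
    else:
        all_classes = sorted(labels.dropna().unique())
        for ca, cb in itertools.combinations(all_classes, 2):
            classes = [ca, cb]
            mask = np.isin(y_all, classes)
            for rep, rs in enumerate(repeat_seeds):
                order, proba = run_cv(mask, y_all, rep, int(rs))
                auroc = roc_auc_score(
                    (y_all[order] == cb).astype(int), proba[:, 1])
                rows.append({"class_a": ca, "class_b": cb, "repeat": rep,
                             "auroc": float(auroc)})
    table = pd.DataFrame(rows, columns=["class_a", "class_b", "repeat",
                                        "auroc"])
    return ClassificationResult(auroc=table, folds=folds)


def audit_folds(result: ClassificationResult) -> bool:
    """True iff no individual ever appears in both train and test."""
    return all(f.held_out_individual not in f.train_individuals
               for f in result.folds)


def pca_scores(
    conc: ConcentrationMatrix,
    n_components: int = 2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA scores on log10-transformed, column-standardized data.

    Zeros are imputed to half the smallest positive value before the
    log transform. Returns (scores, explained-variance fractions).
    """
    X = conc.values.to_numpy(dtype=float).copy()
    pos = X[X > 0]
    if pos.size == 0:
        raise ValidationError("concentration matrix has no positive values")
    X[X == 0] = pos.min() / 2.0
    X = np.log10(X)
    if np.allclose(X.std(axis=0), 0):
        raise ValidationError("constant matrix: PCA undefined")
    X = StandardScaler().fit_transform(X)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (pd.DataFrame(scores, index=conc.values.index, columns=cols),
            pca.explained_variance_ratio_)


def pooled_class_sd(
    conc: ConcentrationMatrix,
    class_map: Mapping[str, str],
) -> pd.DataFrame:
    """Pooled over-time SD per (blood matrix, lipid class).

    Per lipid, the variance of the per-time-point mean concentration is
    computed within each matrix; variances are pooled across the lipids
    of a class as sum((n_i-1)*var_i)/sum(n_i-1), and the square root is
    reported.
    """
    fac = conc.factors()
    rows = []
    skipped: set[str] = set()
    for matrix in conc.matrices:
        ids = fac[fac["matrix"] == matrix]
        by_class: dict[str, list[tuple[float, int]]] = {}
        for lipid in conc.values.columns:
            cls = class_map.get(lipid)
            if cls is None:
                skipped.add(lipid)
                continue
            tp_means = (conc.values.loc[ids.index, lipid]
                        .groupby(ids["time_point"]).mean())
            if len(tp_means) < 2:
                raise ValidationError(
                    f"lipid {lipid!r}: need >= 2 time points in {matrix!r}"
                )
            var = float(tp_means.var(ddof=1))
            by_class.setdefault(cls, []).append((var, len(tp_means)))
        for cls, items in sorted(by_class.items()):
            num = sum((n - 1) * v for v, n in items)
            den = sum(n - 1 for _, n in items)
            rows.append({"matrix": matrix, "lipid_class": cls,
                         "pooled_sd": float(np.sqrt(num / den)),
                         "n_lipids": len(items)})
    return pd.DataFrame(rows, columns=["matrix", "lipid_class", "pooled_sd",
                                       "n_lipids"])


# numerator/denominator pairs feeding the published cardiovascular risk
# score; the score's coefficients are external and not computed here
MARKER_RATIOS: tuple[tuple[str, str, str], ...] = (
    ("Cer d18:1_24:1/Cer d18:1_24:0", "Cer d18:1_24:1", "Cer d18:1_24:0"),
    ("Cer d18:1_16:0/PC 38:5", "Cer d18:1_16:0", "PC 38:5"),
    ("Cer d18:1_18:0/PC 14:0_22:6", "Cer d18:1_18:0", "PC 14:0_22:6"),
)
MARKER_CONCENTRATION = "PC 16:0_16:0"


def marker_ratios(conc: ConcentrationMatrix) -> pd.DataFrame:
    """Per-sample risk-score inputs: three ceramide/PC molar ratios plus
    the PC 16:0_16:0 concentration."""
    needed = {s for _, num, den in MARKER_RATIOS for s in (num, den)}
    needed.add(MARKER_CONCENTRATION)
    missing = sorted(needed - set(conc.values.columns))
    if missing:
        raise ValidationError(f"missing marker species: {missing}")
    out = pd.DataFrame(index=conc.values.index)
    for label, num, den in MARKER_RATIOS:
        d = conc.values[den].to_numpy(dtype=float)
        if np.any(d == 0):
            bad = conc.values.index[d == 0].tolist()
            raise ValidationError(
                f"zero denominator {den!r} in samples {bad}"
            )
        out[label] = conc.values[num].to_numpy(dtype=float) / d
    out[MARKER_CONCENTRATION] = conc.values[MARKER_CONCENTRATION]
    return out
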
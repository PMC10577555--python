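"""Age-state classification from signature-gene expression.

Cells are the classification units: features are the log-normalized
expression of the signature genes (all, up-only, or down-only), the label
is the donor age group. Cells are split 90:10 into train and test within
(sample, cell type, age group) strata, a random forest (500 trees, sqrt-p
features per split, Gini) is trained under three-times-repeated stratified
10-fold cross-validation, and held-out performance is summarized with
AUROC (midrank statistic), accuracy at a 0.5 vote threshold, and
mean-decrease-in-impurity variable importance.

Because cell-level splits place cells of the same donor on both sides, a
leave-samples-out mode is also provided for donor-level generalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold

from .qc import LogNormMatrix
from .signature import SignatureSet


@dataclass
class SplitSpec:
    test_fraction: float = 0.10
    seed: int = 0
    min_cells_per_celltype: int = 200

    def validate(self) -> None:
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must be in (0, 1)")
        if self.min_cells_per_celltype < 0:
            raise ValueError("min_cells_per_celltype must be nonnegative")


@dataclass
class CvSpec:
    n_repeats: int = 3
    n_folds: int = 10
    n_trees: int = 500
    seed: int = 0

    def validate(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if self.n_repeats < 1 or self.n_trees < 1:
            raise ValueError("n_repeats and n_trees must be positive")


def make_features(
    lognorm: LogNormMatrix,
    signature: SignatureSet,
    meta: pd.DataFrame,
    subset: str = "all",
) -> tuple[pd.DataFrame, pd.Series]:
    """Cells x signature-genes expression matrix plus YOUNG/AGED labels.

    MIDDLE-aged cells are dropped; signature genes absent from the matrix
    are dropped with a warning.
    """
    genes = signature.genes(subset)
    if not genes:
        raise ValueError(f"signature has no genes for subset {subset!r}")
    gene_pos = {g: i for i, g in enumerate(lognorm.genes)}
    present = [g for g in genes if g in gene_pos]
    if not present:
        raise ValueError("no signature genes present in the matrix")
    if len(present) < len(genes):
        warnings.warn(f"{len(genes) - len(present)} signature gene(s) absent, dropped")
    meta = meta.loc[[c for c in lognorm.cells if c in meta.index]]
    keep_cells = meta.index[meta["age_group"].isin(["YOUNG", "AGED"])]
    cell_pos = {c: j for j, c in enumerate(lognorm.cells)}
    cols = [cell_pos[c] for c in keep_cells]
    rows = [gene_pos[g] for g in present]
    X = pd.DataFrame(
        lognorm.values[rows][:, cols].toarray().T, index=keep_cells, columns=present
    )
    y = meta.loc[keep_cells, "age_group"].copy()
    return X, y


def stratified_split(
    meta: pd.DataFrame, spec: SplitSpec | None = None
) -> tuple[list[str], list[str]]:
    """Seeded 90:10 split within (sample, cell_type, age_group) strata.

    Cell types with ``min_cells_per_celltype`` or fewer cells are removed
    entirely before splitting. ceil(test_fraction * n) cells per stratum go
    to test; singleton strata go to train with a warning. Train and test
    are disjoint and together exhaust the retained cells.
    """
    spec = spec or SplitSpec()
    spec.validate()
    meta = meta[meta["age_group"].isin(["YOUNG", "AGED"])]
    ct_counts = meta["cell_type"].value_counts()
    kept_ct = ct_counts.index[ct_counts > spec.min_cells_per_celltype]
    meta = meta[meta["cell_type"].isin(kept_ct)]
    if meta.empty:
        raise ValueError("no cell type exceeds min_cells_per_celltype")
    rng = np.random.default_rng(spec.seed)
    train: list[str] = []
    test: list[str] = []
    for _, sub in meta.groupby(["sample", "cell_type", "age_group"], sort=True):
        ids = list(sub.index)
        n = len(ids)
        if n == 1:
            warnings.warn("stratum of size 1 assigned to train")
            train.extend(ids)
            continue
        n_test = min(int(np.ceil(spec.test_fraction * n)), n - 1)
        pick = rng.choice(n, size=n_test, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[pick] = True
        test.extend([ids[i] for i in range(n) if mask[i]])
        train.extend([ids[i] for i in range(n) if not mask[i]])
    return train, test


def leave_samples_out_split(
    meta: pd.DataFrame, test_samples: list[str]
) -> tuple[list[str], list[str]]:
    """Donor-held-out alternative: whole samples go to test."""
    meta = meta[meta["age_group"].isin(["YOUNG", "AGED"])]
    is_test = meta["sample"].isin(test_samples)
    return list(meta.index[~is_test]), list(meta.index[is_test])


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC from the midrank (Mann-Whitney) statistic.

    ``labels`` is boolean (True = positive). Ties contribute 1/2 per pair.
    Returns NaN when either class is absent.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    r = rankdata(scores)
    return float((r[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def train_rf(
    X: pd.DataFrame, y: pd.Series, cv: CvSpec | None = None
) -> tuple[RandomForestClassifier, dict]:
    """Fit the random forest and report repeated stratified CV AUROC.

    Deterministic given ``cv.seed``. Raises when the training labels
    contain a single class.
    """
    cv = cv or CvSpec()
    cv.validate()
    y_bin = (np.asarray(y) == "AGED").astype(int)
    if len(np.unique(y_bin)) < 2:
        raise ValueError("training labels contain a single class")
    Xv = np.asarray(X, dtype=float)
    splitter = RepeatedStratifiedKFold(
        n_splits=cv.n_folds, n_repeats=cv.n_repeats, random_state=cv.seed
    )
    aucs = []
    for tr, te in splitter.split(Xv, y_bin):
        m = RandomForestClassifier(
            n_estimators=cv.n_trees, max_features="sqrt", random_state=cv.seed, n_jobs=1
        )
        m.fit(Xv[tr], y_bin[tr])
        p = m.predict_proba(Xv[te])[:, list(m.classes_).index(1)]
        aucs.append(auroc(p, y_bin[te] == 1))
    model = RandomForestClassifier(
        n_estimators=cv.n_trees, max_features="sqrt", random_state=cv.seed, n_jobs=1
    )
    model.fit(Xv, y_bin)
    model.feature_names_ = list(X.columns)
    return model, {"cv_auroc_mean": float(np.mean(aucs)), "cv_auroc_sd": float(np.std(aucs, ddof=1))}


def evaluate(
    model: RandomForestClassifier,
    X: pd.DataFrame,
    y: pd.Series,
    cell_types: pd.Series | None = None,
) -> dict:
    """Held-out AUROC, accuracy at the 0.5 vote threshold, confusion counts
    and per-cell-type accuracy. One-class test sets get AUROC = NaN with
    accuracy only (the external all-aged validation case)."""
    if len(X) == 0:
        raise ValueError("test set is empty")
    y_bin = (np.asarray(y) == "AGED").astype(int)
    p = model.predict_proba(np.asarray(X, dtype=float))[:, list(model.classes_).index(1)]
    pred = (p >= 0.5).astype(int)
    acc = float((pred == y_bin).mean())
    report = {
        "auroc": auroc(p, y_bin == 1),
        "accuracy": acc,
        "confusion": {
            "tp": int(((pred == 1) & (y_bin == 1)).sum()),
            "fp": int(((pred == 1) & (y_bin == 0)).sum()),
            "fn": int(((pred == 0) & (y_bin == 1)).sum()),
            "tn": int(((pred == 0) & (y_bin == 0)).sum()),
        },
        "n_test": int(len(y_bin)),
    }
    if cell_types is not None:
        per_ct = {}
        for ct in sorted(pd.unique(cell_types)):
            m = np.asarray(cell_types) == ct
            per_ct[str(ct)] = float((pred[m] == y_bin[m]).mean())
        report["per_celltype_accuracy"] = per_ct
    return report


def variable_importance(
    model: RandomForestClassifier,
    top_k: int = 20,
    deg_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mean-decrease-in-impurity importances, descending, ties broken
    lexicographically by gene; optionally annotated with the cell types
    where each gene was called a DEG."""
    names = getattr(model, "feature_names_", None)
    if names is None:
        names = [f"f{i}" for i in range(len(model.feature_importances_))]
    imp = pd.DataFrame({"gene": names, "importance": model.feature_importances_})
    imp = imp.sort_values(["importance", "gene"], ascending=[False, True], kind="stable")
    imp = imp.head(min(top_k, len(imp))).reset_index(drop=True)
    if deg_table is not None:
        sig = deg_table[deg_table["direction"].isin(["up", "down"])]
        ann = sig.groupby("gene")["cell_type"].apply(lambda s: sorted(set(s)))
        imp["deg_celltypes"] = imp["gene"].map(ann).apply(
            lambda v: v if isinstance(v, list) else []
        )
    return imp
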
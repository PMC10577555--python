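"""Control-gene-subtracted module scores and group comparisons.

The score of a gene set in a cell is the mean log-normalized expression of
the set genes minus the mean expression of a pooled panel of randomly
drawn, expression-matched control genes: genes are ranked by dataset-mean
expression and cut into equal-frequency bins, and each set gene draws
``n_ctrl_per_gene`` controls (with replacement) from its own bin, set genes
excluded from the pool. Matching controls by expression centers random
gene sets at zero and absorbs depth effects.

Group differences per cell type are assessed with a two-sided Wilcoxon
rank-sum test (exact enumeration for small groups, normal approximation
with tie and continuity correction otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .qc import LogNormMatrix


@dataclass
class ScoreConfig:
    n_bins: int = 24
    n_ctrl_per_gene: int = 100
    seed: int = 0
    min_set_genes_present: int = 2

    def validate(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be at least 1")
        if self.n_ctrl_per_gene < 1:
            raise ValueError("n_ctrl_per_gene must be at least 1")
        if self.min_set_genes_present < 1:
            raise ValueError("min_set_genes_present must be at least 1")


def _expression_bins(mean_expr: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin id per gene; ties broken by stable gene order."""
    order = np.argsort(mean_expr, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return (rank * n_bins) // len(order)


def module_score(
    lognorm: LogNormMatrix,
    gene_set,
    cfg: ScoreConfig | None = None,
    set_name: str = "set",
) -> pd.DataFrame:
    """Per-cell control-subtracted score of one gene set.

    Deterministic given ``cfg.seed``. Genes absent from the matrix are
    dropped with a warning; fewer than ``min_set_genes_present`` present
    genes is an error.
    """
    cfg = cfg or ScoreConfig()
    cfg.validate()
    n_genes = len(lognorm.genes)
    if cfg.n_bins > n_genes:
        raise ValueError(f"n_bins={cfg.n_bins} exceeds number of genes {n_genes}")
    gene_pos = {g: i for i, g in enumerate(lognorm.genes)}
    present = [g for g in gene_set if g in gene_pos]
    missing = [g for g in gene_set if g not in gene_pos]
    if missing:
        warnings.warn(f"{set_name}: {len(missing)} gene(s) absent from matrix, dropped")
    if len(present) < cfg.min_set_genes_present:
        raise ValueError(
            f"{set_name}: only {len(present)} set gene(s) present; "
            f"need at least {cfg.min_set_genes_present}"
        )
    set_idx = np.asarray([gene_pos[g] for g in present])

    x = lognorm.values.tocsr()
    mean_expr = np.asarray(x.mean(axis=1)).ravel()
    bins = _expression_bins(mean_expr, cfg.n_bins)

    in_set = np.zeros(n_genes, dtype=bool)
    in_set[set_idx] = True
    rng = np.random.default_rng(cfg.seed)
    ctrl_weight = np.zeros(n_genes)
    for gi in set_idx:
        pool = np.flatnonzero((bins == bins[gi]) & ~in_set)
        if pool.size == 0:
            # degenerate bin fully occupied by set genes: widen to all non-set genes
            pool = np.flatnonzero(~in_set)
            warnings.warn(f"{set_name}: control pool empty in bin {bins[gi]}, using all genes")
        draws = rng.choice(pool, size=cfg.n_ctrl_per_gene, replace=True)
        np.add.at(ctrl_weight, draws, 1.0)

    set_mean = np.asarray(x[set_idx].mean(axis=0)).ravel()
    w = ctrl_weight / ctrl_weight.sum()
    ctrl_mean = np.asarray(w @ x).ravel()
    score = set_mean - ctrl_mean
    return pd.DataFrame({"cell": lognorm.cells, "set": set_name, "score": score})


def _wilcoxon(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum p for a vs b; exact when both groups <= 10 and
    tie-free, else normal approximation with tie and continuity correction."""
    exact = len(a) <= 10 and len(b) <= 10 and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic",
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    scores: pd.DataFrame,
    meta: pd.DataFrame,
    by_celltype: bool = True,
    per_sample: bool = False,
) -> pd.DataFrame:
    """Aged-vs-young score comparison, overall or per cell type.

    ``per_sample=True`` first averages scores within each sample so that
    donors, not cells, are the test units (cell-level tests treat
    correlated cells as independent replicates).
    """
    df = scores.merge(
        meta[["sample", "cell_type", "age_group"]], left_on="cell", right_index=True
    )
    df = df[df["age_group"].isin(["YOUNG", "AGED"])]
    groups = df.groupby(["set", "cell_type"]) if by_celltype else df.groupby(["set"])
    rows = []
    for key, sub in groups:
        set_name = key[0]
        ct = key[1] if by_celltype else "all"
        if per_sample:
            sub = (
                sub.groupby(["sample", "age_group"], as_index=False)["score"].mean()
            )
        young = sub.loc[sub["age_group"] == "YOUNG", "score"].to_numpy()
        aged = sub.loc[sub["age_group"] == "AGED", "score"].to_numpy()
        if len(young) == 0 or len(aged) == 0:
            warnings.warn(f"{set_name}/{ct}: one age group absent, skipped")
            continue
        stat, p = _wilcoxon(aged, young)
        rows.append(
            {
                "set": set_name,
                "cell_type": ct,
                "n_young": len(young),
                "n_aged": len(aged),
                "statistic": stat,
                "pvalue": p,
                "median_diff": float(np.median(aged) - np.median(young)),
            }
        )
    return pd.DataFrame(rows)


def senescence_scores(
    lognorm: LogNormMatrix,
    gene_sets: dict[str, list[str]],
    cfg: ScoreConfig | None = None,
) -> pd.DataFrame:
    """Module scores for each senescence set and their deduplicated union."""
    cfg = cfg or ScoreConfig()
    parts = [module_score(lognorm, genes, cfg, set_name=name) for name, genes in gene_sets.items()]
    if len(gene_sets) > 1:
        union: list[str] = []
        seen: set[str] = set()
        for genes in gene_sets.values():
            for g in genes:
                if g not in seen:
                    seen.add(g)
                    union.append(g)
        parts.append(module_score(lognorm, union, cfg, set_name="union"))
    return pd.concat(parts, ignore_index=True)


def set_overlap(a, b) -> tuple[int, list[str]]:
    """Exact intersection of two gene lists: (size, sorted members)."""
    inter = sorted(set(a) & set(b))
    return len(inter), inter
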
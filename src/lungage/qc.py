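"""Cell-level quality control and log-normalization.

Cells are kept when they have strictly more than ``min_features`` detected
genes and a mitochondrial fraction strictly below ``max_mito_fraction``.
Scoring operates on log-CP10K values: ln(1 + count / cell_total * scale).
Differential testing never sees this layer; it runs on raw pseudobulk
counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .synthetic import CountMatrix


@dataclass
class QcConfig:
    min_features: int = 200
    max_mito_fraction: float = 0.35
    lognorm_scale: float = 1e4

    def validate(self) -> None:
        if self.min_features < 0:
            raise ValueError("min_features must be nonnegative")
        if not (0 < self.max_mito_fraction <= 1):
            raise ValueError("max_mito_fraction must be in (0, 1]")
        if self.lognorm_scale <= 0:
            raise ValueError("lognorm_scale must be positive")


@dataclass
class LogNormMatrix:
    """Genes x cells log-normalized expression (same layout as CountMatrix)."""

    genes: list[str]
    cells: list[str]
    values: sp.csr_matrix

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def filter_cells(
    counts: CountMatrix, meta: pd.DataFrame, cfg: QcConfig | None = None
) -> tuple[CountMatrix, pd.DataFrame, dict]:
    """Apply the two cell-level QC cutoffs; both inequalities are strict.

    Returns the filtered matrix, filtered metadata (same cell order) and a
    report of removal counts per criterion. The gene set is unchanged.
    Raises if no cell survives.
    """
    cfg = cfg or QcConfig()
    cfg.validate()
    if set(meta.index) != set(counts.cells):
        raise ValueError("metadata cell set does not match count matrix cells")
    meta = meta.loc[counts.cells]
    feat_ok = meta["n_features"].to_numpy() > cfg.min_features
    mito_ok = meta["mito_fraction"].to_numpy() < cfg.max_mito_fraction
    keep = feat_ok & mito_ok
    report = {
        "n_input": int(len(keep)),
        "removed_low_features": int((~feat_ok).sum()),
        "removed_high_mito": int((~mito_ok).sum()),
        "removed_total": int((~keep).sum()),
        "n_kept": int(keep.sum()),
        "min_features": cfg.min_features,
        "max_mito_fraction": cfg.max_mito_fraction,
    }
    if not keep.any():
        raise ValueError("no cells survive QC")
    kept_cells = [c for c, k in zip(counts.cells, keep) if k]
    out = CountMatrix(
        genes=list(counts.genes), cells=kept_cells, counts=counts.counts[:, keep].tocsr()
    )
    return out, meta.loc[kept_cells], report


def lognormalize(counts: CountMatrix, scale: float = 1e4) -> LogNormMatrix:
    """log-CP10K: value = ln(1 + count / cell_total * scale), per cell.

    A purely column-wise operation: zero counts stay exactly zero and
    doubling every count in a cell leaves its values unchanged.
    """
    totals = np.asarray(counts.counts.sum(axis=0)).ravel()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"cell has zero total count: {counts.cells[zero[0]]}")
    x = counts.counts.tocsc(copy=True).astype(float)
    # scale each stored entry by its cell total, then log1p in place
    percell = np.repeat(totals, np.diff(x.indptr))
    x.data = np.log1p(x.data / percell * scale)
    return LogNormMatrix(genes=list(counts.genes), cells=list(counts.cells), values=x.tocsr())
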
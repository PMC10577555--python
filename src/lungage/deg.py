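"""Pseudobulk negative-binomial differential expression between age groups.

Counts are summed to sample x cell-type pseudobulk so donors, not cells,
are the units of replication. Per cell type, each gene is tested with a
likelihood-ratio test comparing an NB log-linear model with batch and age
terms against the batch-only reduction, at fixed gene-wise dispersion:

    full:    log mu = log(sizefactor) + b0 + b_batch + b_age
    reduced: log mu = log(sizefactor) + b0 + b_batch

2 * (ll_full - ll_reduced) is referred to chi-square with 1 df. Batch is a
model covariate rather than a separate correction pass. P-values are
BH-adjusted within each cell type (each cell type is its own family) and
genes are called up/down at FDR < 0.1. MIDDLE-aged cells are excluded
before aggregation; cell types with fewer than 500 cells are not tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .synthetic import CountMatrix


@dataclass
class DegConfig:
    min_cells_per_cluster: int = 500
    min_samples_per_group: int = 2
    fdr_threshold: float = 0.1
    min_total_count: int = 10
    dispersion_floor: float = 0.001
    dispersion_shrink: float = 0.3
    independent_filtering: bool = True

    def validate(self) -> None:
        if self.min_cells_per_cluster < 0:
            raise ValueError("min_cells_per_cluster must be nonnegative")
        if self.min_samples_per_group < 1:
            raise ValueError("min_samples_per_group must be at least 1")
        if not (0 < self.fdr_threshold < 1):
            raise ValueError("fdr_threshold must be in (0, 1)")
        if self.dispersion_floor <= 0:
            raise ValueError("dispersion_floor must be positive")
        if not (0 <= self.dispersion_shrink <= 1):
            raise ValueError("dispersion_shrink must be in [0, 1]")


@dataclass
class PseudobulkMatrix:
    """Summed counts for one cell type: genes x samples, with design labels."""

    cell_type: str
    genes: list[str]
    sample_ids: list[str]
    age_groups: list[str]      # YOUNG/AGED per sample column
    batches: list[str]         # batch label per sample column
    counts: np.ndarray         # genes x samples, integer
    n_cells_per_sample: list[int]
    # per-gene cell-level NB dispersion scaled to the pseudobulk: a sum of
    # n cells has Var = M + (alpha_cell * sum(sf^2)/sum(sf)^2) * M^2, so this
    # is a physically implied lower bound on the pseudobulk dispersion
    cell_dispersion: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return int(sum(self.n_cells_per_sample))


def aggregate_pseudobulk(counts: CountMatrix, meta: pd.DataFrame) -> list[PseudobulkMatrix]:
    """Sum cell counts to sample level within each cell type.

    MIDDLE-aged cells are dropped; only the YOUNG/AGED contrast is kept.
    One matrix per cell type present; strata with no cells are simply
    absent.
    """
    if set(meta.index) != set(counts.cells):
        raise ValueError("metadata cell set does not match count matrix cells")
    meta = meta.loc[counts.cells]
    keep = meta["age_group"].isin(["YOUNG", "AGED"]).to_numpy()
    meta = meta.loc[keep]
    x = counts.counts[:, keep]

    out = []
    ct_arr = meta["cell_type"].to_numpy()
    sample_arr = meta["sample"].to_numpy()
    x_csc = x.tocsc()
    libsize = np.asarray(x.sum(axis=0)).ravel()
    for ct in sorted(pd.unique(ct_arr)):
        in_ct = ct_arr == ct
        samples = sorted(pd.unique(sample_arr[in_ct]))
        cols = np.zeros((len(genes_ := counts.genes), len(samples)), dtype=np.int64)
        n_cells = []
        ages, batches = [], []
        disp_num = np.zeros(len(genes_))
        disp_den = 0.0
        pb_scale = []
        for j, s in enumerate(samples):
            sel = in_ct & (sample_arr == s)
            cols[:, j] = np.asarray(x[:, sel].sum(axis=1)).ravel()
            n_cells.append(int(sel.sum()))
            sub = meta.loc[sel]
            age = sub["age_group"].unique()
            batch = sub["batch"].unique()
            if len(age) != 1 or len(batch) != 1:
                raise ValueError(f"sample {s}: inconsistent age_group or batch labels")
            ages.append(str(age[0]))
            batches.append(str(batch[0]))
            # cell-level NB moments within the sample (cells share the gene
            # mean up to a library-size factor)
            n = int(sel.sum())
            if n >= 3 and libsize[sel].min() > 0:
                sf = libsize[sel] / libsize[sel].mean()
                z = x_csc[:, sel].multiply(1.0 / sf[None, :]).tocsr()
                m = np.asarray(z.mean(axis=1)).ravel()
                sq = np.asarray(z.multiply(z).mean(axis=1)).ravel()
                s2 = (sq - m**2) * n / (n - 1)
                h = float(np.mean(1.0 / sf))
                with np.errstate(divide="ignore", invalid="ignore"):
                    a = (s2 - m * h) / m**2
                ok = (m > 0) & np.isfinite(a)
                disp_num[ok] += (n - 1) * a[ok]
                disp_den += n - 1
                pb_scale.append(float((sf**2).sum() / sf.sum() ** 2))
        cell_disp = None
        if disp_den > 0 and pb_scale:
            cell_disp = np.maximum(disp_num / disp_den, 0.0) * float(np.mean(pb_scale))
        out.append(
            PseudobulkMatrix(
                cell_type=str(ct),
                genes=list(genes_),
                sample_ids=samples,
                age_groups=ages,
                batches=batches,
                counts=cols,
                n_cells_per_sample=n_cells,
                cell_dispersion=cell_disp,
            )
        )
    return out


def exclude_small_clusters(
    pbs: list[PseudobulkMatrix], cfg: DegConfig | None = None
) -> list[PseudobulkMatrix]:
    """Drop cell types too small or too unbalanced to test.

    A cell type is kept when it has at least ``min_cells_per_cluster`` cells
    in total and at least ``min_samples_per_group`` samples in each age
    group.
    """
    cfg = cfg or DegConfig()
    cfg.validate()
    kept = []
    for pb in pbs:
        ages = np.asarray(pb.age_groups)
        if pb.n_cells < cfg.min_cells_per_cluster:
            continue
        if (ages == "YOUNG").sum() < cfg.min_samples_per_group:
            continue
        if (ages == "AGED").sum() < cfg.min_samples_per_group:
            continue
        kept.append(pb)
    if not kept:
        raise ValueError("all cell types excluded: none meet the size/balance thresholds")
    return kept


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (genes x samples input).

    Uses genes with all-positive counts for the gene-wise geometric means;
    falls back to total-count factors when no such gene exists. Factors are
    scaled to geometric mean 1.
    """
    counts = np.asarray(counts, dtype=float)
    allpos = (counts > 0).all(axis=1)
    if allpos.sum() >= 1:
        logg = np.log(counts[allpos])
        loggeo = logg.mean(axis=1)
        sf = np.exp(np.median(logg - loggeo[:, None], axis=0))
    else:
        totals = counts.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("sample with zero total count")
        sf = totals
    sf = sf / np.exp(np.mean(np.log(sf)))
    return sf


def estimate_dispersions(pb: PseudobulkMatrix, cfg: DegConfig | None = None) -> pd.DataFrame:
    """Gene-wise method-of-moments NB dispersion on normalized counts.

    alpha_hat = max(floor, (s^2 - m) / m^2) on size-factor-normalized
    values, with the moments taken within each age x batch design group and
    pooled (df-weighted) so that a real age effect does not inflate its own
    gene's dispersion. The estimate is then linearly shrunk toward the
    median alpha with weight ``dispersion_shrink``. All-zero genes get the
    floor and are flagged.
    """
    cfg = cfg or DegConfig()
    cfg.validate()
    if len(pb.sample_ids) < 3:
        raise ValueError("need at least 3 samples to estimate dispersions")
    sf = size_factors(pb.counts)
    norm = pb.counts / sf[None, :]
    m = norm.mean(axis=1)
    # within-group moments so the age effect itself does not inflate the
    # dispersion of truly differential genes
    design = [f"{a}|{b}" for a, b in zip(pb.age_groups, pb.batches)]
    raw_num = np.zeros(len(pb.genes))
    raw_den = np.zeros(len(pb.genes))
    for grp in sorted(set(design)):
        cols = np.asarray([d == grp for d in design])
        if cols.sum() < 2:
            continue
        mk = norm[:, cols].mean(axis=1)
        s2k = norm[:, cols].var(axis=1, ddof=1)
        w = cols.sum() - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            ak = (s2k - mk) / mk**2
        ok = mk > 0
        raw_num[ok] += w * ak[ok]
        raw_den[ok] += w
    if (raw_den == 0).all():
        # no design group has replication: fall back to pooled moments
        s2 = norm.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = (s2 - m) / m**2
        raw_den[:] = 1.0
        raw_num = raw
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = raw_num / raw_den
    allzero = m == 0
    raw[allzero | (raw_den == 0) | ~np.isfinite(raw)] = cfg.dispersion_floor
    if pb.cell_dispersion is not None:
        # The cell-level sampling variance implies a per-gene value the
        # pseudobulk dispersion cannot fall below; shrink the noisy
        # donor-level MoM toward that per-gene target and floor at it, so
        # extra donor-level variance is kept while MoM noise is damped.
        target = pb.cell_dispersion
        alpha = (1.0 - cfg.dispersion_shrink) * raw + cfg.dispersion_shrink * target
        alpha = np.maximum.reduce([alpha, target, np.full_like(alpha, cfg.dispersion_floor)])
    else:
        alpha = np.maximum(cfg.dispersion_floor, raw)
        med = float(np.median(alpha))
        shrunk = (1.0 - cfg.dispersion_shrink) * alpha + cfg.dispersion_shrink * med
        # shrink only upward: pulling genuinely high-dispersion genes toward
        # the median would understate their variance and inflate false
        # discoveries
        alpha = np.maximum(alpha, shrunk)
    return pd.DataFrame(
        {"alpha": alpha, "all_zero": allzero, "mean_norm": m}, index=pb.genes
    )


# ---------------------------------------------------------------------------
# NB GLM fitting


def _nb_negloglik(beta: np.ndarray, y: np.ndarray, X: np.ndarray, offset: np.ndarray,
                  alpha: float, ridge: float = 0.0) -> float:
    r = 1.0 / alpha
    eta = X @ beta + offset
    eta = np.clip(eta, -30, 30)
    mu = np.exp(eta)
    ll = (
        special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1)
        + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu) + 1e-300)
    ).sum()
    return -ll + ridge * float(beta @ beta)


def _nb_negloglik_grad(beta: np.ndarray, y: np.ndarray, X: np.ndarray, offset: np.ndarray,
                       alpha: float, ridge: float = 0.0) -> np.ndarray:
    r = 1.0 / alpha
    eta = np.clip(X @ beta + offset, -30, 30)
    mu = np.exp(eta)
    w = (y - mu) * r / (r + mu)
    return -(X.T @ w) + 2.0 * ridge * beta


def _fit_ridge(y, X, offset, alpha, ridge=1e-6):
    beta0 = np.zeros(X.shape[1])
    beta0[0] = np.log(max(y.mean(), 0.1)) - np.mean(offset)
    res = optimize.minimize(
        _nb_negloglik, beta0, args=(y, X, offset, alpha, ridge),
        jac=_nb_negloglik_grad, method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
    )
    llf = -_nb_negloglik(res.x, y, X, offset, alpha, 0.0)
    return res.x, llf


def _fit_nb(y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: float):
    """Fit NB GLM (log link, fixed alpha). Returns (beta, llf, flag)."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset)
            res = model.fit(maxiter=200, tol=1e-10)
        if np.all(np.isfinite(res.params)) and np.isfinite(res.llf):
            return res.params, float(res.llf), ""
    except (PerfectSeparationError, ValueError, np.linalg.LinAlgError):
        pass
    beta, llf = _fit_ridge(y, X, offset, alpha)
    if not np.all(np.isfinite(beta)) or not np.isfinite(llf):
        return None, np.nan, "failed"
    return beta, llf, "ridge"


def _design_matrices(pb: PseudobulkMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Full (intercept + batch dummies + age) and reduced (no age) designs."""
    ages = np.asarray(pb.age_groups)
    batches = np.asarray(pb.batches)
    age_col = (ages == "AGED").astype(float)
    if age_col.min() == age_col.max():
        raise ValueError("contrast not estimable: age group is constant")
    cols = [np.ones(len(ages))]
    for b in sorted(set(batches))[1:]:
        cols.append((batches == b).astype(float))
    X_red = np.column_stack(cols)
    X_full = np.column_stack(cols + [age_col])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("contrast not estimable: age is collinear with batch/intercept")
    return X_full, X_red


def nb_lrt(
    pb: PseudobulkMatrix,
    dispersions: pd.DataFrame,
    cfg: DegConfig | None = None,
) -> pd.DataFrame:
    """Per-gene likelihood-ratio test for the age term, one cell type.

    Genes below the ``min_total_count`` prefilter get NA p-values and do
    not count toward the multiplicity m of the BH adjustment. Separation
    and non-convergence fall back to a ridge-stabilized fit (penalty 1e-6)
    and are flagged.
    """
    cfg = cfg or DegConfig()
    cfg.validate()
    X_full, X_red = _design_matrices(pb)
    sf = size_factors(pb.counts)
    offset = np.log(sf)
    alphas = dispersions["alpha"].reindex(pb.genes).to_numpy()
    ages = np.asarray(pb.age_groups)
    aged = ages == "AGED"

    rows = []
    norm = pb.counts / sf[None, :]
    ln2 = np.log(2.0)
    for gi, gene in enumerate(pb.genes):
        y = pb.counts[gi].astype(float)
        mean_expr = float(norm[gi].mean())
        if y.sum() < cfg.min_total_count:
            rows.append((pb.cell_type, gene, np.nan, np.nan, np.nan, mean_expr, "prefiltered"))
            continue
        alpha = float(alphas[gi])
        flag = ""
        # complete separation: expressed in exactly one age group
        if (y[aged].sum() == 0) != (y[~aged].sum() == 0) and min(y[aged].sum(), y[~aged].sum()) == 0:
            bf, llf_full = _fit_ridge(y, X_full, offset, alpha)
            br, llf_red = _fit_ridge(y, X_red, offset, alpha)
            flag = "separation"
        else:
            bf, llf_full, f1 = _fit_nb(y, X_full, offset, alpha)
            br, llf_red, f2 = _fit_nb(y, X_red, offset, alpha)
            flag = f1 or f2
        if bf is None or br is None or not np.isfinite(llf_full) or not np.isfinite(llf_red):
            rows.append((pb.cell_type, gene, np.nan, np.nan, np.nan, mean_expr, "failed"))
            continue
        lrt = max(0.0, 2.0 * (llf_full - llf_red))
        pval = float(stats.chi2.sf(lrt, df=1))
        log2fc = float(bf[-1] / ln2)
        rows.append((pb.cell_type, gene, log2fc, lrt, pval, mean_expr, flag))
    return pd.DataFrame(
        rows,
        columns=["cell_type", "gene", "log2fc", "lrt_stat", "pvalue", "mean_expr", "flag"],
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up; NA values pass through untouched."""
    p = np.asarray(pvalues, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _filtered_bh(pvalues: np.ndarray, mean_expr: np.ndarray, enable: bool) -> np.ndarray:
    """BH with independent filtering on mean expression.

    Scans lower-quantile cutoffs on mean expression and keeps the one that
    maximizes the number of discoveries at FDR < 0.1, the default behavior
    of standard pseudobulk count-model packages; genes removed by the
    filter keep an NA adjusted value. Filtering on the mean is valid
    because the mean is independent of the test statistic under the null.
    """
    if not enable:
        return bh_adjust(pvalues)
    testable = ~np.isnan(pvalues)
    best_fdr = bh_adjust(pvalues)
    best_n = int((best_fdr[testable] < 0.1).sum())
    pos = mean_expr[testable & (mean_expr > 0)]
    if pos.size == 0:
        return best_fdr
    for q in np.arange(0.05, 0.45, 0.05):
        cut = np.quantile(pos, q)
        p_try = np.where(mean_expr >= cut, pvalues, np.nan)
        fdr_try = bh_adjust(p_try)
        n_try = int((fdr_try[testable] < 0.1).sum())
        if n_try > best_n:
            best_n, best_fdr = n_try, fdr_try
    return best_fdr


def call_degs(table: pd.DataFrame, cfg: DegConfig | None = None) -> pd.DataFrame:
    """BH-adjust within each cell type and set up/down/ns directions."""
    cfg = cfg or DegConfig()
    cfg.validate()
    table = table.copy()
    table["fdr"] = np.nan
    for ct, idx in table.groupby("cell_type").groups.items():
        table.loc[idx, "fdr"] = _filtered_bh(
            table.loc[idx, "pvalue"].to_numpy(float),
            table.loc[idx, "mean_expr"].to_numpy(float),
            cfg.independent_filtering,
        )
    sig = table["fdr"] < cfg.fdr_threshold
    table["direction"] = "ns"
    table.loc[sig & (table["log2fc"] > 0), "direction"] = "up"
    table.loc[sig & (table["log2fc"] < 0), "direction"] = "down"
    return table


def deg_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell-type counts of up/down/total significant genes."""
    return (
        table.groupby("cell_type")["direction"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["up", "down", "ns"], fill_value=0)
        .assign(total_deg=lambda d: d["up"] + d["down"])
    )


def run_deg(
    counts: CountMatrix, meta: pd.DataFrame, cfg: DegConfig | None = None
) -> pd.DataFrame:
    """Aggregate, filter, estimate dispersions, test and call, all cell types."""
    cfg = cfg or DegConfig()
    pbs = exclude_small_clusters(aggregate_pseudobulk(counts, meta), cfg)
    parts = []
    for pb in pbs:
        disp = estimate_dispersions(pb, cfg)
        parts.append(nb_lrt(pb, disp, cfg))
    return call_degs(pd.concat(parts, ignore_index=True), cfg)
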
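"""Synthetic scRNA-seq count generator with planted aging ground truth.

Generates droplet-style count matrices with the statistical structure the
downstream pipeline assumes: multiple donors in two age groups across
batches, several cell types with unequal abundances, negative-binomial
counts with per-gene dispersion, per-cell-type planted age effects with
controlled cross-cell-type sharing, gene-by-batch mean shifts, and an
elevated senescence gene set in aged cells of chosen target cell types.

The generator is the pipeline's test bed: everything planted is recorded in
a :class:`GroundTruth` object so each downstream stage (differential
expression, consensus signatures, module scores, the classifier) can be
scored against known truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

AGE_GROUPS = ("YOUNG", "MIDDLE", "AGED")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG of one global stream.

    Each stage of the generator draws from its own substream so that adding
    draws to one stage does not perturb the others.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=(key,)))


@dataclass
class SynthConfig:
    """Parameters of one synthetic dataset.

    ``cell_types`` maps name -> mean cells per sample (Poisson-distributed
    realized counts). ``samples`` is a list of (sample_id, age_group,
    batch_id) with age_group in {YOUNG, AGED}. ``sharing_profile`` is a
    distribution over the number of cell types a planted gene affects.
    Log-fold-change parameters are in log2 units; ``baseline_logmean_range``
    is on the natural-log scale of per-cell mean counts.
    """

    n_genes: int = 3000
    cell_types: list[tuple[str, float]] = field(
        default_factory=lambda: [
            ("Monocyte", 200.0),
            ("FABP4_Macro", 125.0),
            ("AT2", 75.0),
            ("T_cell", 60.0),
            ("Endothelial", 40.0),
        ]
    )
    samples: list[tuple[str, str, str]] = field(
        default_factory=lambda: [
            (f"{grp[0]}{i + 1}", grp, f"batch{(i % 2) + 1}")
            for grp in ("YOUNG", "AGED")
            for i in range(6)
        ]
    )
    baseline_logmean_range: tuple[float, float] = (np.log(0.1), np.log(3.0))
    dispersion_shape: float = 2.0
    libsize_sigma: float = 0.3
    batch_logfc_sigma: float = 0.15
    n_up_planted: int = 60
    n_down_planted: int = 30
    planted_log2fc: float = 1.0
    sharing_profile: dict[int, float] = field(default_factory=lambda: {1: 0.5, 2: 0.3, 3: 0.2})
    senescence_set_size: int = 15
    senescence_log2fc: float = 1.0
    senescence_target_celltypes: list[str] = field(default_factory=lambda: ["Monocyte", "AT2"])
    mito_fraction_beta: tuple[float, float] = (2.0, 18.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        for name, val in [
            ("n_up_planted", self.n_up_planted),
            ("n_down_planted", self.n_down_planted),
            ("senescence_set_size", self.senescence_set_size),
        ]:
            if val < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_up_planted + self.n_down_planted + self.senescence_set_size > self.n_genes:
            raise ValueError("n_up_planted + n_down_planted + senescence_set_size exceeds n_genes")
        if self.planted_log2fc <= 0:
            raise ValueError("planted_log2fc must be positive")
        if self.senescence_log2fc < 0:
            raise ValueError("senescence_log2fc must be nonnegative")
        if self.dispersion_shape <= 0:
            raise ValueError("dispersion_shape must be positive")
        if self.libsize_sigma < 0:
            raise ValueError("libsize_sigma must be nonnegative")
        if self.batch_logfc_sigma < 0:
            raise ValueError("batch_logfc_sigma must be nonnegative")
        if not self.cell_types:
            raise ValueError("cell_types must be nonempty")
        groups = {g for _, g, _ in self.samples}
        bad = groups - {"YOUNG", "AGED"}
        if bad:
            raise ValueError(f"samples: age group must be YOUNG or AGED, got {sorted(bad)}")
        if "YOUNG" not in groups or "AGED" not in groups:
            raise ValueError("samples: need at least one sample per age group")
        ct_names = {n for n, _ in self.cell_types}
        if len(ct_names) != len(self.cell_types):
            raise ValueError("cell_types: duplicate names")
        missing = set(self.senescence_target_celltypes) - ct_names
        if missing:
            raise ValueError(f"senescence_target_celltypes: unknown cell types {sorted(missing)}")
        if self.sharing_profile:
            ks = sorted(self.sharing_profile)
            if ks[0] < 1 or ks[-1] > len(self.cell_types):
                raise ValueError("sharing_profile: support must lie in 1..n_cell_types")
            total = sum(self.sharing_profile.values())
            if not np.isclose(total, 1.0):
                raise ValueError("sharing_profile: probabilities must sum to 1")
        a, b = self.mito_fraction_beta
        if a <= 0 or b <= 0:
            raise ValueError("mito_fraction_beta parameters must be positive")


@dataclass
class CountMatrix:
    """Sparse genes x cells raw integer counts with identifiers."""

    genes: list[str]
    cells: list[str]
    counts: sp.csr_matrix  # genes x cells

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("duplicate cell identifiers")
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError("counts shape does not match gene/cell identifiers")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def gene_index(self) -> pd.Index:
        return pd.Index(self.genes)


@dataclass
class GroundTruth:
    """Everything planted by the generator, for scoring downstream stages."""

    planted_up: dict[str, set[str]]      # gene -> affected cell types
    planted_down: dict[str, set[str]]
    senescence_genes: list[str]
    basemean: dict[str, float]
    dispersion: dict[str, float]
    batch_shift_sigma: float
    seed: int

    def planted_in_at_least(self, k: int, direction: str) -> set[str]:
        """Genes whose planted effect spans >= k cell types in a direction."""
        table = self.planted_up if direction == "up" else self.planted_down
        return {g for g, cts in table.items() if len(cts) >= k}

    def to_jsonable(self) -> dict:
        return {
            "planted_up": {g: sorted(c) for g, c in self.planted_up.items()},
            "planted_down": {g: sorted(c) for g, c in self.planted_down.items()},
            "senescence_genes": list(self.senescence_genes),
            "basemean": self.basemean,
            "dispersion": self.dispersion,
            "batch_shift_sigma": self.batch_shift_sigma,
            "seed": self.seed,
        }


def generate_dataset(config: SynthConfig) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Simulate a labeled count matrix with planted age effects.

    Gene g in cell c is NB-distributed with mean

        sizefactor(c) * basemean(g) * 2^(batch shift) * 2^(planted effect)

    and per-gene dispersion alpha (Var = mu + alpha * mu^2). Planted effects
    apply only in AGED cells of the cell types a gene was assigned to.
    Deterministic given ``config.seed``.

    Returns (counts, metadata, ground_truth) where metadata is a DataFrame
    indexed by cell barcode with columns sample, cell_type, age_group,
    batch, n_features, mito_fraction.
    """
    config.validate()
    seed = config.seed
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    gene_arr = np.asarray(genes)

    rng_base = substream(seed, "basemean")
    lo, hi = config.baseline_logmean_range
    basemean = np.exp(rng_base.uniform(lo, hi, config.n_genes))

    rng_disp = substream(seed, "dispersion")
    # E[alpha] = 0.5 regardless of shape; shape controls spread
    alpha = rng_disp.gamma(config.dispersion_shape, 0.5 / config.dispersion_shape, config.n_genes)

    batches = sorted({b for _, _, b in config.samples})
    rng_batch = substream(seed, "batch")
    batch_shift = {
        b: rng_batch.normal(0.0, config.batch_logfc_sigma, config.n_genes) for b in batches
    }

    ct_names = [n for n, _ in config.cell_types]
    rng_plant = substream(seed, "planting")
    n_special = config.n_up_planted + config.n_down_planted + config.senescence_set_size
    special = rng_plant.choice(config.n_genes, size=n_special, replace=False)
    up_idx = special[: config.n_up_planted]
    down_idx = special[config.n_up_planted : config.n_up_planted + config.n_down_planted]
    sen_idx = special[config.n_up_planted + config.n_down_planted :]

    def assign_celltypes(idx: np.ndarray) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        ks = sorted(config.sharing_profile)
        probs = [config.sharing_profile[k] for k in ks]
        for gi in idx:
            k = int(rng_plant.choice(ks, p=probs)) if ks else 1
            chosen = rng_plant.choice(len(ct_names), size=k, replace=False)
            out[gene_arr[gi]] = {ct_names[j] for j in chosen}
        return out

    planted_up = assign_celltypes(up_idx)
    planted_down = assign_celltypes(down_idx)
    senescence_genes = [gene_arr[i] for i in sen_idx]

    # per (cell type) signed log2 effect vectors applied in AGED cells
    effect = {ct: np.zeros(config.n_genes) for ct in ct_names}
    for table, sign in ((planted_up, 1.0), (planted_down, -1.0)):
        for g, cts in table.items():
            gi = int(np.flatnonzero(gene_arr == g)[0])
            for ct in cts:
                effect[ct][gi] += sign * config.planted_log2fc
    for ct in config.senescence_target_celltypes:
        effect[ct][sen_idx] += config.senescence_log2fc

    rng_cells = substream(seed, "cells")
    rng_counts = substream(seed, "counts")
    rng_mito = substream(seed, "mito")

    blocks = []
    cell_ids: list[str] = []
    meta_rows = []
    r = 1.0 / alpha  # NB size parameter per gene
    for sample_id, age, batch in config.samples:
        for ct, mean_cells in config.cell_types:
            n_c = int(rng_cells.poisson(mean_cells))
            if n_c == 0:
                continue
            sf = np.exp(rng_cells.normal(0.0, config.libsize_sigma, n_c))
            log2_shift = batch_shift[batch]
            if age == "AGED":
                log2_shift = log2_shift + effect[ct]
            mu = basemean * np.exp2(log2_shift)  # per-gene mean at sf = 1
            mu_block = mu[:, None] * sf[None, :]
            p = r[:, None] / (r[:, None] + mu_block)
            block = rng_counts.negative_binomial(r[:, None], p)
            blocks.append(sp.csc_matrix(block))
            start = len(cell_ids)
            for j in range(n_c):
                cell_ids.append(f"{sample_id}.{ct}.{start + j:05d}")
            mito = rng_mito.beta(*config.mito_fraction_beta, n_c)
            nfeat = (block > 0).sum(axis=0)
            for j in range(n_c):
                meta_rows.append(
                    {
                        "cell": cell_ids[start + j],
                        "sample": sample_id,
                        "cell_type": ct,
                        "age_group": age,
                        "batch": batch,
                        "n_features": int(nfeat[j]),
                        "mito_fraction": float(mito[j]),
                    }
                )

    counts = sp.hstack(blocks, format="csr")
    cm = CountMatrix(genes=genes, cells=cell_ids, counts=counts)
    meta = pd.DataFrame(meta_rows).set_index("cell")

    truth = GroundTruth(
        planted_up=planted_up,
        planted_down=planted_down,
        senescence_genes=senescence_genes,
        basemean={g: float(m) for g, m in zip(genes, basemean)},
        dispersion={g: float(a) for g, a in zip(genes, alpha)},
        batch_shift_sigma=config.batch_logfc_sigma,
        seed=seed,
    )
    return cm, meta, truth


def empirical_summary(counts: CountMatrix, meta: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Sanity panel: per-cell-type cell counts and depth, per-gene moments."""
    if set(meta.index) != set(counts.cells):
        raise ValueError("metadata cell set does not match count matrix cells")
    meta = meta.loc[counts.cells]
    libsize = np.asarray(counts.counts.sum(axis=0)).ravel()
    nfeat = np.asarray((counts.counts > 0).sum(axis=0)).ravel()
    per_ct = (
        pd.DataFrame(
            {"cell_type": meta["cell_type"].to_numpy(), "libsize": libsize, "n_features": nfeat}
        )
        .groupby("cell_type")
        .agg(n_cells=("libsize", "size"), median_features=("n_features", "median"),
             median_libsize=("libsize", "median"))
    )
    x = counts.counts
    mean = np.asarray(x.mean(axis=1)).ravel()
    sq = np.asarray(x.multiply(x).mean(axis=1)).ravel()
    n = x.shape[1]
    var = (sq - mean**2) * (n / max(n - 1, 1))
    per_gene = pd.DataFrame({"mean": mean, "variance": var}, index=counts.genes)
    return {"cell_types": per_ct, "genes": per_gene}


# ---------------------------------------------------------------------------
# Preset study conditions


def default_fixture_config(seed: int = 0) -> SynthConfig:
    """The default planted fixture: 12 donors (6 young / 6 aged, 2 batches),
    5 cell types with 40:25:15:12:8 abundances, 3,000 genes, 60 up / 30 down
    planted at log2FC 1.0 with about half of planted genes shared across
    two or more cell types."""
    return SynthConfig(seed=seed)


def null_fixture_config(seed: int = 0) -> SynthConfig:
    """Null fixture: same cohort structure, 3 cell types, 2,000 genes,
    nothing planted. Used for calibration checks."""
    return SynthConfig(
        n_genes=2000,
        cell_types=[("Monocyte", 250.0), ("AT2", 150.0), ("T_cell", 100.0)],
        n_up_planted=0,
        n_down_planted=0,
        senescence_set_size=0,
        senescence_log2fc=0.0,
        senescence_target_celltypes=[],
        sharing_profile={1: 1.0},
        seed=seed,
    )


def classifier_fixture_config(seed: int = 0) -> SynthConfig:
    """Strong-effect fixture for classifier validation: planted log2FC 2.0
    shared across most cell types, smaller cohort so cross-validation is
    quick. Effects this strong make per-cell age state nearly separable,
    which is what a positive-control classifier check needs."""
    return SynthConfig(
        n_genes=1500,
        cell_types=[("Monocyte", 150.0), ("AT2", 100.0), ("T_cell", 80.0)],
        samples=[
            (f"{grp[0]}{i + 1}", grp, f"batch{(i % 2) + 1}")
            for grp in ("YOUNG", "AGED")
            for i in range(4)
        ],
        n_up_planted=40,
        n_down_planted=20,
        planted_log2fc=2.0,
        sharing_profile={2: 0.3, 3: 0.7},
        senescence_set_size=0,
        senescence_log2fc=0.0,
        senescence_target_celltypes=[],
        seed=seed,
    )
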
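"""Readers and writers for the on-disk formats.

Count matrices travel as a 10x-style MTX triplet (MatrixMarket integer
coordinate with 1-based indices, plus features.tsv and barcodes.tsv,
tab-separated, no header) alongside a metadata TSV. Gene sets travel as
GMT. Gzipped variants of the triplet are accepted on read. Gene identifier
matching is exact and case-sensitive throughout; ``normalize_symbols`` is
an opt-in helper for upper-casing before matching.
"""

from __future__ import annotations

import gzip
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .synthetic import AGE_GROUPS, CountMatrix, GroundTruth


def _find(dirpath: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dirpath / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}[.gz] not found in {dirpath}")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _read_single_column(path: Path) -> list[str]:
    with _open_text(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def _dedup(ids: list[str], what: str) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    dups = 0
    for g in ids:
        if g in seen:
            seen[g] += 1
            out.append(f"{g}.{seen[g]}")
            dups += 1
        else:
            seen[g] = 0
            out.append(g)
    if dups:
        warnings.warn(f"{dups} duplicate {what} identifier(s) disambiguated by suffixing")
    return out


def read_mtx_bundle(
    dirpath, metadata: str = "metadata.tsv"
) -> tuple[CountMatrix, pd.DataFrame, dict]:
    """Read matrix.mtx(+.gz), features.tsv, barcodes.tsv and the metadata TSV.

    Returns (counts, metadata, report); the report lists barcodes present
    in the matrix but missing from the metadata and vice versa. Metadata
    rows are aligned to the matrix cell order.
    """
    dirpath = Path(dirpath)
    mtx_path = _find(dirpath, "matrix.mtx")
    with _open_text(mtx_path) as fh:
        try:
            mat = scipy.io.mmread(fh)
        except Exception as e:  # noqa: BLE001 - rewrap with file context
            raise ValueError(f"malformed MatrixMarket file {mtx_path}: {e}") from e
    mat = sp.csr_matrix(mat)
    if (mat.data < 0).any():
        raise ValueError("negative counts in matrix")
    genes = _dedup(_read_single_column(_find(dirpath, "features.tsv")), "feature")
    cells = _read_single_column(_find(dirpath, "barcodes.tsv"))
    if mat.shape != (len(genes), len(cells)):
        raise ValueError(
            f"dimension mismatch: matrix {mat.shape}, {len(genes)} features, {len(cells)} barcodes"
        )
    counts = CountMatrix(genes=genes, cells=cells, counts=mat)

    meta_path = dirpath / metadata
    if not meta_path.exists():
        raise FileNotFoundError(meta_path)
    meta = pd.read_csv(meta_path, sep="\t", dtype={"cell": str, "sample": str, "batch": str})
    meta = meta.set_index("cell")
    bad = set(meta["age_group"].unique()) - set(AGE_GROUPS)
    if bad:
        raise ValueError(f"unknown age-group token(s): {sorted(bad)}; expected {AGE_GROUPS}")
    unmatched_cells = [c for c in cells if c not in meta.index]
    unmatched_meta = [c for c in meta.index if c not in set(cells)]
    report = {"cells_without_metadata": unmatched_cells, "metadata_without_cells": unmatched_meta}
    matched = [c for c in cells if c in meta.index]
    if unmatched_cells:
        warnings.warn(f"{len(unmatched_cells)} barcode(s) in matrix lack metadata; dropped")
        keep = np.asarray([c in meta.index for c in cells])
        counts = CountMatrix(genes=genes, cells=matched, counts=mat[:, keep].tocsr())
    return counts, meta.loc[counts.cells], report


def write_mtx_bundle(dirpath, counts: CountMatrix, meta: pd.DataFrame) -> None:
    """Write the MTX triplet plus metadata.tsv (uncompressed)."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(dirpath / "matrix.mtx"), sp.coo_matrix(counts.counts), field="integer"
    )
    (dirpath / "features.tsv").write_text("".join(f"{g}\t{g}\n" for g in counts.genes))
    (dirpath / "barcodes.tsv").write_text("".join(f"{c}\n" for c in counts.cells))
    out = meta.loc[counts.cells].reset_index()
    out = out.rename(columns={out.columns[0]: "cell"})
    out.to_csv(dirpath / "metadata.tsv", sep="\t", index=False)


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file into {set name: ordered gene list}.

    Each line: name, description, then genes, tab-separated. Duplicate
    genes within a set are dropped with a warning; lines with fewer than
    three fields are an error.
    """
    sets: dict[str, list[str]] = {}
    with _open_text(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            name = fields[0]
            genes = []
            seen = set()
            dups = 0
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    dups += 1
                    continue
                seen.add(g)
                genes.append(g)
            if dups:
                warnings.warn(f"{path}:{lineno}: {dups} duplicate gene(s) in set {name}, deduplicated")
            sets[name] = genes
    return sets


def write_gmt(path, sets: dict[str, list[str]], descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def write_ground_truth(path, truth: GroundTruth) -> None:
    Path(path).write_text(json.dumps(truth.to_jsonable(), indent=1))


def write_deg_table(path, table: pd.DataFrame) -> None:
    cols = ["cell_type", "gene", "log2fc", "lrt_stat", "pvalue", "fdr", "direction", "mean_expr"]
    table[cols].to_csv(path, sep="\t", index=False)


def read_deg_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def normalize_symbols(genes: list[str]) -> list[str]:
    """Opt-in symbol normalization (upper-casing); matching is otherwise
    exact and case-sensitive because silent coercion corrupts signatures."""
    return [g.upper() for g in genes]
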
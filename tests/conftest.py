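"""Shared fixtures: synthetic datasets at the preset study conditions.

Everything is generated at test time from the package's own simulator;
expensive artifacts (DEG runs) are session-scoped so the acceptance checks
and unit tests share them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import lungage
from lungage import (CountMatrix, classifier_fixture_config, default_fixture_config,
                     filter_cells, generate_dataset, lognormalize, null_fixture_config,
                     run_deg)


@pytest.fixture(scope="session")
def default_run():
    """Default planted fixture (seed 0): QC'd counts, metadata, truth,
    lognorm layer and the full DEG table."""
    counts, meta, truth = generate_dataset(default_fixture_config(0))
    counts, meta, _ = filter_cells(counts, meta)
    lognorm = lognormalize(counts)
    degs = run_deg(counts, meta)
    return {"counts": counts, "meta": meta, "truth": truth, "lognorm": lognorm, "degs": degs}


@pytest.fixture(scope="session")
def null_run():
    """Null fixture (seed 0): nothing planted, DEG table included."""
    counts, meta, truth = generate_dataset(null_fixture_config(0))
    counts, meta, _ = filter_cells(counts, meta)
    lognorm = lognormalize(counts)
    degs = run_deg(counts, meta)
    return {"counts": counts, "meta": meta, "truth": truth, "lognorm": lognorm, "degs": degs}


@pytest.fixture(scope="session")
def strong_run():
    """Strong-effect fixture (seed 0) for classifier positive controls."""
    counts, meta, truth = generate_dataset(classifier_fixture_config(0))
    counts, meta, _ = filter_cells(counts, meta)
    lognorm = lognormalize(counts)
    degs = run_deg(counts, meta)
    sig = lungage.consensus_signature(
        lungage.build_membership(degs, "up"), lungage.build_membership(degs, "down"), 2
    )
    return {"counts": counts, "meta": meta, "truth": truth, "lognorm": lognorm,
            "degs": degs, "sig": sig}


def tiny_counts(n_genes=6, n_cells=4, seed=0) -> tuple[CountMatrix, pd.DataFrame]:
    """Small deterministic matrix for format/edge-case tests."""
    rng = np.random.default_rng(seed)
    dense = rng.integers(0, 9, size=(n_genes, n_cells))
    dense[0, :] = 1  # keep every cell nonzero
    genes = [f"G{i}" for i in range(n_genes)]
    cells = [f"C{j}" for j in range(n_cells)]
    counts = CountMatrix(genes=genes, cells=cells, counts=sp.csr_matrix(dense))
    meta = pd.DataFrame(
        {
            "sample": ["S1", "S1", "S2", "S2"][:n_cells],
            "cell_type": ["A", "A", "A", "B"][:n_cells],
            "age_group": ["YOUNG", "YOUNG", "AGED", "AGED"][:n_cells],
            "batch": ["b1"] * n_cells,
            "n_features": (dense > 0).sum(axis=0),
            "mito_fraction": [0.05] * n_cells,
        },
        index=cells,
    )
    return counts, meta
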
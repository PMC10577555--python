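"""Pseudobulk aggregation, dispersion, the NB likelihood-ratio test and BH."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, special

from lungage import CountMatrix
from lungage.deg import (DegConfig, PseudobulkMatrix, aggregate_pseudobulk, bh_adjust,
                         call_degs, estimate_dispersions, exclude_small_clusters, nb_lrt,
                         size_factors)


def _random_cells(n_cells=200, n_genes=30, seed=0):
    rng = np.random.default_rng(seed)
    counts = sp.csr_matrix(rng.poisson(2.0, size=(n_genes, n_cells)))
    genes = [f"G{i}" for i in range(n_genes)]
    cells = [f"C{j}" for j in range(n_cells)]
    meta = pd.DataFrame(
        {
            "sample": rng.choice(["Y1", "Y2", "A1", "A2"], n_cells),
            "cell_type": rng.choice(["A", "B"], n_cells),
            "batch": "b1",
            "n_features": 10,
            "mito_fraction": 0.05,
        },
        index=cells,
    )
    meta["age_group"] = np.where(meta["sample"].str.startswith("Y"), "YOUNG", "AGED")
    meta.loc[meta.index[:10], "age_group"] = "MIDDLE"  # some excluded cells
    return CountMatrix(genes=genes, cells=cells, counts=counts), meta


def test_aggregation_matches_bruteforce_groupby():
    counts, meta = _random_cells()
    pbs = {pb.cell_type: pb for pb in aggregate_pseudobulk(counts, meta)}
    dense = pd.DataFrame(counts.counts.toarray(), index=counts.genes, columns=counts.cells)
    kept = meta[meta["age_group"].isin(["YOUNG", "AGED"])]
    for ct, sub in kept.groupby("cell_type"):
        expected = dense[sub.index].T.groupby(sub["sample"]).sum().T
        pb = pbs[ct]
        got = pd.DataFrame(pb.counts, index=pb.genes, columns=pb.sample_ids)
        pd.testing.assert_frame_equal(got, expected[got.columns], check_dtype=False,
                                      check_names=False)


def test_middle_aged_cells_never_aggregated():
    counts, meta = _random_cells()
    pbs = aggregate_pseudobulk(counts, meta)
    middle_samples = set(meta.loc[meta["age_group"] == "MIDDLE", "sample"])
    total = sum(pb.n_cells for pb in pbs)
    assert total == (meta["age_group"].isin(["YOUNG", "AGED"])).sum()
    assert middle_samples  # the fixture really contains MIDDLE cells


def test_aggregation_order_invariance():
    counts, meta = _random_cells()
    rng = np.random.default_rng(1)
    perm = rng.permutation(len(counts.cells))
    shuffled = CountMatrix(
        genes=counts.genes,
        cells=[counts.cells[i] for i in perm],
        counts=counts.counts[:, perm],
    )
    a = aggregate_pseudobulk(counts, meta)
    b = aggregate_pseudobulk(shuffled, meta.iloc[perm])
    for pa, pb in zip(a, b):
        assert pa.cell_type == pb.cell_type
        np.testing.assert_array_equal(pa.counts, pb.counts)


def _make_pb(counts, ages=None, batches=None, n_cells=None, cell_disp=None):
    counts = np.atleast_2d(np.asarray(counts))
    n = counts.shape[1]
    return PseudobulkMatrix(
        cell_type="A",
        genes=[f"G{i}" for i in range(counts.shape[0])],
        sample_ids=[f"S{j}" for j in range(n)],
        age_groups=ages or ["YOUNG"] * (n // 2) + ["AGED"] * (n - n // 2),
        batches=batches or ["b1"] * n,
        counts=counts,
        n_cells_per_sample=n_cells or [100] * n,
        cell_dispersion=cell_disp,
    )


def test_cluster_exclusion_thresholds():
    small = _make_pb(np.ones((2, 4)), n_cells=[125, 125, 125, 124])  # 499 cells
    big = _make_pb(np.ones((2, 4)), n_cells=[125, 125, 125, 125])    # 500 cells
    kept = exclude_small_clusters([small, big])
    assert len(kept) == 1 and kept[0].n_cells == 500

    one_sided = _make_pb(np.ones((2, 4)), ages=["AGED"] * 4, n_cells=[200] * 4)
    with pytest.raises(ValueError):
        exclude_small_clusters([one_sided])

    permissive = DegConfig(min_cells_per_cluster=0)
    assert len(exclude_small_clusters([small, big], permissive)) == 2


def test_dispersion_poisson_and_nb_recovery():
    rng = np.random.default_rng(0)
    # Poisson genes: dispersion collapses to near zero
    pb = _make_pb(rng.poisson(100, size=(200, 20)))
    disp = estimate_dispersions(pb)
    assert disp["alpha"].median() <= 0.05

    # NB genes at alpha=0.5: MoM recovers the truth across genes
    mu, alpha = 50.0, 0.5
    r = 1 / alpha
    pb2 = _make_pb(rng.negative_binomial(r, r / (r + mu), size=(200, 50)))
    disp2 = estimate_dispersions(pb2)
    assert 0.3 <= disp2["alpha"].median() <= 0.7


def test_dispersion_constant_gene_hits_floor():
    pb = _make_pb(np.full((1, 6), 42))
    disp = estimate_dispersions(pb)
    assert disp["alpha"].iloc[0] == pytest.approx(DegConfig().dispersion_floor, rel=0.5)


def _oracle_lrt(y, X_full, X_red, offset, alpha):
    """Independent numeric maximization of the NB log-likelihood."""
    r = 1.0 / alpha

    def nll(beta, X):
        mu = np.exp(X @ beta + offset)
        return -np.sum(
            special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1)
            + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))
        )

    def best(X):
        out = np.inf
        for start in ([0.0] * X.shape[1], [np.log(y.mean() + 0.5)] + [0.0] * (X.shape[1] - 1)):
            res = optimize.minimize(nll, start, args=(X,), method="Nelder-Mead",
                                    options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
            out = min(out, res.fun)
        return out

    return 2.0 * (best(X_red) - best(X_full))


def test_lrt_statistic_matches_bruteforce_on_small_instances():
    rng = np.random.default_rng(2024)
    ages = ["YOUNG", "YOUNG", "AGED", "AGED"]
    batches = ["b1", "b2", "b1", "b2"]
    X_red = np.column_stack([np.ones(4), [0, 1, 0, 1]])
    X_full = np.column_stack([X_red, [0, 0, 1, 1]])
    for i in range(20):
        y = rng.poisson(rng.uniform(20, 200), 4).astype(float) + 1
        alpha = rng.uniform(0.02, 0.3)
        # anchor genes pin the size factors so the tested gene's fit is not
        # absorbed into the offset
        anchors = rng.poisson(100, size=(3, 4)).astype(float) + 1
        counts = np.vstack([y[None, :], anchors])
        pb = _make_pb(counts, ages=ages, batches=batches)
        disp = pd.DataFrame({"alpha": [alpha] * 4}, index=pb.genes)
        table = nb_lrt(pb, disp, DegConfig(min_total_count=0))
        sf = size_factors(pb.counts)
        expected = _oracle_lrt(y, X_full, X_red, np.log(sf), alpha)
        assert table["lrt_stat"].iloc[0] == pytest.approx(expected, abs=1e-4), f"instance {i}"
        assert table["lrt_stat"].iloc[0] >= 0


def test_degenerate_contrast_is_an_error():
    pb = _make_pb(np.ones((1, 4)), ages=["AGED"] * 4)
    disp = pd.DataFrame({"alpha": [0.1]}, index=pb.genes)
    with pytest.raises(ValueError, match="contrast not estimable"):
        nb_lrt(pb, disp)


def test_lrt_null_calibration_small():
    """beta_age = 0 data: empirical P(p<0.05) in the calibration band."""
    rng = np.random.default_rng(5)
    n_genes = 400
    mu = 100.0
    alpha = 0.05
    r = 1 / alpha
    counts = rng.negative_binomial(r, r / (r + mu), size=(n_genes, 12))
    pb = _make_pb(counts, ages=["YOUNG"] * 6 + ["AGED"] * 6,
                  batches=(["b1", "b2"] * 6))
    disp = estimate_dispersions(pb)
    table = nb_lrt(pb, disp, DegConfig())
    p = table["pvalue"].dropna()
    assert 0.02 <= (p < 0.05).mean() <= 0.09


def test_bh_step_up_example_and_na_passthrough():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])
    np.testing.assert_allclose(bh_adjust([0.7]), [0.7])
    out = bh_adjust([0.01, np.nan, 0.04])
    assert np.isnan(out[1]) and not np.isnan(out[0])
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
def test_bh_matches_direct_step_up_formula(pvals):
    """The implementation agrees with q_i = min over j with p_(j) >= p_(i) of
    min(1, m p_(j) / j), computed from scratch."""
    got = bh_adjust(pvals)
    p = np.asarray(pvals)
    m = len(p)
    order = np.argsort(p, kind="stable")
    expected = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        expected[i] = running
    np.testing.assert_allclose(got, expected, atol=1e-12)
    assert (got >= p - 1e-12).all() and (got <= 1 + 1e-12).all()


def test_direction_calls_respect_threshold():
    table = pd.DataFrame(
        {
            "cell_type": ["A"] * 4,
            "gene": ["G0", "G1", "G2", "G3"],
            "log2fc": [0.5, -0.5, 2.0, 0.9],
            "lrt_stat": [9.0, 9.0, 0.1, 2.0],
            "pvalue": [0.001, 0.002, 0.9, 0.2],
            "mean_expr": [10.0] * 4,
            "flag": [""] * 4,
        }
    )
    out = call_degs(table, DegConfig(independent_filtering=False))
    byg = out.set_index("gene")
    assert byg.loc["G0", "direction"] == "up"
    assert byg.loc["G1", "direction"] == "down"
    assert byg.loc["G2", "direction"] == "ns"
    # fdr exactly at the threshold is not significant (strict <)
    table2 = table.assign(pvalue=[0.1, 0.1, 0.1, 0.1])
    out2 = call_degs(table2, DegConfig(independent_filtering=False))
    assert (out2["direction"] == "ns").all()


def test_size_factors_median_of_ratios_and_fallback():
    counts = np.array([[10, 20], [100, 200], [5, 10]])
    sf = size_factors(counts)
    np.testing.assert_allclose(sf, [np.sqrt(0.5), np.sqrt(2.0)], rtol=1e-9)
    # no all-positive gene: falls back to totals
    counts2 = np.array([[0, 4], [6, 0]])
    sf2 = size_factors(counts2)
    np.testing.assert_allclose(np.exp(np.mean(np.log(sf2))), 1.0)
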
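"""Module-score algebra, control matching, and the rank-sum comparisons."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from lungage import ScoreConfig, compare_groups, module_score, set_overlap
from lungage.qc import LogNormMatrix
from lungage.scoring import _wilcoxon, senescence_scores


def _lognorm_from_dense(values, genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    cells = cells or [f"C{j}" for j in range(values.shape[1])]
    return LogNormMatrix(genes=genes, cells=cells, values=sp.csr_matrix(values))


def _bruteforce_score(values, genes, gene_set, cfg):
    """Straight-line reimplementation: rank genes by mean, equal-frequency
    bins, per-set-gene control draws, subtract pooled control mean."""
    values = np.asarray(values, dtype=float)
    mean = values.mean(axis=1)
    order = np.argsort(mean, kind="stable")
    rank = np.empty(len(genes), dtype=int)
    rank[order] = np.arange(len(genes))
    bins = rank * cfg.n_bins // len(genes)
    set_idx = [genes.index(g) for g in gene_set if g in genes]
    in_set = set(set_idx)
    rng = np.random.default_rng(cfg.seed)
    ctrl = []
    for gi in set_idx:
        pool = [j for j in range(len(genes)) if bins[j] == bins[gi] and j not in in_set]
        ctrl.extend(rng.choice(pool, size=cfg.n_ctrl_per_gene, replace=True))
    scores = []
    for c in range(values.shape[1]):
        s = np.mean([values[g, c] for g in set_idx])
        k = np.mean([values[g, c] for g in ctrl])
        scores.append(s - k)
    return np.asarray(scores)


def test_identical_genes_cancel_exactly():
    # every gene has the same per-cell profile, so any control panel matches
    # the set exactly and all scores are 0 to machine precision
    profile = np.linspace(0.5, 2.0, 30)
    values = np.tile(profile, (40, 1))
    ln = _lognorm_from_dense(values)
    out = module_score(ln, ln.genes[:8], ScoreConfig(n_bins=4, seed=1))
    assert np.abs(out["score"].to_numpy()).max() < 1e-12


def test_score_is_linear_in_set_expression():
    rng = np.random.default_rng(0)
    # well-separated gene means so a one-cell bump cannot re-rank genes and
    # change the expression bins (the binning is a function of the data)
    base_levels = np.arange(50) * 0.5
    values = base_levels[:, None] + rng.random((50, 200)) * 0.05
    ln = _lognorm_from_dense(values)
    gene_set = ln.genes[5:15]
    cfg = ScoreConfig(n_bins=5, n_ctrl_per_gene=30, seed=7)
    base = module_score(ln, gene_set, cfg)["score"].to_numpy()
    delta = 0.37
    bumped = values.copy()
    bumped[5:15, 3] += delta
    out = module_score(_lognorm_from_dense(bumped), gene_set, cfg)["score"].to_numpy()
    assert out[3] - base[3] == pytest.approx(delta, abs=1e-10)
    np.testing.assert_allclose(np.delete(out, 3), np.delete(base, 3), atol=1e-10)


def test_matches_bruteforce_reimplementation():
    rng = np.random.default_rng(42)
    values = rng.gamma(2.0, 1.0, size=(120, 50))
    ln = _lognorm_from_dense(values)
    gene_set = [ln.genes[i] for i in rng.choice(120, 15, replace=False)]
    cfg = ScoreConfig(n_bins=8, n_ctrl_per_gene=25, seed=99)
    got = module_score(ln, gene_set, cfg)["score"].to_numpy()
    expected = _bruteforce_score(values, ln.genes, gene_set, cfg)
    np.testing.assert_allclose(got, expected, atol=1e-12)


def test_score_invariant_to_cell_and_gene_order():
    rng = np.random.default_rng(1)
    values = rng.random((60, 30))
    ln = _lognorm_from_dense(values)
    gene_set = ln.genes[10:20]
    cfg = ScoreConfig(n_bins=6, n_ctrl_per_gene=40, seed=3)
    base = module_score(ln, gene_set, cfg).set_index("cell")["score"]
    perm = rng.permutation(30)
    ln2 = _lognorm_from_dense(values[:, perm], genes=ln.genes,
                              cells=[ln.cells[j] for j in perm])
    out = module_score(ln2, gene_set, cfg).set_index("cell")["score"]
    pd.testing.assert_series_equal(base.sort_index(), out.sort_index())


def test_same_seed_same_scores():
    rng = np.random.default_rng(2)
    ln = _lognorm_from_dense(rng.random((80, 10)))
    cfg = ScoreConfig(seed=11, n_bins=8)
    a = module_score(ln, ln.genes[:5], cfg)["score"]
    b = module_score(ln, ln.genes[:5], cfg)["score"]
    assert (a == b).all()


def test_too_few_present_genes_and_bad_bins_error():
    ln = _lognorm_from_dense(np.ones((10, 4)))
    with pytest.raises(ValueError, match="set gene"):
        module_score(ln, ["absent1", "absent2"], ScoreConfig(n_bins=2))
    with pytest.raises(ValueError, match="n_bins"):
        module_score(ln, ln.genes[:3], ScoreConfig(n_bins=99))


def test_wilcoxon_exact_small_groups():
    # {4,5,6} vs {1,2,3}: most extreme of C(6,3)=20 arrangements, two-sided
    stat, p = _wilcoxon(np.array([4.0, 5, 6]), np.array([1.0, 2, 3]))
    assert p == pytest.approx(0.1, abs=1e-12)


def test_wilcoxon_identical_groups_p_near_one():
    rng = np.random.default_rng(0)
    x = rng.random(50)
    _, p = _wilcoxon(x, x.copy())
    assert p > 0.9


def test_wilcoxon_normal_approx_close_to_exact_enumeration():
    """Independent oracle: enumerate all label assignments for small
    tie-free samples and compare the asymptotic p-value."""
    from scipy import stats

    rng = np.random.default_rng(8)
    for _ in range(6):
        # sizes where the implementation actually takes the asymptotic branch
        n1, n2 = rng.integers(8, 10, 2)
        N = int(n1 + n2)
        pooled = rng.permutation(np.arange(1.0, N + 1))  # distinct ranks
        a, b = pooled[:n1], pooled[n1:]
        u_obs = float(sum((x > y) for x in a for y in b))
        mu = n1 * n2 / 2
        # enumeration via rank sums: values are exactly the ranks 1..N
        us = np.asarray([
            sum(vals) - n1 * (n1 + 1) / 2 for vals in combinations(range(1, N + 1), int(n1))
        ])
        p_exact = np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-9)
        p_approx = stats.mannwhitneyu(a, b, alternative="two-sided",
                                      method="asymptotic", use_continuity=True).pvalue
        assert abs(p_approx - p_exact) < 0.02


def test_compare_groups_skips_one_sided_celltypes():
    scores = pd.DataFrame({"cell": ["c1", "c2", "c3"], "set": "s",
                           "score": [0.1, 0.4, 0.2]})
    meta = pd.DataFrame(
        {
            "sample": ["S1", "S2", "S3"],
            "cell_type": ["A", "A", "B"],
            "age_group": ["YOUNG", "AGED", "AGED"],
        },
        index=["c1", "c2", "c3"],
    )
    with pytest.warns(UserWarning, match="absent"):
        out = compare_groups(scores, meta)
    assert list(out["cell_type"]) == ["A"]


def test_compare_groups_per_sample_units():
    rng = np.random.default_rng(4)
    cells = [f"c{i}" for i in range(40)]
    meta = pd.DataFrame(
        {
            "sample": [f"S{i % 8}" for i in range(40)],
            "cell_type": "A",
            "age_group": ["YOUNG" if i % 8 < 4 else "AGED" for i in range(40)],
        },
        index=cells,
    )
    scores = pd.DataFrame({"cell": cells, "set": "s", "score": rng.random(40)})
    out = compare_groups(scores, meta, per_sample=True)
    assert out.loc[0, "n_young"] == 4 and out.loc[0, "n_aged"] == 4


def test_senescence_union_and_missing_set():
    rng = np.random.default_rng(5)
    ln = _lognorm_from_dense(rng.random((100, 30)))
    sets = {"consensus": ln.genes[:11], "csgene": ln.genes[11:31]}
    out = senescence_scores(ln, sets, ScoreConfig(n_bins=5, seed=2))
    assert set(out["set"]) == {"consensus", "csgene", "union"}
    # disjoint 11 + 20 genes: union of 31
    assert set_overlap(sets["consensus"], sets["csgene"])[0] == 0
    with pytest.raises(ValueError):
        senescence_scores(ln, {"absent": ["x1", "x2", "x3"]}, ScoreConfig(n_bins=5))


def test_set_overlap_bruteforce():
    a = ["g1", "g2", "g3", "g5"]
    b = ["g3", "g5", "g9"]
    n, members = set_overlap(a, b)
    assert n == 2 and members == ["g3", "g5"]
    assert set_overlap(a, a)[0] == len(set(a))
    assert set_overlap([], b) == (0, [])
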
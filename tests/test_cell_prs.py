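"""LD estimation, clumping and conditioned PRS features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scprs.cell_prs import (CTGrid, CTParams, cell_prs_tensor, celltype_prs,
                            clump, combine_multi_celltype, ct_prs, ld_r2,
                            nonpeak_prs, normalize_prs)
from scprs.io_harmonize import assign_variants_to_peaks

from conftest import make_cpm, make_genotypes, make_sumstats


def brute_force_clump(s, ld_dense, candidates, params):
    """Independent greedy re-implementation used as the clumping oracle."""
    df = s.df
    order = sorted(candidates,
                   key=lambda i: (df.at[i, "pval"], df.at[i, "chrom"],
                                  df.at[i, "pos"]))
    removed = set()
    selected = []
    for i in order:
        if df.at[i, "pval"] > params.p_thresh:
            continue
        if i in removed:
            continue
        selected.append(i)
        removed.add(i)
        for j in range(len(df)):
            if (df.at[j, "chrom"] == df.at[i, "chrom"]
                    and abs(df.at[j, "pos"] - df.at[i, "pos"])
                    <= params.window_kb * 1000
                    and ld_dense[i, j] >= params.r2_thresh):
                removed.add(j)
    return selected


def test_grid_defaults():
    grid = CTGrid.default()
    assert len(grid) == 21
    with pytest.raises(ValueError):
        CTGrid((CTParams(0.5, 0.1), CTParams(0.5, 0.1)))
    with pytest.raises(ValueError):
        CTParams(p_thresh=0.0, r2_thresh=0.1)


def test_ld_duplicated_variant_is_one():
    col = np.array([0, 1, 2, 1, 0, 2, 1, 0], dtype=float)
    g = make_genotypes(np.column_stack([col, col]), pos=[100, 200])
    ld = ld_r2(g)
    assert ld.r2[0, 1] == pytest.approx(1.0, abs=1e-12)


def test_ld_matches_hand_computation(rng):
    d = rng.binomial(2, 0.4, size=(30, 5)).astype(float)
    d[3, 1] = np.nan  # exercise pairwise-complete handling
    g = make_genotypes(d, pos=[100, 200, 300, 400, 500])
    ld = ld_r2(g)
    for i in range(5):
        for j in range(i + 1, 5):
            both = ~np.isnan(d[:, i]) & ~np.isnan(d[:, j])
            r = np.corrcoef(d[both, i], d[both, j])[0, 1]
            assert ld.r2[i, j] == pytest.approx(r * r, abs=1e-10)
            assert ld.r2[j, i] == pytest.approx(r * r, abs=1e-10)


def test_ld_independent_variants_mean_r2_near_1_over_n(rng):
    n = 2000
    d = rng.binomial(2, 0.3, size=(n, 20)).astype(float)
    g = make_genotypes(d, pos=list(range(100, 2100, 100)))
    ld = ld_r2(g)
    dense = ld.r2.toarray()
    off = dense[~np.eye(20, dtype=bool)]
    assert np.mean(off) == pytest.approx(1.0 / n, rel=0.5)


def test_ld_window_limits_pairs():
    g = make_genotypes(np.tile([[0.0], [1.0], [2.0]], (1, 2)),
                       pos=[100, 400_000])
    ld = ld_r2(g, window_kb=250)
    assert ld.r2[0, 1] == 0.0  # beyond the window, not stored


def test_clump_trivial_cases(rng):
    s = make_sumstats("1", [100, 200], pval=[1e-6, 1e-4])
    col = rng.binomial(2, 0.5, size=50).astype(float)
    g = make_genotypes(np.column_stack([col, col]), pos=[100, 200])
    ld = ld_r2(g)
    prm = CTParams(p_thresh=0.01, r2_thresh=0.5)
    # two candidates in perfect LD: only the smaller p survives
    assert clump(s, ld, [0, 1], prm) == [0]
    assert clump(s, ld, [1], prm) == [1]
    assert clump(s, ld, [], prm) == []


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_clump_matches_bruteforce(seed, tiny_bundle):
    rng = np.random.default_rng(seed)
    g = tiny_bundle["target"]
    s = tiny_bundle["sumstats"]
    sub = rng.choice(len(s.df), size=20, replace=False)
    ld = tiny_bundle["ld"]
    dense = ld.r2.toarray()
    for r2_t, p_t in [(0.1, 0.5), (0.5, 0.05)]:
        prm = CTParams(p_thresh=p_t, r2_thresh=r2_t)
        assert clump(s, ld, sub, prm) == brute_force_clump(s, dense, sub, prm)


def test_ct_prs_arithmetic():
    s = make_sumstats("1", [100, 200], beta=[0.1, -0.2])
    g = make_genotypes([[1.0, 2.0], [0.0, 0.0], [2.0, np.nan]],
                       pos=[100, 200])
    out = ct_prs(g, s, [0, 1])
    # (0.1*1 - 0.2*2)/(2*2), all-zero -> 0, missing shrinks M to 1
    np.testing.assert_allclose(out, [-0.075, 0.0, 0.1 * 2 / 2])
    s1 = make_sumstats("1", [100], beta=[0.5])
    g1 = make_genotypes([[2.0]], pos=[100])
    assert ct_prs(g1, s1, [0])[0] == pytest.approx(0.5)


@given(scale=st.floats(0.5, 4.0), perm_seed=st.integers(0, 10))
@settings(max_examples=10, deadline=None)
def test_prs_linearity_and_permutation(scale, perm_seed):
    rng = np.random.default_rng(42)
    d = rng.binomial(2, 0.4, size=(12, 6)).astype(float)
    g = make_genotypes(d, pos=list(range(100, 700, 100)))
    s = make_sumstats("1", list(range(100, 700, 100)),
                      beta=list(rng.normal(size=6)))
    base = ct_prs(g, s, range(6))
    s2 = make_sumstats("1", list(range(100, 700, 100)),
                       beta=list(np.asarray(s.df["beta"]) * scale))
    np.testing.assert_allclose(ct_prs(g, s2, range(6)), base * scale,
                               atol=1e-12)
    perm = np.random.default_rng(perm_seed).permutation(12)
    gp = make_genotypes(d[perm], pos=list(range(100, 700, 100)))
    np.testing.assert_allclose(ct_prs(gp, s, range(6)), base[perm],
                               atol=1e-12)


def test_cell_prs_tensor_degenerate_and_duplicate_cells(tiny_bundle):
    g, s = tiny_bundle["target"], tiny_bundle["sumstats"]
    atlas = tiny_bundle["atlas"]
    counts = atlas.matrix.toarray()[:4].copy()
    counts[0] = 0                     # cell with no accessible peaks
    counts[2] = counts[1]             # duplicated cell
    cpm = make_cpm(counts)
    cpm.peaks.df = atlas.peaks.df     # reuse real intervals
    cpm = type(cpm)(barcodes=cpm.barcodes, peaks=atlas.peaks,
                    matrix=cpm.matrix, cell_types=None)
    membership = assign_variants_to_peaks(s, atlas.peaks)
    t = cell_prs_tensor(g, s, cpm, CTGrid.default(), membership,
                        ld=tiny_bundle["ld"])
    assert t.values.shape == (g.n_samples, 4, 21)
    np.testing.assert_array_equal(t.values[:, 0, :], 0.0)
    assert t.counts[0].sum() == 0
    np.testing.assert_array_equal(t.values[:, 1, :], t.values[:, 2, :])


def test_cell_prs_tensor_cache_equals_bruteforce(tiny_bundle):
    g, s, cpm = (tiny_bundle["target"], tiny_bundle["sumstats"],
                 tiny_bundle["atlas"])
    sub_rows = np.arange(5)
    small = type(cpm)(barcodes=cpm.barcodes[sub_rows], peaks=cpm.peaks,
                      matrix=cpm.matrix[sub_rows],
                      cell_types=None)
    membership = assign_variants_to_peaks(s, cpm.peaks)
    a = cell_prs_tensor(g, s, small, membership=membership,
                        ld=tiny_bundle["ld"], cache=True)
    b = cell_prs_tensor(g, s, small, membership=membership,
                        ld=tiny_bundle["ld"], cache=False)
    np.testing.assert_array_equal(a.values, b.values)
    np.testing.assert_array_equal(a.counts, b.counts)


def test_index_counts_bounded_by_candidates(tiny_pipe, tiny_bundle):
    s = tiny_bundle["sumstats"]
    cpm = tiny_bundle["atlas"]
    membership = assign_variants_to_peaks(s, cpm.peaks)
    from scprs.io_harmonize import membership_matrix

    vp = membership_matrix(membership, len(s.df), cpm.n_peaks).tocsc()
    acc = cpm.matrix.tocsr()
    t = tiny_pipe.tensor
    for j in range(cpm.n_cells):
        peaks_j = acc.indices[acc.indptr[j]:acc.indptr[j + 1]]
        n_cand = len(np.unique(vp[:, peaks_j].tocoo().row))
        assert t.counts[j].max() <= n_cand


def test_nonpeak_prs_disjoint_and_compositional(tiny_bundle):
    g, s, cpm = (tiny_bundle["target"], tiny_bundle["sumstats"],
                 tiny_bundle["atlas"])
    membership = assign_variants_to_peaks(s, cpm.peaks)
    ld = tiny_bundle["ld"]
    grid = CTGrid(tuple(CTParams(p, 0.1) for p in (0.01, 0.5)))
    got = nonpeak_prs(g, s, cpm, grid, membership, ld=ld)
    outside = [i for i in range(len(s.df)) if i not in membership]
    assert set(outside).isdisjoint(membership.keys())
    for f, prm in enumerate(grid):
        sel = clump(s, ld, outside, prm)
        np.testing.assert_allclose(got[:, f], ct_prs(g, s, sel), atol=1e-12)


def test_nonpeak_all_variants_in_peaks_gives_zero():
    g = make_genotypes([[0.0, 1.0], [1.0, 2.0], [2.0, 1.0]],
                       pos=[150, 160])
    s = make_sumstats("1", [150, 160])
    cpm = make_cpm([[1]], starts=[100], width=100)  # one peak covers both
    out = nonpeak_prs(g, s, cpm)
    np.testing.assert_array_equal(out, 0.0)


def test_celltype_prs_reductions(tiny_bundle):
    g, s, cpm = (tiny_bundle["target"], tiny_bundle["sumstats"],
                 tiny_bundle["atlas"])
    membership = assign_variants_to_peaks(s, cpm.peaks)
    ld = tiny_bundle["ld"]
    grid = CTGrid(tuple(CTParams(p, 0.3) for p in (0.01, 0.5)))
    one_type = np.asarray(["all"] * cpm.n_cells, dtype=object)
    blocks = celltype_prs(g, s, cpm, one_type, grid, membership, ld=ld)
    # single type covering all cells reduces to the union-peak PRS
    union_peaks = np.flatnonzero(np.asarray(
        cpm.matrix.sum(axis=0)).ravel() > 0)
    from scprs.io_harmonize import membership_matrix

    vp = membership_matrix(membership, len(s.df), cpm.n_peaks).tocsc()
    cand = np.unique(vp[:, union_peaks].tocoo().row)
    for f, prm in enumerate(grid):
        sel = clump(s, ld, cand, prm)
        np.testing.assert_allclose(blocks["all"][:, f], ct_prs(g, s, sel),
                                   atol=1e-12)
    # two identical cell types give identical blocks
    half = cpm.n_cells // 2
    labels = np.asarray(["a"] * half + ["b"] * (cpm.n_cells - half),
                        dtype=object)
    dup = type(cpm)(barcodes=cpm.barcodes, peaks=cpm.peaks,
                    matrix=type(cpm.matrix)(np.vstack(
                        [cpm.matrix[:half].toarray()] * 2)),
                    cell_types=labels)
    blocks2 = celltype_prs(g, s, dup, labels, grid, membership, ld=ld)
    np.testing.assert_array_equal(blocks2["a"], blocks2["b"])


def test_combine_multi_celltype_probabilities(tiny_bundle):
    rng = np.random.default_rng(0)
    n = tiny_bundle["target"].n_samples
    blocks = {"a": rng.normal(size=(n, 4)), "b": rng.normal(size=(n, 4))}
    y = tiny_bundle["labels"]
    tr = np.arange(0, n, 2)
    te = np.arange(1, n, 2)
    p = combine_multi_celltype(blocks, y, tr, te)
    assert p.shape == (len(te),)
    assert np.all((p >= 0) & (p <= 1))


def test_normalize_prs_contract(tiny_pipe):
    t = tiny_pipe.tensor
    fit = np.arange(0, t.n_individuals, 2)
    tn = normalize_prs(t, fit)
    sub = tn.values[fit]
    sd0 = t.values[fit].std(axis=0) == 0
    np.testing.assert_allclose(sub.mean(axis=0)[~sd0], 0.0, atol=1e-10)
    np.testing.assert_allclose(sub.std(axis=0)[~sd0], 1.0, atol=1e-10)
    if sd0.any():
        assert np.all(tn.values[:, sd0] == 0)
    held = np.setdiff1d(np.arange(t.n_individuals), fit)
    expect = (t.values[held] - t.values[fit].mean(axis=0)) / \
        np.where(t.values[fit].std(axis=0) > 0,
                 t.values[fit].std(axis=0), 1.0)
    expect = np.where(sd0, 0.0, expect)
    np.testing.assert_allclose(tn.values[held], expect, atol=1e-12)
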
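"""Meta-cell smoothing, per-cell correction, high-variance selection, ARI."""

import numpy as np
import pytest
from scipy import sparse
from scipy.spatial.distance import cdist

from tn5shadow import singlecell as sc
from tn5shadow import synthetic as syn
from tn5shadow import tracks as tr


def _matrix(counts, labels=None, layout_len=None):
    counts = np.asarray(counts)
    n_bins = counts.shape[1]
    bins = [tr.GenomicBin("chrA", i * 200, 200) for i in range(n_bins)]
    return sc.CellBinMatrix(
        matrix=sparse.csr_matrix(counts),
        barcodes=[f"c{i}" for i in range(counts.shape[0])],
        bins=bins,
        labels=None if labels is None else np.asarray(labels),
    )


def _embedding(coords):
    return sc.CellEmbedding(coords=np.asarray(coords, dtype=float))


# ---------------------------------------------------------------------------
# meta-cell smoothing


def test_smooth_with_k0_is_identity():
    rng = np.random.default_rng(0)
    mat = _matrix(rng.integers(0, 5, (6, 10)))
    emb = _embedding(rng.normal(size=(6, 3)))
    out = sc.metacell_smooth(mat, emb, k=0)
    assert np.array_equal(out.dense(), mat.dense())


def test_smooth_eleven_identical_cells_multiplies_by_eleven():
    row = np.arange(10)
    mat = _matrix(np.tile(row, (11, 1)))
    emb = _embedding(np.zeros((11, 2)))
    out = sc.metacell_smooth(mat, emb, k=10)
    assert np.array_equal(out.dense(), np.tile(11 * row, (11, 1)))


def test_neighbor_sets_match_bruteforce_all_pairs():
    rng = np.random.default_rng(4)
    coords = rng.normal(size=(50, 5))
    nbrs = sc.neighbor_indices(_embedding(coords), k=10)
    d = cdist(coords, coords)
    for i in range(50):
        assert nbrs[i, 0] == i
        others = np.delete(np.arange(50), i)
        # stable tie-break by index matches lexicographic (distance, index)
        brute = others[np.lexsort((others, d[i, others]))][:10]
        assert set(nbrs[i, 1:]) == set(brute)


def test_smooth_mass_bookkeeping_identity():
    rng = np.random.default_rng(5)
    counts = rng.integers(0, 4, (30, 20))
    mat = _matrix(counts)
    emb = _embedding(rng.normal(size=(30, 4)))
    k = 6
    out = sc.metacell_smooth(mat, emb, k=k)
    nbrs = sc.neighbor_indices(emb, k=k)
    expected = sum(counts[nbrs[i]].sum() for i in range(30))
    assert out.dense().sum() == expected
    # symmetric special case: all cells identical coordinates with k = n-1
    emb_same = _embedding(np.zeros((30, 4)))
    out_same = sc.metacell_smooth(mat, emb_same, k=29)
    assert out_same.dense().sum() == 30 * counts.sum()


def test_smooth_requires_k_below_cell_count():
    mat = _matrix(np.zeros((5, 4)))
    with pytest.raises(ValueError, match="smaller than the number of cells"):
        sc.metacell_smooth(mat, _embedding(np.zeros((5, 2))), k=5)


# ---------------------------------------------------------------------------
# high-variance bin selection


def test_highvar_never_prefers_constant_bins():
    counts = np.ones((10, 5))
    counts[:, 2] = np.arange(10)  # the only varying bin
    got = sc.select_highvar_bins(_matrix(counts), n=1)
    assert got.tolist() == [2]


def test_highvar_all_bins_is_identity():
    mat = _matrix(np.random.default_rng(1).integers(0, 5, (8, 12)))
    assert sc.select_highvar_bins(mat, n=12).tolist() == list(range(12))


def test_highvar_matches_bruteforce_variance_sort():
    rng = np.random.default_rng(2)
    counts = rng.poisson(2.0, (40, 200))
    got = set(sc.select_highvar_bins(_matrix(counts), n=50))
    var = counts.var(axis=0)
    brute = set(np.argsort(-var, kind="stable")[:50])
    assert got == brute


# ---------------------------------------------------------------------------
# adjusted Rand index


def test_ari_identical_and_relabeled_partitions():
    labels = np.array(["a", "a", "b", "b", "c", "c"])
    assert sc.adjusted_rand(labels, labels) == 1.0
    relabeled = np.array([2, 2, 0, 0, 1, 1])  # same partition, new ids
    assert sc.adjusted_rand(labels, relabeled) == 1.0


def test_ari_matches_contingency_formula_oracle():
    """Hand-computed pair-counting formula on n=20 against the library value."""
    from scipy.special import comb

    rng = np.random.default_rng(6)
    a = rng.integers(0, 3, 20)
    b = rng.integers(0, 4, 20)
    # contingency table
    table = np.zeros((3, 4))
    for x, y in zip(a, b):
        table[x, y] += 1
    sum_comb = comb(table, 2).sum()
    comb_a = comb(table.sum(axis=1), 2).sum()
    comb_b = comb(table.sum(axis=0), 2).sum()
    n_pairs = comb(20, 2)
    expected = comb_a * comb_b / n_pairs
    max_index = (comb_a + comb_b) / 2
    by_hand = (sum_comb - expected) / (max_index - expected)
    assert sc.adjusted_rand(a, b) == pytest.approx(by_hand, abs=1e-12)


def test_ari_of_independent_labelings_is_near_zero():
    rng = np.random.default_rng(7)
    vals = [
        sc.adjusted_rand(rng.integers(0, 4, 1000), rng.integers(0, 4, 1000))
        for _ in range(100)
    ]
    assert abs(np.mean(vals)) < 0.01


def test_ari_length_mismatch_errors():
    with pytest.raises(ValueError, match="length"):
        sc.adjusted_rand([0, 1], [0, 1, 2])


# ---------------------------------------------------------------------------
# clustering


def test_two_separated_blobs_cluster_perfectly():
    rng = np.random.default_rng(8)
    a = rng.normal(0, 0.1, (20, 30))
    b = rng.normal(5, 0.1, (20, 30))
    mat = _matrix(np.abs(np.vstack([a, b])), labels=["x"] * 20 + ["y"] * 20)
    res = sc.cluster_cells(mat, k=2, seed=0, log_normalize=False)
    assert res.ari == 1.0


def test_cluster_determinism_given_seed():
    rng = np.random.default_rng(9)
    mat = _matrix(rng.poisson(3, (40, 50)), labels=["x"] * 20 + ["y"] * 20)
    r1 = sc.cluster_cells(mat, k=2, seed=3)
    r2 = sc.cluster_cells(mat, k=2, seed=3)
    assert np.array_equal(r1.assignments, r2.assignments)


def test_cluster_rejects_degenerate_input():
    mat = _matrix(np.ones((10, 5)))
    with pytest.raises(ValueError, match="degenerate"):
        sc.cluster_cells(mat, k=2, seed=0)


# ---------------------------------------------------------------------------
# per-cell correction


@pytest.fixture(scope="module")
def sc_setup(bundle, biased_bulk, trained_model):
    mat, emb, labels = syn.simulate_cells(bundle, beta=0.5, seed=31)
    smoothed = sc.metacell_smooth(mat, emb, k=10)
    cand = sc.select_highvar_bins(smoothed, n=1000)
    corrected = sc.correct_cells(
        smoothed, biased_bulk["atac_track"], trained_model, candidate=cand
    )
    return mat, smoothed, cand, corrected, labels


def test_correct_cells_scores_are_probabilities(sc_setup):
    _, _, _, corrected, _ = sc_setup
    S = corrected.dense()
    assert S.min() >= 0 and S.max() <= 1


def test_identical_smoothed_rows_get_identical_scores(bundle, biased_bulk, trained_model):
    bins = tr.tile_genome(bundle.layout, 200)
    counts = np.zeros((3, len(bins)))
    counts[:, 100] = 7  # two identical cells + one different
    counts[2, 500] = 4
    mat = sc.CellBinMatrix(sparse.csr_matrix(counts), ["a", "b", "c"], bins)
    corrected = sc.correct_cells(
        mat, biased_bulk["atac_track"], trained_model, candidate=np.arange(0, 1000)
    )
    S = corrected.dense()
    assert np.array_equal(S[0], S[1])
    assert not np.array_equal(S[0], S[2])


def test_all_zero_cell_gets_constant_intercept_scores(bundle, biased_bulk, trained_model):
    bins = tr.tile_genome(bundle.layout, 200)
    counts = np.zeros((2, len(bins)))
    counts[1, 40] = 3
    mat = sc.CellBinMatrix(sparse.csr_matrix(counts), ["empty", "ok"], bins)
    # candidate bins far from any ATAC signal -> zero features for the empty
    # cell give one constant score driven by the model intercept
    cand = np.arange(9500, 9600)
    corrected = sc.correct_cells(mat, biased_bulk["atac_track"], trained_model,
                                 candidate=cand)
    S = corrected.dense()
    atac_flat = np.allclose(
        tr.bin_means(biased_bulk["atac_track"], [bins[j] for j in cand]), 0
    )
    if atac_flat:
        assert len(np.unique(np.round(S[0], 12))) == 1


def test_correction_is_row_independent(bundle, biased_bulk, trained_model, sc_setup):
    mat, smoothed, cand, corrected, _ = sc_setup
    sub = sc.CellBinMatrix(
        smoothed.matrix[:10], smoothed.barcodes[:10], smoothed.bins,
        None if smoothed.labels is None else smoothed.labels[:10],
    )
    sub_corr = sc.correct_cells(sub, biased_bulk["atac_track"], trained_model,
                                candidate=cand)
    assert np.allclose(sub_corr.dense(), corrected.dense()[:10])


def test_marked_bins_outscore_bias_bins_within_cell_types(bundle, sc_setup):
    mat, smoothed, cand, corrected, labels = sc_setup
    key = {(b.chrom, b.start): j for j, b in enumerate(corrected.bins)}
    acc_idx = [
        key[(b.chrom, b.start)]
        for b in syn._intervals_to_bins(bundle.accessible_regions, 200)
        if (b.chrom, b.start) in key
    ]
    S = corrected.dense()
    for t in range(bundle.cfg.n_cell_types):
        cells = labels == f"type{t}"
        mark_idx = [
            key[(b.chrom, b.start)]
            for b in syn._intervals_to_bins(bundle.sc_type_regions(t), 200)
            if (b.chrom, b.start) in key
        ]
        assert np.median(S[np.ix_(cells, mark_idx)]) > np.median(
            S[np.ix_(cells, acc_idx)]
        )


def test_cell_matrix_from_barcoded_fragments(tmp_path, bundle):
    bed = tmp_path / "cells.bed"
    bed.write_text(
        "chr1\t100\t200\tcellB\n"
        "chr1\t100\t160\tcellA\n"
        "chr1\t350\t450\tcellA\n"  # midpoint 400 -> bin 2
        "chrM\t10\t60\tcellA\n"  # excluded chromosome
    )
    mat = sc.cell_matrix_from_fragments(bed, bundle.layout)
    assert mat.barcodes == ["cellB", "cellA"]  # first-appearance order
    dense = mat.dense()
    assert dense.sum() == 3
    assert dense[0, 0] == 1  # cellB, bin [0, 200)
    assert dense[1, 0] == 1 and dense[1, 2] == 1


def test_mtx_round_trip(tmp_path, sc_setup):
    mat, *_ = sc_setup
    outdir = tmp_path / "mtx"
    mat.to_mtx(outdir)
    back = sc.CellBinMatrix.from_mtx(outdir)
    assert np.array_equal(back.dense(), mat.dense())
    assert back.barcodes == mat.barcodes
    assert back.bins == mat.bins
    assert np.array_equal(back.labels, mat.labels)
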
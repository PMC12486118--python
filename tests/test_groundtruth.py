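"""Gene-set selection, candidate binning, and the three curation rule families."""

import numpy as np
import pandas as pd
import pytest

from tn5shadow import groundtruth as gt
from tn5shadow import synthetic as syn
from tn5shadow import tracks as tr
from helpers import make_frags


@pytest.fixture()
def tiny_annotation():
    return gt.GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": ["gA", "gB"],
                "chrom": ["chrA", "chrA"],
                "start": [2000, 6000],
                "end": [3000, 7000],
                "strand": ["+", "-"],
            }
        )
    )


# ---------------------------------------------------------------------------
# gene sets


def test_pick_gene_sets_basic():
    expr = gt.ExpressionTable(pd.Series({"a": 0.0, "b": 0.0, "c": 5.0, "d": 9.0}))
    nonexpr, top = gt.pick_gene_sets(expr, 2)
    assert nonexpr == {"a", "b"}
    assert top == {"d", "c"}


def test_pick_gene_sets_all_zero_is_degenerate():
    expr = gt.ExpressionTable(pd.Series({"a": 0.0, "b": 0.0}))
    with pytest.raises(ValueError, match="zero expression"):
        gt.pick_gene_sets(expr, 1)


def test_pick_gene_sets_n_too_large():
    expr = gt.ExpressionTable(pd.Series({"a": 1.0}))
    with pytest.raises(ValueError, match="exceeds"):
        gt.pick_gene_sets(expr, 2)


def test_pick_gene_sets_counts_match_generator(bundle):
    cfg = bundle.cfg
    nonexpr, top = gt.pick_gene_sets(bundle.expression, cfg.n_false_candidate_regions)
    expected_zero = round(cfg.fraction_nonexpressed * cfg.n_genes)
    assert len(nonexpr) == expected_zero
    assert len(top) == cfg.n_false_candidate_regions


def test_pick_ubiquitous_ranks_by_minimum():
    table = pd.DataFrame({"t1": [3.0, 5.0], "t2": [3.0, 1.0]}, index=["g1", "g2"])
    assert gt.pick_ubiquitous_genes(table, 1) == {"g1"}  # min 3 beats min 1
    assert gt.pick_ubiquitous_genes(table, 2) == {"g1", "g2"}


def test_pick_ubiquitous_matches_bruteforce_sort():
    rng = np.random.default_rng(3)
    table = pd.DataFrame(
        rng.random((500, 4)), index=[f"g{i:03d}" for i in range(500)]
    )
    got = gt.pick_ubiquitous_genes(table, 50)
    mins = table.min(axis=1)
    brute = set(
        sorted(mins.index, key=lambda g: (-mins[g], g))[:50]
    )
    assert got == brute


# ---------------------------------------------------------------------------
# candidate bins


@pytest.mark.parametrize(
    "peak,expected_starts",
    [((250, 760), [200, 400, 600]), ((400, 600), [400])],
)
def test_candidate_bins_snap_to_global_grid(peak, expected_starts):
    peaks = pd.DataFrame({"chrom": ["chrA"], "start": [peak[0]], "end": [peak[1]]})
    bins = gt.candidate_bins_from_peaks(peaks)
    assert bins["start"].tolist() == expected_starts
    assert (bins["width"] == 200).all()


def test_candidate_bins_match_per_bp_marking_oracle():
    rng = np.random.default_rng(7)
    starts = rng.integers(0, 9_000, 100)
    peaks = pd.DataFrame(
        {"chrom": "chrA", "start": starts, "end": starts + rng.integers(1, 900, 100)}
    )
    got = set(gt.candidate_bins_from_peaks(peaks)["start"])
    marked = np.zeros(10_000, dtype=bool)
    for s, e in zip(peaks["start"], peaks["end"]):
        marked[s:e] = True
    brute = {b for b in range(0, 10_000, 200) if marked[b : b + 200].any()}
    assert got == brute


# ---------------------------------------------------------------------------
# repressive curation on hand-built cases


def _one_bin_candidates(start=2000):
    return [pd.DataFrame({"chrom": ["chrA"], "start": [start], "width": [200]})]


def test_repressive_true_when_all_filters_pass(tiny_annotation):
    expr_zero = {"gA"}
    top = {"gB"}
    cfg = gt.CurationConfig(recurrence_min=1, n_top_expressed=1)
    labeled = gt.curate_repressive(
        _one_bin_candidates(), tiny_annotation, expr_zero, top,
        conjugate_frag_sets=[make_frags([])], conjugate_peak_sets=[], cfg=cfg,
    )
    assert labeled.n_true == 1 and labeled.n_false == 0


def test_repressive_excluded_by_single_conjugate_read(tiny_annotation):
    cfg = gt.CurationConfig(recurrence_min=1, n_top_expressed=1)
    conj = make_frags([("chrA", 2100, 2150, "+")])
    labeled = gt.curate_repressive(
        _one_bin_candidates(), tiny_annotation, {"gA"}, {"gB"},
        conjugate_frag_sets=[conj], conjugate_peak_sets=[], cfg=cfg,
    )
    assert labeled.n_true == 0


def test_repressive_recurrence_is_monotone(tiny_annotation):
    # the bin occurs in 2 of 3 samples; raising recurrence_min never adds TRUEs
    cands = [
        _one_bin_candidates()[0],
        _one_bin_candidates()[0],
        pd.DataFrame({"chrom": ["chrA"], "start": [4000], "width": [200]}),
    ]
    n_true = []
    for rmin in (1, 2, 3):
        cfg = gt.CurationConfig(recurrence_min=rmin, n_top_expressed=1)
        labeled = gt.curate_repressive(
            cands, tiny_annotation, {"gA"}, {"gB"},
            conjugate_frag_sets=[make_frags([])], conjugate_peak_sets=[], cfg=cfg,
        )
        n_true.append(labeled.n_true)
    assert n_true[0] >= n_true[1] >= n_true[2]
    assert n_true[1] == 1 and n_true[2] == 0


def test_repressive_recurrence_min_above_sample_count_errors(tiny_annotation):
    cfg = gt.CurationConfig(recurrence_min=5, n_top_expressed=1)
    with pytest.raises(ValueError, match="recurrence_min"):
        gt.curate_repressive(
            _one_bin_candidates(), tiny_annotation, {"gA"}, {"gB"},
            conjugate_frag_sets=[], conjugate_peak_sets=[], cfg=cfg,
        )


# ---------------------------------------------------------------------------
# active curation on hand-built cases


def test_active_true_blocked_by_flanking_repressive_read(tiny_annotation):
    # repressive read 300 bp downstream of the bin: inside the +/-500 window
    cfg = gt.CurationConfig(recurrence_min=1, n_top_expressed=1, flanking_bp=500)
    rep = make_frags([("chrA", 2550, 2600, "+")])  # bin is [2000, 2200)
    labeled = gt.curate_active(
        _one_bin_candidates(), tiny_annotation, {"gB"}, {"gA"},
        conjugate_frag_sets=[rep], conjugate_peak_sets=[], cfg=cfg,
    )
    assert labeled.n_true == 0


def test_active_false_requires_repressive_peak_overlap(tiny_annotation):
    cfg = gt.CurationConfig(recurrence_min=1, n_top_expressed=1)
    rep_peaks = [pd.DataFrame({"chrom": ["chrA"], "start": [5900], "end": [6300]})]
    cands = [pd.DataFrame({"chrom": ["chrA"], "start": [6000], "width": [200]})]
    labeled = gt.curate_active(
        cands, tiny_annotation, {"gB"}, {"gA"},
        conjugate_frag_sets=[make_frags([])], conjugate_peak_sets=rep_peaks, cfg=cfg,
    )
    # bin sits in non-expressed gB's body and overlaps a repressive peak
    assert labeled.n_false == 1 and labeled.n_true == 0


# ---------------------------------------------------------------------------
# heterochromatin curation on hand-built cases


def test_heterochromatin_requires_min_reads_in_every_sample(tiny_annotation):
    cfg = gt.CurationConfig(recurrence_min=1, n_top_expressed=1, min_reads=5)
    peak = pd.DataFrame({"chrom": ["chrA"], "start": [2000], "end": [2400]})
    five = make_frags([("chrA", 2000 + 10 * i, 2050 + 10 * i, "+") for i in range(5)])
    four = make_frags([("chrA", 2000 + 10 * i, 2050 + 10 * i, "+") for i in range(4)])
    labeled = gt.curate_heterochromatin(
        [peak], tiny_annotation, set(), [five, four], [make_frags([])], cfg,
    )
    assert labeled.n_true == 0  # 4 reads in one sample fails the >=5 rule
    labeled = gt.curate_heterochromatin(
        [peak], tiny_annotation, set(), [five, five], [make_frags([])], cfg,
    )
    assert labeled.n_true == 2  # 400 bp region -> two 200 bp bins


def test_heterochromatin_flank_excludes_regions_near_active_genes(tiny_annotation):
    # region 8 kb from gB's body is inside the +/-10 kb window -> not TRUE
    cfg = gt.CurationConfig(recurrence_min=1, n_top_expressed=1, min_reads=1)
    peak = pd.DataFrame({"chrom": ["chrA"], "start": [15000], "end": [15200]})
    reads = make_frags([("chrA", 15000, 15050, "+")])
    labeled = gt.curate_heterochromatin(
        [peak], tiny_annotation, {"gB"}, [reads], [make_frags([])], cfg,
    )
    assert labeled.n_true == 0


# ---------------------------------------------------------------------------
# planted-fixture recovery (clean sampling isolates the rule logic)


@pytest.fixture(scope="module")
def clean_fixture(bundle):
    layout = bundle.layout
    cands, rep_frags, rep_peaks = [], [], []
    for i in range(3):
        frags, peaks = syn.simulate_bulk(
            bundle, "cuttag_repressive", beta=0.0, seed=100 + i, background_fraction=0.0
        )
        cands.append(gt.candidate_bins_from_peaks(peaks, layout=layout))
        rep_frags.append(frags)
        rep_peaks.append(peaks)
    conj_frags, conj_peaks = syn.simulate_bulk(
        bundle, "cuttag_active", beta=0.0, seed=200, background_fraction=0.0
    )
    nonexpr, top = gt.pick_gene_sets(
        bundle.expression, bundle.cfg.n_false_candidate_regions
    )
    return {
        "cands": cands, "rep_frags": rep_frags, "rep_peaks": rep_peaks,
        "conj_frags": conj_frags, "conj_peaks": conj_peaks,
        "nonexpr": nonexpr, "top": top,
    }


def _key_sets(labeled):
    t = {(r.chrom, r.start) for r in labeled.bins[labeled.bins.label == 1].itertuples()}
    f = {(r.chrom, r.start) for r in labeled.bins[labeled.bins.label == 0].itertuples()}
    return t, f


def test_repressive_curation_recovers_planted_labels(bundle, clean_fixture):
    cfg = gt.CurationConfig(
        n_top_expressed=bundle.cfg.n_false_candidate_regions, recurrence_min=2
    )
    labeled = gt.curate_repressive(
        clean_fixture["cands"], bundle.annotation, clean_fixture["nonexpr"],
        clean_fixture["top"], [clean_fixture["conj_frags"]],
        [clean_fixture["conj_peaks"]], cfg, layout=bundle.layout,
    )
    got_t, got_f = _key_sets(labeled)
    planted_t = {(b.chrom, b.start) for b in bundle.true_bins()}
    planted_f = {(b.chrom, b.start) for b in bundle.false_bins()}
    assert got_t == planted_t and got_f == planted_f
    # every TRUE bin re-checks as conjugate-free
    counts = tr.count_overlapping_reads(
        clean_fixture["conj_frags"], labeled.as_bins(label=1)
    )
    assert counts.sum() == 0


def test_active_curation_recovers_planted_labels(bundle, clean_fixture):
    # for the active mark the roles invert: accessible promoters of the top
    # genes are the genuine signal, repressive domains the false candidates
    act_cands = [
        gt.candidate_bins_from_peaks(clean_fixture["conj_peaks"], layout=bundle.layout)
    ]
    cfg = gt.CurationConfig(
        mark_class="active_exclusivity",
        n_top_expressed=bundle.cfg.n_false_candidate_regions, recurrence_min=1,
    )
    labeled = gt.curate_active(
        act_cands, bundle.annotation, clean_fixture["nonexpr"], clean_fixture["top"],
        clean_fixture["rep_frags"], clean_fixture["rep_peaks"][:1], cfg,
        layout=bundle.layout,
    )
    got_t, got_f = _key_sets(labeled)
    assert got_t == {(b.chrom, b.start) for b in bundle.false_bins()}
    assert got_f == {(b.chrom, b.start) for b in bundle.true_bins()}


def test_heterochromatin_curation_recovers_planted_labels(bundle, clean_fixture):
    cfg = gt.CurationConfig(
        mark_class="heterochromatin_counts",
        n_top_expressed=bundle.cfg.n_false_candidate_regions,
        recurrence_min=1, min_reads=5,
    )
    labeled = gt.curate_heterochromatin(
        clean_fixture["rep_peaks"][:2], bundle.annotation, clean_fixture["top"],
        clean_fixture["rep_frags"][:2], [clean_fixture["conj_frags"]], cfg,
        layout=bundle.layout,
    )
    got_t, got_f = _key_sets(labeled)
    assert got_t == {(b.chrom, b.start) for b in bundle.true_bins()}
    assert got_f == {(b.chrom, b.start) for b in bundle.false_bins()}


def test_curation_invariants(bundle, clean_fixture):
    cfg = gt.CurationConfig(
        n_top_expressed=bundle.cfg.n_false_candidate_regions, recurrence_min=2
    )
    labeled = gt.curate_repressive(
        clean_fixture["cands"], bundle.annotation, clean_fixture["nonexpr"],
        clean_fixture["top"], [clean_fixture["conj_frags"]],
        [clean_fixture["conj_peaks"]], cfg, layout=bundle.layout,
    )
    assert (labeled.bins["width"] == 200).all()
    # label disjointness is enforced by construction
    assert not labeled.bins.duplicated(subset=["chrom", "start"]).any()
    # region-length bookkeeping: kb totals follow directly from bin counts
    assert labeled.total_kb(1) == pytest.approx(labeled.n_true * 0.2)


def test_labeled_bins_bed_round_trip(tmp_path, bundle, clean_fixture):
    cfg = gt.CurationConfig(
        n_top_expressed=bundle.cfg.n_false_candidate_regions, recurrence_min=2
    )
    labeled = gt.curate_repressive(
        clean_fixture["cands"], bundle.annotation, clean_fixture["nonexpr"],
        clean_fixture["top"], [clean_fixture["conj_frags"]],
        [clean_fixture["conj_peaks"]], cfg, layout=bundle.layout,
    )
    path = tmp_path / "labels.bed"
    labeled.to_bed(path)
    back = gt.LabeledBinSet.from_bed(path)
    assert back.n_true == labeled.n_true and back.n_false == labeled.n_false
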
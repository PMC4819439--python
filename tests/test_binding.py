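"""Peak association, enrichment, and CRE co-occupancy against brute force."""

import logging

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from grnx.binding import (
    CRE,
    activator_repressor_overlap,
    associate_peaks,
    binding_enrichment,
    bound_genes,
    cres_per_gene,
    link_cres,
    merge_cres,
    non_changing_background,
    sharing_fraction,
    top_peaks,
)
from grnx.io_formats import GeneAnnotation, Peak


def _gene(gene_id, tss, strand="+", chrom="chr1"):
    if strand == "+":
        return GeneAnnotation(gene_id, chrom, "+", tss, tss, tss + 1000)
    return GeneAnnotation(gene_id, chrom, "-", tss, tss - 999, tss + 1)


def _peak(summit, tf="TF", chrom="chr1", score=1.0):
    return Peak(chrom, max(summit - 100, 0), summit + 100, summit, score, tf)


def brute_force_nearest(peaks, annotation, max_distance):
    """Quadratic all-pairs nearest-TSS scan (independent oracle)."""
    out = {}
    for i, p in enumerate(peaks):
        best = None
        for g in annotation:
            if g.chrom != p.chrom:
                continue
            d = abs(p.summit - g.tss)
            if best is None or d < best[0] or (d == best[0] and g.gene_id < best[1]):
                best = (d, g.gene_id)
        if best is not None and best[0] <= max_distance:
            out[i] = best[1]
    return out


def brute_force_merge(windows):
    """Union-find single-linkage merge of [start, end) windows (one chrom)."""
    n = len(windows)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            (s1, e1), (s2, e2) = windows[i], windows[j]
            if s1 < e2 and s2 < e1:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return {frozenset(g) for g in groups.values()}


class TestAssociate:
    def test_nearest_tss_wins(self):
        ann = [_gene("a", 4_000), _gene("b", 20_000)]
        links = associate_peaks([_peak(5_500)], ann)
        assert links[0].gene_id == "a"
        assert links[0].signed_distance == 1_500
        assert links[0].category == "distal"
        # exactly at the promoter halfwidth still counts as promoter
        assert associate_peaks([_peak(5_000)], ann)[0].category == "promoter"

    def test_signed_distance_is_strand_oriented(self):
        ann = [_gene("minus", 10_000, strand="-")]
        links = associate_peaks([_peak(9_500)], ann)
        # summit 500 bp before the TSS in genome coordinates, but the gene
        # reads leftwards: the summit is 500 bp downstream
        assert links[0].signed_distance == 500
        assert links[0].category == "promoter"

    def test_equidistant_tie_breaks_lexicographically(self, caplog):
        ann = [_gene("zzz", 3_000), _gene("aaa", 7_000)]
        with caplog.at_level(logging.WARNING, logger="grnx.binding"):
            links = associate_peaks([_peak(5_000)], ann)
        assert links[0].gene_id == "aaa"
        assert any("equidistant" in r.message for r in caplog.records)

    def test_distance_cap_and_missing_chrom(self):
        ann = [_gene("a", 1_000)]
        links = associate_peaks(
            [_peak(500_000), _peak(2_000, chrom="chrX")], ann, max_distance=100_000)
        assert links == []

    def test_matches_quadratic_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n_genes = int(rng.integers(5, 60))
            ann = [
                _gene(f"g{j:03d}", int(rng.integers(0, 2_000_000)),
                      strand="+" if rng.random() < 0.5 else "-",
                      chrom=f"chr{int(rng.integers(1, 3))}")
                for j in range(n_genes)
            ]
            peaks = [
                _peak(int(rng.integers(0, 2_000_000)),
                      chrom=f"chr{int(rng.integers(1, 3))}")
                for _ in range(int(rng.integers(1, 80)))
            ]
            links = associate_peaks(peaks, ann, max_distance=150_000)
            got = {}
            remaining = {id(p): i for i, p in enumerate(peaks)}
            for l in links:
                got[remaining[id(l.peak)]] = l.gene_id
            assert got == brute_force_nearest(peaks, ann, 150_000)

    def test_bound_genes_deduplicates(self):
        ann = [_gene("a", 4_000)]
        links = associate_peaks([_peak(4_100, tf="X"), _peak(4_300, tf="X"),
                                 _peak(4_200, tf="Y")], ann)
        assert bound_genes(links, "X") == {"a"}
        assert bound_genes(links, "Z") == set()

    def test_top_peaks_by_score(self):
        peaks = [_peak(1_000, score=1.0), _peak(5_000, score=9.0),
                 _peak(9_000, score=5.0)]
        kept = top_peaks(peaks, 2)
        assert {p.summit for p in kept} == {5_000, 9_000}
        assert [p.start for p in kept] == sorted(p.start for p in kept)


class TestEnrichment:
    def test_hand_chi_squared(self):
        # [[53, 47], [20, 80]]:
        # chi2 = 200*(53*80-47*20)^2/(100*100*73*127) = 23.4926...
        gset = {f"s{i}" for i in range(100)}
        bg = {f"b{i}" for i in range(100)}
        bound = {f"s{i}" for i in range(53)} | {f"b{i}" for i in range(20)}
        res = binding_enrichment(gset, bg, bound)
        assert res.chi2 == pytest.approx(200 * 3300**2 / (100 * 100 * 73 * 127))
        assert res.p < 1e-5
        assert res.fisher_p is None  # all expected cells well populated

    def test_identical_proportions_null(self):
        gset = {f"s{i}" for i in range(100)}
        bg = {f"b{i}" for i in range(100)}
        bound = {f"s{i}" for i in range(20)} | {f"b{i}" for i in range(20)}
        res = binding_enrichment(gset, bg, bound)
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_empty_geneset_fatal(self):
        with pytest.raises(ValueError, match="empty"):
            binding_enrichment(set(), {"b"}, set())

    def test_fisher_reported_for_sparse_tables(self):
        gset = {f"s{i}" for i in range(8)}
        bg = {f"b{i}" for i in range(8)}
        res = binding_enrichment(gset, bg, {"s0", "s1"})
        assert res.fisher_p is not None
        assert 0.0 <= res.fisher_p <= 1.0

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            n1, n2 = rng.integers(20, 200, 2)
            k1 = int(rng.integers(1, n1))
            k2 = int(rng.integers(1, n2))
            gset = {f"s{i}" for i in range(n1)}
            bg = {f"b{i}" for i in range(n2)}
            bound = {f"s{i}" for i in range(k1)} | {f"b{i}" for i in range(k2)}
            res = binding_enrichment(gset, bg, bound)
            ref = chi2_contingency([[k1, n1 - k1], [k2, n2 - k2]],
                                   correction=False)
            assert res.chi2 == pytest.approx(ref.statistic)
            assert res.p == pytest.approx(ref.pvalue)


class TestMergeCres:
    def test_overlapping_windows_merge(self):
        cres = merge_cres({"A": [_peak(1_000)], "B": [_peak(1_150)]}, halfwidth=150)
        assert len(cres) == 1
        assert cres[0].occupants == {"A", "B"}
        assert cres[0].n_peaks == 2

    def test_distant_windows_stay_separate(self):
        cres = merge_cres({"A": [_peak(1_000), _peak(2_000)]}, halfwidth=150)
        assert len(cres) == 2

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            summits = rng.integers(500, 20_000, size=int(rng.integers(2, 40)))
            peaks = {"T": [_peak(int(s)) for s in sorted(summits)]}
            hw = int(rng.integers(50, 400))
            cres = merge_cres(peaks, halfwidth=hw)
            windows = [(max(s - hw, 0), s + hw) for s in sorted(summits)]
            expected_groups = brute_force_merge(windows)
            # compare partition sizes by mapping windows into CREs
            sizes = sorted(len(g) for g in expected_groups)
            assert sorted(c.n_peaks for c in cres) == sizes
            # disjoint and sorted
            for c1, c2 in zip(cres, cres[1:]):
                assert c1.end <= c2.start
            assert sum(c.n_peaks for c in cres) == len(summits)


class TestSharing:
    def test_full_and_zero_sharing(self):
        shared = merge_cres({"A": [_peak(1_000)], "B": [_peak(1_000)]})
        assert sharing_fraction(shared, "A", "B") == 1.0
        apart = merge_cres({"A": [_peak(1_000)], "B": [_peak(5_000)]})
        assert sharing_fraction(apart, "A", "B") == 0.0
        assert np.isnan(sharing_fraction(apart, "C", "B"))

    def test_planted_half_coplacement(self):
        """500 tfA windows, 250 sitting on tfB summits -> sharing 0.5 +- 0.07."""
        rng = np.random.default_rng(31)
        a_peaks, b_peaks = [], []
        pos = 10_000
        for i in range(500):
            pos += int(rng.integers(2_000, 4_000))
            a_peaks.append(_peak(pos, tf="A"))
            if i % 2 == 0:
                b_peaks.append(_peak(pos, tf="B"))
        cres = merge_cres({"A": a_peaks, "B": b_peaks})
        assert sharing_fraction(cres, "A", "B") == pytest.approx(0.5, abs=0.07)

    def test_restrict_genes_scopes_the_fraction(self):
        ann = [_gene("a", 1_000), _gene("b", 60_000)]
        cres = merge_cres({"A": [_peak(1_200), _peak(60_200)],
                           "B": [_peak(1_200)]})
        cres = link_cres(cres, ann)
        assert sharing_fraction(cres, "A", "B", restrict_genes={"a"}) == 1.0
        assert sharing_fraction(cres, "A", "B", restrict_genes={"b"}) == 0.0

    def test_cres_per_gene_fraction(self):
        ann = [_gene("a", 10_000), _gene("b", 80_000)]
        cres = link_cres(
            merge_cres({"A": [_peak(10_500), _peak(12_000), _peak(14_000),
                              _peak(80_500)]}),
            ann,
        )
        hist, frac = cres_per_gene(cres, k=3)
        assert hist["a"] == 3 and hist["b"] == 1
        assert frac == 0.5
        empty_hist, empty_frac = cres_per_gene([])
        assert len(empty_hist) == 0 and np.isnan(empty_frac)

    def test_activator_repressor_extremes(self):
        together = link_cres(merge_cres({"Act": [_peak(1_000)],
                                         "Rep": [_peak(1_000)]}),
                             [_gene("a", 1_000)])
        ov = activator_repressor_overlap(together, {"Act"}, {"Rep"})
        assert ov["cre_activator_with_repressor"] == 1.0
        assert ov["gene_repressor_with_activator"] == 1.0
        apart = link_cres(merge_cres({"Act": [_peak(1_000)],
                                      "Rep": [_peak(9_000)]}),
                          [_gene("a", 1_000), _gene("b", 9_000)])
        ov2 = activator_repressor_overlap(apart, {"Act"}, {"Rep"})
        assert ov2["cre_activator_with_repressor"] == 0.0
        assert ov2["gene_activator_with_repressor"] == 0.0

    def test_planted_mid_fraction_overlap(self):
        rng = np.random.default_rng(37)
        act, rep = [], []
        pos = 10_000
        hits = 0
        for i in range(300):
            pos += int(rng.integers(2_000, 4_000))
            act.append(_peak(pos, tf="Act"))
            if rng.random() < 0.4:
                rep.append(_peak(pos, tf="Rep"))
                hits += 1
            else:
                rep.append(_peak(pos + 1_000, tf="Rep"))
        cres = merge_cres({"Act": act, "Rep": rep})
        ov = activator_repressor_overlap(cres, {"Act"}, {"Rep"})
        assert ov["cre_activator_with_repressor"] == pytest.approx(hits / 300,
                                                                   abs=0.02)


def test_non_changing_background_excludes_geneset():
    import pandas as pd
    from grnx.diffexpr import DETable

    def tab(padj: dict[str, float]) -> DETable:
        frame = pd.DataFrame({
            "base_mean": 10.0, "log2fc": 0.0, "p": list(padj.values()),
            "padj": list(padj.values()), "direction": "none",
        }, index=list(padj))
        return DETable("A", "B", 36.0, 0.05, 1.0, frame)

    t1 = tab({"g1": 0.9, "g2": 0.9, "g3": 0.01})
    t2 = tab({"g1": 0.8, "g2": 0.2, "g3": 0.9})
    bg = non_changing_background([t1, t2], exclude={"g1"})
    assert bg == set()  # g1 excluded, g2 changes in t2, g3 in t1
    bg2 = non_changing_background([t1, t2])
    assert bg2 == {"g1"}
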
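import numpy as np
import pytest

from tommscan import precursors as P
from tommscan import seeds
from tommscan.genome import GeneAnnotation, extract_all_regions, find_anchors
from tommscan.synthetic import back_translate, make_filler, reverse_complement

from .conftest import make_dna_region, make_region
from .oracles import brute_orfs


class TestCstFraction:
    def test_all_cst_half(self):
        assert P.cst_fraction("AAAASSSS") == 1.0

    def test_no_cst_in_half(self):
        assert P.cst_fraction("SSSSAAAA") == 0.0

    def test_direct_count_odd_length(self):
        # L=10, C-terminal half = final 5 residues "TAGCS" -> 3/5
        assert P.cst_fraction("MAGCSTAGCS") == pytest.approx(0.6)

    def test_odd_length_uses_floor_half(self):
        # L=9 -> half=4 -> "ASSS" has 3/4
        assert P.cst_fraction("AAAAAASSS") == pytest.approx(0.75)

    def test_include_gly_flag(self):
        assert P.cst_fraction("AAAAGGGG") == 0.0
        assert P.cst_fraction("AAAAGGGG", include_gly=True) == 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            P.cst_fraction("")

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        peps = ["M" + "".join(rng.choice(list("ACDESTG"), size=40)) for _ in range(50)]
        for lo, hi in [(0.3, 0.5), (0.45, 0.65)]:
            keep_hi = [p for p in peps if P.cst_fraction(p) >= hi]
            keep_lo = [p for p in peps if P.cst_fraction(p) >= lo]
            assert set(keep_hi) <= set(keep_lo)


def _gene(gene_id, length_bp, protein, start=1000, strand="+"):
    return (gene_id, protein, strand, start, start + length_bp)


def _region_with_genes(genes):
    members = [
        GeneAnnotation(gid, "g", s, e, strand, protein=prot)
        for gid, prot, strand, s, e in genes
    ]
    from tommscan.genome import GenomicRegion

    return GenomicRegion(
        region_id="r1",
        genome_id="g",
        anchor_gene_id="anchor",
        window_start=0,
        window_end=30_000,
        member_proteins=sorted(members, key=lambda m: m.start),
        intergenic_segments=[],
        dna="",
    )


class TestMethod1:
    def test_450bp_gene_excluded_despite_high_cst(self):
        pep = "M" + "S" * 148  # 149 aa -> gene span 450 bp with stop
        region = _region_with_genes([_gene("g450", 450, pep)])
        assert P.method1_annotated(region) == []

    def test_300bp_gene_at_exact_threshold_included(self):
        # 40 residues, final 20 contain exactly 9 C/S/T -> 0.45
        pep = "M" + "A" * 19 + "A" * 11 + "S" * 9
        assert P.cst_fraction(pep) == pytest.approx(0.45)
        region = _region_with_genes([_gene("g300", 123, pep)])
        (cand,) = P.method1_annotated(region)
        assert cand.method == "1_annotated"
        assert cand.gene_id == "g300"

    def test_below_threshold_excluded(self):
        pep = "M" + "A" * 19 + "A" * 12 + "S" * 8  # 8/20 = 0.40
        region = _region_with_genes([_gene("g", 123, pep)])
        assert P.method1_annotated(region) == []

    def test_anchor_and_excluded_genes_skipped(self):
        pep = "M" + "S" * 39
        region = _region_with_genes(
            [
                _gene("anchor", 123, pep, start=100),
                _gene("cprot", 123, pep, start=400),
                _gene("ok", 123, pep, start=700),
            ]
        )
        found = P.method1_annotated(region, exclude_gene_ids={"cprot"})
        assert [c.gene_id for c in found] == ["ok"]


class TestSixFrameOrfs:
    def test_smallest_case(self):
        assert P.six_frame_orfs("ATGAAATAA", 2, 150) == [("MK", 0, 9, "+", 0)]

    def test_minus_strand_symmetry(self):
        rc = reverse_complement("ATGAAATAA")
        assert P.six_frame_orfs(rc, 2, 150) == [("MK", 0, 9, "-", 0)]

    def test_length_bounds(self):
        dna = back_translate("M" + "K" * 10)  # 11 aa ORF
        assert P.six_frame_orfs(dna, 12, 150) == []
        assert P.six_frame_orfs(dna, 11, 150) != []
        assert P.six_frame_orfs(dna, 2, 11) == []

    def test_non_acgt_never_starts(self):
        dna = "ANGAAATAA" + "ATGAAATAA"
        hits = P.six_frame_orfs(dna, 2, 150)
        assert ("MK", 9, 18, "+", 0) in hits
        assert all(h[1] != 0 for h in hits)

    def test_longest_per_stop_default(self):
        # two in-frame starts sharing one stop -> earliest only
        dna = "ATGAAAATGAAATAA"
        hits = [h for h in P.six_frame_orfs(dna, 2, 150) if h[3] == "+"]
        assert hits == [("MKMK", 0, 15, "+", 0)]
        all_hits = [h for h in P.six_frame_orfs(dna, 2, 150, all_starts=True) if h[3] == "+"]
        assert ("MKMK", 0, 15, "+", 0) in all_hits
        assert ("MK", 6, 15, "+", 0) in all_hits

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_enumerator(self, seed):
        rng = np.random.default_rng(seed)
        dna = "".join(rng.choice(list("ACGT"), size=1000))
        for all_starts in (False, True):
            assert P.six_frame_orfs(dna, 10, 150, all_starts=all_starts) == brute_orfs(
                dna, 10, 150, all_starts
            )


class TestMethod2:
    def _dna_for(self, peptide, pad=600):
        rng = np.random.default_rng(0)
        return make_filler(pad, rng) + back_translate(peptide) + make_filler(pad, rng)

    def test_recovers_unannotated_precursor(self):
        pep = "M" + "A" * 19 + "S" * 40  # 60 aa, C-half all S
        region = make_dna_region(self._dna_for(pep))
        cands = P.method2_sixframe(region)
        assert [c.sequence for c in cands] == [pep]
        assert cands[0].method == "2_sixframe"

    def test_exactly_150aa_excluded(self):
        pep = "M" + "A" * 74 + "S" * 75  # 150 aa
        region = make_dna_region(self._dna_for(pep))
        assert P.method2_sixframe(region) == []
        pep149 = "M" + "A" * 73 + "S" * 75  # 149 aa
        region = make_dna_region(self._dna_for(pep149))
        assert len(P.method2_sixframe(region)) == 1

    def test_cst_065_boundary(self):
        # 60 aa, half=30: 20/30 = 0.667 passes, 19/30 = 0.633 fails
        ok = "M" + "A" * 39 + "A" * 0 + "L" * 0 + "A" * 10 + "S" * 10  # recompute below
        ok = "M" + "A" * 29 + "A" * 10 + "S" * 20  # half = last 30 -> 20 S
        assert P.cst_fraction(ok) >= 0.65
        bad = "M" + "A" * 29 + "A" * 11 + "S" * 19
        assert P.cst_fraction(bad) < 0.65
        assert len(P.method2_sixframe(make_dna_region(self._dna_for(ok)))) == 1
        assert P.method2_sixframe(make_dna_region(self._dna_for(bad))) == []

    def test_duplicates_removed_keep_first_by_coordinate(self):
        pep = "M" + "A" * 19 + "S" * 40
        rng = np.random.default_rng(1)
        dna = (
            make_filler(500, rng)
            + back_translate(pep)
            + make_filler(500, rng)
            + back_translate(pep)
            + make_filler(500, rng)
        )
        cands = P.method2_sixframe(make_dna_region(dna))
        assert len(cands) == 1
        assert cands[0].start == 500

    def test_merge_with_method1_records_both(self):
        pep = "M" + "A" * 19 + "S" * 40  # passes both 0.45 and 0.65
        dna = self._dna_for(pep)
        start = 600
        region = _region_with_genes(
            [("pre", pep, "+", start, start + 3 * (len(pep) + 1))]
        )
        region.dna = dna
        region.window_end = len(dna)
        m1 = P.method1_annotated(region)
        m2 = P.method2_sixframe(region)
        merged = P.merge_candidates(m1, m2)
        assert len(merged) == 1
        assert merged[0].method == "both"
        assert merged[0].gene_id == "pre"


class TestScanAll:
    def test_flags_match_truth_table(self, small_bundle):
        genome, annotations, _, truth = small_bundle
        anchors = find_anchors(annotations, seeds.D_REFERENCES)
        regions = extract_all_regions({genome.id: genome}, annotations, anchors)
        _, flags = P.scan_all(regions, exclude_gene_ids={a.gene_id for a in anchors})
        anchor_cluster = {
            gid: c for c in truth.clusters for gid in c.anchor_gene_ids
        }
        expected_by_cluster = {
            c.cluster_id: any(
                p.cluster_id == c.cluster_id and p.expected_detection_method in ("1", "2")
                for p in truth.precursors
            )
            for c in truth.clusters
        }
        for region in regions:
            cluster = anchor_cluster[region.anchor_gene_id]
            assert flags[region.region_id] == expected_by_cluster[cluster.cluster_id], (
                region.region_id
            )

    def test_decoy_and_distal_regions_flag_false(self, small_bundle):
        genome, annotations, _, truth = small_bundle
        anchors = find_anchors(annotations, seeds.D_REFERENCES)
        regions = extract_all_regions({genome.id: genome}, annotations, anchors)
        _, flags = P.scan_all(regions, exclude_gene_ids={a.gene_id for a in anchors})
        anchor_cluster = {gid: c for c in truth.clusters for gid in c.anchor_gene_ids}
        for region in regions:
            arch = anchor_cluster[region.anchor_gene_id].archetype
            if arch in ("decoy_nonTOMM", "fused_CD_with_F"):
                assert flags[region.region_id] is False

    def test_raising_cst_threshold_never_adds(self, small_bundle):
        genome, annotations, _, _ = small_bundle
        anchors = find_anchors(annotations, seeds.D_REFERENCES)
        regions = extract_all_regions({genome.id: genome}, annotations, anchors)
        loose, _ = P.scan_all(regions, min_cst1=0.30, min_cst2=0.50)
        tight, _ = P.scan_all(regions, min_cst1=0.45, min_cst2=0.65)
        key = lambda cs: {(c.region_id, c.start, c.end, c.strand) for c in cs}
        assert key(tight) <= key(loose)


def test_candidate_tsv_written(tmp_path, small_bundle):
    genome, annotations, _, _ = small_bundle
    anchors = find_anchors(annotations, seeds.D_REFERENCES)
    regions = extract_all_regions({genome.id: genome}, annotations, anchors)
    cands, _ = P.scan_all(regions)
    path = tmp_path / "cands.tsv"
    P.write_candidates_tsv(cands, path)
    lines = path.read_text().splitlines()
    assert lines[0].startswith("region_id\tmethod")
    assert len(lines) == len(cands) + 1
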
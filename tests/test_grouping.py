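import numpy as np
import pytest

from tommscan import grouping
from tommscan.synthetic import mutate_protein

from .conftest import make_region, random_protein
from .oracles import brute_synteny


def _homolog_regions(rng, n_genes, identity=0.85, strands=None, order_b=None, rid=("ra", "rb")):
    """Two regions whose genes are mutants of shared founders."""
    founders = [random_protein(rng, 80) for _ in range(n_genes)]
    strands = strands or ["+"] * n_genes
    genes_a = [
        (f"a{i:02d}", mutate_protein(founders[i], identity, rng), strands[i])
        for i in range(n_genes)
    ]
    order_b = order_b if order_b is not None else list(range(n_genes))
    genes_b = [
        (f"b{i:02d}", mutate_protein(founders[i], identity, rng), strands[i])
        for i in order_b
    ]
    return make_region(genes_a, rid[0]), make_region(genes_b, rid[1])


class TestMapHits:
    def test_identical_regions_map_all_genes(self):
        rng = np.random.default_rng(0)
        genes = [(f"g{i}", random_protein(rng, 60), "+") for i in range(8)]
        ra = make_region(genes, "ra")
        rb = make_region([(f"h{i}", p, s) for (_, p, s), i in zip(genes, range(8))], "rb")
        mapping = grouping.map_hits(ra, rb)
        assert len(mapping) == 8
        assert {m.gene_a for m in mapping} == {g[0] for g in genes}

    def test_disjoint_regions_no_hits(self):
        rng = np.random.default_rng(1)
        ra = make_region([(f"a{i}", random_protein(rng, 150), "+") for i in range(5)], "ra")
        rb = make_region([(f"b{i}", random_protein(rng, 150), "+") for i in range(5)], "rb")
        assert grouping.map_hits(ra, rb) == []

    def test_duplicate_maps_once(self):
        rng = np.random.default_rng(2)
        p = random_protein(rng, 60)
        ra = make_region([("a0", p, "+")], "ra")
        rb = make_region([("b0", p, "+"), ("b1", p, "+")], "rb")
        mapping = grouping.map_hits(ra, rb)
        assert len(mapping) == 1
        assert mapping[0].gene_b == "b0"  # deterministic tie-break by gene order

    def test_hit_cap(self):
        rng = np.random.default_rng(3)
        genes = [(f"g{i}", random_protein(rng, 50), "+") for i in range(6)]
        ra = make_region(genes, "ra")
        rb = make_region([(f"h{i}", p, s) for (_, p, s), i in zip(genes, range(6))], "rb")
        assert len(grouping.map_hits(ra, rb, max_hits=3)) == 3


class TestSynteny:
    def test_identical_eight_gene_regions(self):
        rng = np.random.default_rng(4)
        ra, rb = _homolog_regions(rng, 8, identity=1.0)
        mapping = grouping.map_hits(ra, rb)
        assert grouping.synteny_score(mapping, ra, rb) == 7

    def test_whole_cluster_inversion_scores_full(self):
        rng = np.random.default_rng(5)
        strands = ["+", "-", "+", "+", "-", "+", "+", "+"]
        founders = [random_protein(rng, 80) for _ in range(8)]
        genes_a = [(f"a{i}", founders[i], strands[i]) for i in range(8)]
        flip = {"+": "-", "-": "+"}
        genes_b = [(f"b{i}", founders[i], flip[strands[i]]) for i in reversed(range(8))]
        ra, rb = make_region(genes_a, "ra"), make_region(genes_b, "rb")
        mapping = grouping.map_hits(ra, rb)
        assert len(mapping) == 8
        assert grouping.synteny_score(mapping, ra, rb) == 7

    def test_incoherent_inversion_does_not_count(self):
        rng = np.random.default_rng(6)
        founders = [random_protein(rng, 80) for _ in range(2)]
        ra = make_region([("a0", founders[0], "+"), ("a1", founders[1], "+")], "ra")
        # reversed order but strands NOT flipped -> not a coherent inversion
        rb = make_region([("b1", founders[1], "+"), ("b0", founders[0], "+")], "rb")
        mapping = grouping.map_hits(ra, rb)
        assert grouping.synteny_score(mapping, ra, rb) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_random_shuffle_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed + 100)
        order = list(rng.permutation(7))
        strands = [str(rng.choice(["+", "-"])) for _ in range(7)]
        ra, rb = _homolog_regions(rng, 7, identity=1.0, strands=strands, order_b=order)
        mapping = grouping.map_hits(ra, rb)
        got = grouping.synteny_score(mapping, ra, rb)
        expected = brute_synteny(
            ra.gene_order,
            rb.gene_order,
            {g.gene_id: g.strand for g in ra.member_proteins},
            {g.gene_id: g.strand for g in rb.member_proteins},
            {m.gene_a: m.gene_b for m in mapping},
        )
        assert got == expected


class TestRegionScore:
    def test_identical_21_gene_regions_score(self):
        rng = np.random.default_rng(7)
        ra, rb = _homolog_regions(rng, 21, identity=1.0)
        score = grouping.region_score(ra, rb)
        assert score.hit_count == 21
        assert score.synteny_score == 20
        assert score.total == pytest.approx(0.5 * 21 + 0.5 * 20)

    def test_disjoint_zero(self):
        rng = np.random.default_rng(8)
        ra = make_region([(f"a{i}", random_protein(rng, 150), "+") for i in range(4)], "ra")
        rb = make_region([(f"b{i}", random_protein(rng, 150), "+") for i in range(4)], "rb")
        assert grouping.region_score(ra, rb).total == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed + 200)
        order = list(rng.permutation(6))
        ra, rb = _homolog_regions(rng, 6, identity=0.8, order_b=order)
        s1 = grouping.region_score(ra, rb)
        s2 = grouping.region_score(rb, ra)
        assert s1.total == s2.total
        assert (s1.hit_count, s1.synteny_score) == (s2.hit_count, s2.synteny_score)

    def test_invariants(self):
        rng = np.random.default_rng(9)
        ra, rb = _homolog_regions(rng, 6, identity=0.75, order_b=[2, 0, 1, 5, 4, 3])
        s = grouping.region_score(ra, rb)
        assert s.hit_count <= 6
        assert s.synteny_score <= max(s.hit_count - 1, 0)

    def test_bits_mode(self):
        rng = np.random.default_rng(10)
        ra, rb = _homolog_regions(rng, 4, identity=1.0)
        s = grouping.region_score(ra, rb, score_mode="bits")
        assert s.total == pytest.approx(0.5 * s.bit_total + 0.5 * s.synteny_score)
        assert s.total > grouping.region_score(ra, rb).total


def _score(a, b, total):
    return grouping.RegionPairScore(a, b, 0, 0, total)


class TestGroupFamilies:
    def test_exact_threshold_excluded(self):
        fams = grouping.group_families([_score("r1", "r2", 10.0)], ["r1", "r2"])
        assert [f.member_region_ids for f in fams] == [["r1"], ["r2"]]

    def test_chain_single_linkage(self):
        fams = grouping.group_families(
            [_score("a", "b", 12.0), _score("b", "c", 11.0), _score("a", "c", 2.0)],
            ["a", "b", "c"],
        )
        assert [f.member_region_ids for f in fams] == [["a", "b", "c"]]
        assert fams[0].family_id == "a"

    def test_singletons_form_families(self):
        fams = grouping.group_families([], ["x", "y"])
        assert [f.family_id for f in fams] == ["x", "y"]

    def test_input_order_invariance(self):
        scores = [
            _score("a", "b", 12.0),
            _score("c", "d", 15.0),
            _score("b", "c", 3.0),
        ]
        ids = ["a", "b", "c", "d"]
        f1 = grouping.group_families(scores, ids)
        f2 = grouping.group_families(list(reversed(scores)), list(reversed(ids)))
        assert [f.member_region_ids for f in f1] == [f.member_region_ids for f in f2]

    def test_partition_property(self):
        rng = np.random.default_rng(11)
        ids = [f"r{i}" for i in range(12)]
        scores = [
            _score(ids[i], ids[j], float(rng.uniform(0, 20)))
            for i in range(12)
            for j in range(i + 1, 12)
        ]
        fams = grouping.group_families(scores, ids)
        seen = [rid for f in fams for rid in f.member_region_ids]
        assert sorted(seen) == sorted(ids)
        assert len(seen) == len(set(seen))

    def test_threshold_monotonicity_only_splits(self):
        rng = np.random.default_rng(12)
        ids = [f"r{i}" for i in range(10)]
        scores = [
            _score(ids[i], ids[j], float(rng.uniform(0, 20)))
            for i in range(10)
            for j in range(i + 1, 10)
        ]
        lo = grouping.group_families(scores, ids, threshold=8.0)
        hi = grouping.group_families(scores, ids, threshold=14.0)
        fam_lo = {rid: f.family_id for f in lo for rid in f.member_region_ids}
        # each high-threshold family must sit inside one low-threshold family
        for f in hi:
            assert len({fam_lo[rid] for rid in f.member_region_ids}) == 1


def test_planted_family_recovery(e2e_result, e2e_bundle):
    """Same-archetype regions group together; archetypes sharing no seed
    proteins never group."""
    _, _, _, truth = e2e_bundle
    anchor_cluster = {gid: c for c in truth.clusters for gid in c.anchor_gene_ids}
    fam_of = {
        rid: f.family_id for f in e2e_result.families for rid in f.member_region_ids
    }
    arch_of_region = {
        r.region_id: anchor_cluster[r.anchor_gene_id].archetype for r in e2e_result.regions
    }
    for fam in e2e_result.families:
        archs = {arch_of_region[rid] for rid in fam.member_region_ids}
        assert len(archs) == 1  # families never mix archetypes
    # all regions of each TOMM archetype landed in a single family
    for arch in ("discrete_CD", "fused_CD", "fused_CD_with_F", "standalone_D_bottromycin"):
        fams = {fam_of[rid] for rid, a in arch_of_region.items() if a == arch}
        assert len(fams) == 1, arch


def test_tsv_writers(tmp_path):
    scores = [_score("a", "b", 11.5)]
    fams = grouping.group_families(scores, ["a", "b"])
    grouping.write_scores_tsv(scores, tmp_path / "s.tsv")
    grouping.write_families_tsv(fams, tmp_path / "f.tsv")
    assert "a\tb\t0\t0\t11.500" in (tmp_path / "s.tsv").read_text()
    assert "a\ta\n" in (tmp_path / "f.tsv").read_text()
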
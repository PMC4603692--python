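"""Region-pair scoring and family grouping.

A pair of anchor regions is scored by a weighted combination of the number
of one-to-one homology hits between their member proteins (identity >= 30 %,
coverage >= 25, capped at 100 mapped hits) and a synteny term counting
adjacent hit pairs whose partners are also adjacent with coherent
orientation (whole-cluster inversions score as conserved).  Default
weights are 0.5/0.5 and regions with pair score above 10 (strict) are
merged into families by single linkage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from . import align
from .genome import GenomicRegion

DEFAULT_MIN_IDENTITY = 30.0
DEFAULT_MIN_COVERAGE = 25.0
DEFAULT_MAX_HITS = 100
DEFAULT_THRESHOLD = 10.0
DEFAULT_WEIGHTS = (0.5, 0.5)


@dataclass
class MappedHit:
    gene_a: str
    gene_b: str
    hit: align.AlignmentHit


@dataclass
class RegionPairScore:
    region_a: str
    region_b: str
    hit_count: int
    synteny_score: int
    total: float
    bit_total: float = 0.0

    @property
    def pair(self) -> tuple[str, str]:
        return (self.region_a, self.region_b)


def map_hits(
    region_a: GenomicRegion,
    region_b: GenomicRegion,
    params: align.ScoringParams = align.DEFAULT_PARAMS,
    *,
    min_identity_pct: float = DEFAULT_MIN_IDENTITY,
    min_coverage_pct: float = DEFAULT_MIN_COVERAGE,
    max_hits: int = DEFAULT_MAX_HITS,
    coverage_mode: str = "both",
) -> list[MappedHit]:
    """Greedy best-score one-to-one matching of member proteins.

    Coverage defaults to the symmetric "both sequences" mode so the
    resulting region score is symmetric.  Tie-break is by (score, gene
    order); at most ``max_hits`` pairs are mapped.
    """
    prot_a = [(g.gene_id, g.protein) for g in region_a.member_proteins if g.protein]
    prot_b = [(g.gene_id, g.protein) for g in region_b.member_proteins if g.protein]
    n_db = sum(len(p) for _, p in prot_a) + sum(len(p) for _, p in prot_b)
    candidates: list[tuple[int, int, int, align.AlignmentHit]] = []
    for ia, (ga, pa) in enumerate(prot_a):
        for ib, (gb, pb) in enumerate(prot_b):
            hit = align.compare(ga, pa, gb, pb, n_db, params)
            if hit is None:
                continue
            if hit.identity_pct < min_identity_pct:
                continue
            cov = (
                min(hit.query_coverage_pct, hit.subject_coverage_pct)
                if coverage_mode == "both"
                else hit.query_coverage_pct
            )
            if cov < min_coverage_pct:
                continue
            candidates.append((hit.raw_score, ia, ib, hit))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    mapped: list[MappedHit] = []
    for score, ia, ib, hit in candidates:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        mapped.append(MappedHit(prot_a[ia][0], prot_b[ib][0], hit))
        if len(mapped) >= max_hits:
            break
    return mapped


def synteny_score(
    mapping: Sequence[MappedHit],
    region_a: GenomicRegion,
    region_b: GenomicRegion,
) -> int:
    """Number of gene pairs adjacent in region a whose partners are adjacent
    in region b with coherent orientation.

    A pair counts if it is colinear (positions +1 apart in b, strand
    relationship preserved for both genes) or inverted (positions -1 apart
    with both strands flipped), making the score tolerant of whole-cluster
    inversions.
    """
    rank_a = {gid: i for i, gid in enumerate(region_a.gene_order)}
    rank_b = {gid: i for i, gid in enumerate(region_b.gene_order)}
    strand_a = {g.gene_id: g.strand for g in region_a.member_proteins}
    strand_b = {g.gene_id: g.strand for g in region_b.member_proteins}
    partner = {m.gene_a: m.gene_b for m in mapping}
    ordered = sorted(partner, key=lambda gid: rank_a[gid])
    score = 0
    for g1, g2 in zip(ordered, ordered[1:]):
        if rank_a[g2] - rank_a[g1] != 1:
            continue
        p1, p2 = partner[g1], partner[g2]
        delta = rank_b[p2] - rank_b[p1]
        same1 = strand_a[g1] == strand_b[p1]
        same2 = strand_a[g2] == strand_b[p2]
        if delta == 1 and same1 and same2:
            score += 1
        elif delta == -1 and not same1 and not same2:
            score += 1
    return score


def region_score(
    region_a: GenomicRegion,
    region_b: GenomicRegion,
    params: align.ScoringParams = align.DEFAULT_PARAMS,
    *,
    weights: tuple[float, float] = DEFAULT_WEIGHTS,
    min_identity_pct: float = DEFAULT_MIN_IDENTITY,
    min_coverage_pct: float = DEFAULT_MIN_COVERAGE,
    max_hits: int = DEFAULT_MAX_HITS,
    score_mode: str = "hits",
) -> RegionPairScore:
    """Weighted homology + synteny score; symmetric by construction (the
    pair is canonicalised by region_id before mapping)."""
    a, b = sorted((region_a, region_b), key=lambda r: r.region_id)
    mapping = map_hits(
        a,
        b,
        params,
        min_identity_pct=min_identity_pct,
        min_coverage_pct=min_coverage_pct,
        max_hits=max_hits,
    )
    syn = synteny_score(mapping, a, b)
    bits = sum(m.hit.bit_score for m in mapping)
    w_blast, w_synteny = weights
    hit_component = bits if score_mode == "bits" else len(mapping)
    return RegionPairScore(
        region_a=a.region_id,
        region_b=b.region_id,
        hit_count=len(mapping),
        synteny_score=syn,
        total=w_blast * hit_component + w_synteny * syn,
        bit_total=bits,
    )


def score_all_pairs(
    regions: Sequence[GenomicRegion],
    params: align.ScoringParams = align.DEFAULT_PARAMS,
    **kwargs,
) -> list[RegionPairScore]:
    return [
        region_score(a, b, params, **kwargs)
        for a, b in itertools.combinations(
            sorted(regions, key=lambda r: r.region_id), 2
        )
    ]


@dataclass
class FamilyAssignment:
    family_id: str
    member_region_ids: list[str]


def group_families(
    pair_scores: Iterable[RegionPairScore],
    region_ids: Iterable[str],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[FamilyAssignment]:
    """Single-linkage connected components over edges with total strictly
    above the threshold; singletons form their own families.  The family id
    is the lexicographically smallest member; output order is deterministic
    and independent of input order."""
    graph = nx.Graph()
    graph.add_nodes_from(region_ids)
    for ps in pair_scores:
        if ps.total > threshold:
            graph.add_edge(ps.region_a, ps.region_b)
    families = []
    for component in nx.connected_components(graph):
        members = sorted(component)
        families.append(FamilyAssignment(family_id=members[0], member_region_ids=members))
    families.sort(key=lambda f: f.family_id)
    return families


def write_scores_tsv(scores: Iterable[RegionPairScore], path) -> None:
    with open(path, "w") as fh:
        fh.write("region_a\tregion_b\thit_count\tsynteny_score\ttotal\tbit_total\n")
        for s in scores:
            fh.write(
                f"{s.region_a}\t{s.region_b}\t{s.hit_count}\t{s.synteny_score}\t"
                f"{s.total:.3f}\t{s.bit_total:.2f}\n"
            )


def write_families_tsv(families: Iterable[FamilyAssignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tregion_id\n")
        for fam in families:
            for rid in fam.member_region_ids:
                fh.write(f"{fam.family_id}\t{rid}\n")
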
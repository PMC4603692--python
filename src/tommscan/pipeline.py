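"""End-to-end orchestration: anchors -> regions -> precursors -> families
-> verdicts -> networks -> report."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import align, classify, grouping, precursors, report, seeds, ssn
from .genome import (
    DEFAULT_WINDOW,
    GeneAnnotation,
    GenomeRecord,
    extract_all_regions,
    find_anchors,
)


@dataclass
class PipelineResult:
    anchors: list[GeneAnnotation]
    regions: list
    candidates: list[precursors.PrecursorCandidate]
    precursor_flags: dict[str, bool]
    pair_scores: list[grouping.RegionPairScore]
    families: list[grouping.FamilyAssignment]
    role_calls: dict[str, list[classify.DomainCall]]
    bottromycin_flags: dict[str, bool]
    verdicts: list[classify.TOMMVerdict]
    d_network: ssn.SSNGraph | None = None
    all_network: ssn.SSNGraph | None = None
    family_table: pd.DataFrame | None = None

    def verdict_for_region(self, region_id: str) -> bool:
        for v in self.verdicts:
            if region_id in v.region_evidence:
                return v.is_tomm
        raise KeyError(region_id)


def run_pipeline(
    genomes: Mapping[str, GenomeRecord],
    annotations: Sequence[GeneAnnotation],
    *,
    window: int = DEFAULT_WINDOW,
    anchor_evalue: float = 1e-10,
    family_threshold: float = grouping.DEFAULT_THRESHOLD,
    params: align.ScoringParams = align.DEFAULT_PARAMS,
    build_networks: bool = True,
    min_component_size: int | None = None,
) -> PipelineResult:
    anchors = find_anchors(annotations, seeds.D_REFERENCES, anchor_evalue, params)
    regions = extract_all_regions(genomes, annotations, anchors, window)

    # role calls once per gene, shared across overlapping regions
    all_proteins = {g.gene_id: g.protein for r in regions for g in r.member_proteins}
    gene_calls = classify.call_genes(all_proteins, params=params)
    role_calls = {
        r.region_id: [gene_calls[g.gene_id] for g in r.member_proteins] for r in regions
    }

    # precursor scan, excluding anchors and C/CD/B-called genes from method 1
    exclude = {gid for gid, c in gene_calls.items() if c.role in ("C", "CD_fusion", "B")}
    exclude |= {a.gene_id for a in anchors}
    candidates, flags = precursors.scan_all(regions, exclude_gene_ids=exclude)

    pair_scores = grouping.score_all_pairs(regions, params)
    families = grouping.group_families(
        pair_scores, [r.region_id for r in regions], family_threshold
    )

    bmc_flags = {
        r.region_id: classify.bottromycin_like(r, role_calls[r.region_id], params=params)
        for r in regions
    }
    verdicts = classify.classify(families, role_calls, flags, bmc_flags)

    d_network = all_network = None
    if build_networks:
        tomm_regions = {
            rid for v in verdicts if v.is_tomm for rid in v.region_evidence
        }
        family_of = {
            rid: f.family_id for f in families for rid in f.member_region_ids
        }
        d_prots: dict[str, str] = {}
        all_prots: dict[str, str] = {}
        attrs: dict[str, dict] = {}
        for r in regions:
            if r.region_id not in tomm_regions:
                continue
            for g in r.member_proteins:
                role = gene_calls[g.gene_id].role
                attrs[g.gene_id] = {"role": role, "family": family_of[r.region_id]}
                all_prots[g.gene_id] = g.protein
                if role in ("D", "CD_fusion"):
                    d_prots[g.gene_id] = g.protein
        if d_prots:
            d_network = ssn.build_network(
                d_prots, ssn.D_NETWORK_EVALUE, node_attributes=attrs, params=params
            )
        if all_prots:
            all_network = ssn.build_network(
                all_prots,
                ssn.ALL_NETWORK_EVALUE,
                min_component_size=min_component_size,
                node_attributes=attrs,
                params=params,
            )

    table = report.family_report(families, verdicts, role_calls, candidates)
    return PipelineResult(
        anchors=anchors,
        regions=regions,
        candidates=candidates,
        precursor_flags=flags,
        pair_scores=pair_scores,
        families=families,
        role_calls=role_calls,
        bottromycin_flags=bmc_flags,
        verdicts=verdicts,
        d_network=d_network,
        all_network=all_network,
        family_table=table,
    )
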
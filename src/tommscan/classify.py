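"""Gene-role calling and the three-rule TOMM decision.

A family is a TOMM if ANY member region carries a C or CD-fusion protein,
contains a precursor peptide, or looks bottromycin-like (scores with a
bottromycin reference region, or carries two D-role genes plus a
radical-SAM enzyme).  The family verdict propagates to every member
region.

Role calling here is self-contained: local-alignment similarity against
bundled role seed sequences.  For real-data use an adapter ingests HMMER
domtblout rows keyed by model accession (TIGR03603 -> C, TIGR03882 ->
CD_fusion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import align, seeds
from .genome import GenomicRegion
from .grouping import DEFAULT_THRESHOLD, RegionPairScore, region_score

ROLE_PRIORITY = [
    "CD_fusion",
    "C",
    "B",
    "F",
    "D",
    "radical_SAM",
    "transporter",
    "protease",
    "methyltransferase",
    "other",
]
_PRIORITY = {r: i for i, r in enumerate(ROLE_PRIORITY)}

DEFAULT_ROLE_EVALUE = 1e-10
TRUNCATED_CD_EVALUE = 1e-5  # reduced C-side cutoff for truncated fusions

#: HMMER accession -> role, for the external-domtbl adapter
ACCESSION_ROLES = {"TIGR03603": "C", "TIGR03882": "CD_fusion"}


@dataclass
class DomainCall:
    gene_id: str
    role: str
    best_reference: str | None
    evalue: float
    truncated: bool = False


def call_genes(
    proteins: Mapping[str, str],
    reference_panel: Mapping[str, tuple[str, str]] | None = None,
    evalue_cutoff: float = DEFAULT_ROLE_EVALUE,
    params: align.ScoringParams = align.DEFAULT_PARAMS,
) -> dict[str, DomainCall]:
    """Assign each protein the role of its best reference hit passing the
    cutoff (ties broken by role priority: CD_fusion > C > B > F > ...),
    else "other".

    A gene whose best call is D but whose C-reference similarity passes a
    reduced cutoff is promoted to a CD_fusion call flagged ``truncated``
    (handles fusions missing part of the C domain).
    """
    panel = reference_panel if reference_panel is not None else seeds.role_panel()
    if not panel:
        raise ValueError("reference panel must be non-empty")
    n_db = sum(len(s) for _, s in panel.values())
    max_le = math.log10(evalue_cutoff)
    reduced_le = math.log10(TRUNCATED_CD_EVALUE)
    calls: dict[str, DomainCall] = {}
    for gene_id in sorted(proteins):
        protein = proteins[gene_id]
        if not protein:
            calls[gene_id] = DomainCall(gene_id, "other", None, 1.0)
            continue
        best_by_role: dict[str, tuple[float, str]] = {}  # role -> (log10e, ref)
        for ref_id in sorted(panel):
            role, ref_seq = panel[ref_id]
            score = align.raw_score(protein, ref_seq, params)
            le = align.log10_evalue(score, len(protein), n_db, params)
            if role not in best_by_role or le < best_by_role[role][0]:
                best_by_role[role] = (le, ref_id)
        c_le, c_ref = best_by_role.get("C", (math.inf, None))
        d_le, d_ref = best_by_role.get("D", (math.inf, None))
        cd_le, cd_ref = best_by_role.get("CD_fusion", (math.inf, None))
        # a CD fusion must carry BOTH domains (or match a bundled CD
        # reference outright); D-side plus weak C-side => truncated fusion
        if c_le <= max_le and d_le <= max_le:
            le, ref = min((cd_le, cd_ref), (c_le, c_ref), (d_le, d_ref))
            call = DomainCall(gene_id, "CD_fusion", ref, 10.0 ** max(le, -323.0))
        elif d_le <= max_le and c_le <= reduced_le:
            call = DomainCall(
                gene_id, "CD_fusion", d_ref, 10.0 ** max(d_le, -323.0), truncated=True
            )
        elif c_le <= max_le:
            call = DomainCall(gene_id, "C", c_ref, 10.0 ** max(c_le, -323.0))
        elif d_le <= max_le:
            call = DomainCall(gene_id, "D", d_ref, 10.0 ** max(d_le, -323.0))
        else:
            rest = [
                (le, _PRIORITY.get(role, len(ROLE_PRIORITY)), ref, role)
                for role, (le, ref) in best_by_role.items()
                if role not in ("C", "D", "CD_fusion") and le <= max_le
            ]
            if rest:
                le, _, ref, role = min(rest)
                call = DomainCall(gene_id, role, ref, 10.0 ** max(le, -323.0))
            else:
                call = DomainCall(gene_id, "other", None, 1.0)
        calls[gene_id] = call
    return calls


def call_roles(
    region: GenomicRegion,
    reference_panel: Mapping[str, tuple[str, str]] | None = None,
    evalue_cutoff: float = DEFAULT_ROLE_EVALUE,
    params: align.ScoringParams = align.DEFAULT_PARAMS,
) -> list[DomainCall]:
    """Role calls for every member gene of a region, in coordinate order."""
    calls = call_genes(region.proteins(), reference_panel, evalue_cutoff, params)
    return [calls[g.gene_id] for g in region.member_proteins]


def calls_from_domtbl(path, evalue_cutoff: float = DEFAULT_ROLE_EVALUE) -> dict[str, DomainCall]:
    """Adapter: HMMER domtblout rows -> role calls via model accession."""
    calls: dict[str, DomainCall] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            gene_id, accession, ev = f[0], f[4], float(f[6])
            role = ACCESSION_ROLES.get(accession.split(".")[0])
            if role is None or ev > evalue_cutoff:
                continue
            if gene_id not in calls or ev < calls[gene_id].evalue:
                calls[gene_id] = DomainCall(gene_id, role, accession, ev)
    return calls


# ---------------------------------------------------------------------------
# Bottromycin rule


def bottromycin_like(
    region: GenomicRegion,
    role_calls: Sequence[DomainCall],
    bottromycin_reference_regions: Sequence[GenomicRegion] = (),
    params: align.ScoringParams = align.DEFAULT_PARAMS,
    threshold: float = DEFAULT_THRESHOLD,
) -> bool:
    """True iff the region scores above the family threshold against a
    bottromycin reference region, or carries two D-role genes plus at
    least one radical-SAM call."""
    n_d = sum(1 for c in role_calls if c.role == "D")
    n_rsam = sum(1 for c in role_calls if c.role == "radical_SAM")
    if n_d >= 2 and n_rsam >= 1:
        return True
    for ref in bottromycin_reference_regions:
        if region_score(region, ref, params).total > threshold:
            return True
    return False


# ---------------------------------------------------------------------------
# Family-level classification


EVIDENCE_TYPES = ("has_C_or_CD", "has_precursor", "bottromycin_like")


@dataclass
class TOMMVerdict:
    family_id: str
    is_tomm: bool
    evidence: tuple[str, ...]
    region_evidence: dict[str, tuple[str, ...]] = field(default_factory=dict)


def classify(
    families,
    role_calls_by_region: Mapping[str, Sequence[DomainCall]],
    precursor_flags: Mapping[str, bool],
    bottromycin_flags: Mapping[str, bool] | None = None,
) -> list[TOMMVerdict]:
    """Apply the three evidence rules per region, then propagate: a family
    is a TOMM if any member region shows any evidence, and every member
    inherits the family verdict."""
    bottromycin_flags = bottromycin_flags or {}
    verdicts = []
    for family in families:
        family_evidence: set[str] = set()
        per_region: dict[str, tuple[str, ...]] = {}
        for rid in family.member_region_ids:
            ev = set()
            calls = role_calls_by_region.get(rid, ())
            if any(c.role in ("C", "CD_fusion") for c in calls):
                ev.add("has_C_or_CD")
            if precursor_flags.get(rid, False):
                ev.add("has_precursor")
            if bottromycin_flags.get(rid, False):
                ev.add("bottromycin_like")
            per_region[rid] = tuple(sorted(ev))
            family_evidence |= ev
        verdicts.append(
            TOMMVerdict(
                family_id=family.family_id,
                is_tomm=bool(family_evidence),
                evidence=tuple(sorted(family_evidence)),
                region_evidence=per_region,
            )
        )
    return verdicts


def write_calls_tsv(calls: Iterable[DomainCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\trole\treference\tevalue\ttruncated\n")
        for c in calls:
            ref = c.best_reference or "."
            fh.write(f"{c.gene_id}\t{c.role}\t{ref}\t{c.evalue:.3g}\t{int(c.truncated)}\n")


def write_verdicts_tsv(verdicts: Iterable[TOMMVerdict], path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tis_tomm\tevidence\n")
        for v in verdicts:
            ev = ",".join(v.evidence) if v.evidence else "."
            fh.write(f"{v.family_id}\t{int(v.is_tomm)}\t{ev}\n")
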
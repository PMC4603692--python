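"""Precursor-peptide detection.

Two detection routes over an anchor-centred region:

* method 1 — screen annotated genes: span < 450 bp and C-terminal-half
  Cys/Ser/Thr fraction >= 0.45 (inclusive);
* method 2 — six-frame ORF enumeration over the full region window:
  length < 150 aa (strict) and C-terminal-half fraction >= 0.65.

The C-terminal half of a length-L peptide is its final ``floor(L/2)``
residues.  Duplicates (identical peptide within a region) are removed,
keeping the first by coordinate; a six-frame hit coinciding exactly with a
method-1 gene is merged and recorded as method "both".
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .genome import GenomicRegion

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

DEFAULT_MIN_ORF_AA = 25
METHOD1_MAX_GENE_BP = 450
METHOD1_MIN_CST = 0.45
METHOD2_MAX_LEN_AA = 150
METHOD2_MIN_CST = 0.65


def cst_fraction(peptide: str, include_gly: bool = False) -> float:
    """Fraction of Cys/Ser/Thr in the final floor(L/2) residues."""
    if not peptide:
        raise ValueError("empty peptide")
    half = len(peptide) // 2
    if half == 0:
        return 0.0
    residues = "CSTG" if include_gly else "CST"
    tail = peptide[-half:]
    return sum(1 for a in tail if a in residues) / half


@dataclass
class PrecursorCandidate:
    region_id: str
    sequence: str
    start: int  # genome coordinates, half-open, stop codon included
    end: int
    strand: str
    frame: int
    method: str  # "1_annotated", "2_sixframe", or "both"
    gene_id: str | None = None

    @property
    def length_aa(self) -> int:
        return len(self.sequence)

    def cst(self, include_gly: bool = False) -> float:
        return cst_fraction(self.sequence, include_gly)


# ---------------------------------------------------------------------------
# Six-frame ORF enumeration


def _scan_frames(seq: str, min_len_aa: int, max_len_aa: int, all_starts: bool):
    """Yield (peptide, start, end, frame) for one strand of ``seq``
    (coordinates local, half-open, stop codon included)."""
    n = len(seq)
    for frame in range(3):
        starts: list[int] = []
        for ci in range((n - frame) // 3):
            pos = frame + 3 * ci
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                chosen = starts if all_starts else starts[:1]
                for s in chosen:
                    length = (pos - s) // 3
                    if min_len_aa <= length < max_len_aa:
                        peptide = str(Seq(seq[s:pos]).translate(table=11))
                        yield peptide, s, pos + 3, frame
                starts = []
            elif codon in START_CODONS:
                starts.append(pos)


def six_frame_orfs(
    dna: str,
    min_len_aa: int,
    max_len_aa: int,
    *,
    all_starts: bool = False,
) -> list[tuple[str, int, int, str, int]]:
    """Enumerate ORFs (start codon {ATG,GTG,TTG} to next in-frame stop) in
    all six frames.

    By default only the longest ORF per (frame, stop) — i.e. the earliest
    start since the previous stop — is reported; ``all_starts=True``
    enumerates every (start, stop) pair.  Unterminated ORFs (no in-frame
    stop) are not reported.  Returns ``(peptide, start, end, strand,
    frame)`` with half-open coordinates on the forward strand, stop codon
    included, sorted deterministically.
    """
    dna = dna.upper()
    out = []
    for peptide, s, e, frame in _scan_frames(dna, min_len_aa, max_len_aa, all_starts):
        out.append((peptide, s, e, "+", frame))
    rc = str(Seq(dna).reverse_complement())
    n = len(dna)
    for peptide, s, e, frame in _scan_frames(rc, min_len_aa, max_len_aa, all_starts):
        out.append((peptide, n - e, n - s, "-", frame))
    out.sort(key=lambda t: (t[1], t[2], t[3], t[4]))
    return out


# ---------------------------------------------------------------------------
# Detection methods


def method1_annotated(
    region: GenomicRegion,
    *,
    max_gene_bp: int = METHOD1_MAX_GENE_BP,
    min_cst: float = METHOD1_MIN_CST,
    include_gly: bool = False,
    exclude_gene_ids: Iterable[str] = (),
) -> list[PrecursorCandidate]:
    """Annotated genes < ``max_gene_bp`` (strict) with C-terminal-half
    C/S/T fraction >= ``min_cst`` (inclusive).  The anchor gene and any
    explicitly excluded genes (e.g. domain-called C/CD/B) are skipped."""
    excluded = set(exclude_gene_ids) | {region.anchor_gene_id}
    out = []
    for gene in region.member_proteins:  # already sorted by coordinate
        if gene.gene_id in excluded or not gene.protein:
            continue
        if gene.length_bp >= max_gene_bp:
            continue
        if cst_fraction(gene.protein, include_gly) < min_cst:
            continue
        if gene.strand == "+":
            frame = (gene.start - region.window_start) % 3
        else:
            frame = (region.window_end - gene.end) % 3
        out.append(
            PrecursorCandidate(
                region_id=region.region_id,
                sequence=gene.protein,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                frame=frame,
                method="1_annotated",
                gene_id=gene.gene_id,
            )
        )
    return out


def method2_sixframe(
    region: GenomicRegion,
    *,
    min_len_aa: int = DEFAULT_MIN_ORF_AA,
    max_len_aa: int = METHOD2_MAX_LEN_AA,
    min_cst: float = METHOD2_MIN_CST,
    include_gly: bool = False,
    all_starts: bool = False,
) -> list[PrecursorCandidate]:
    """Six-frame ORFs over the full region window (annotated + intergenic
    DNA) under the length/composition filters, deduplicated by peptide."""
    seen: set[str] = set()
    out = []
    for peptide, s, e, strand, frame in six_frame_orfs(
        region.dna, min_len_aa, max_len_aa, all_starts=all_starts
    ):
        if "*" in peptide:
            continue
        if cst_fraction(peptide, include_gly) < min_cst:
            continue
        if peptide in seen:
            continue
        seen.add(peptide)
        out.append(
            PrecursorCandidate(
                region_id=region.region_id,
                sequence=peptide,
                start=region.window_start + s,
                end=region.window_start + e,
                strand=strand,
                frame=frame,
                method="2_sixframe",
            )
        )
    return out


def merge_candidates(
    m1: Sequence[PrecursorCandidate], m2: Sequence[PrecursorCandidate]
) -> list[PrecursorCandidate]:
    """Union of the two methods; a six-frame hit identical in sequence and
    coordinates to a method-1 hit is merged with method "both"."""
    keyed = {(c.start, c.end, c.strand, c.sequence): c for c in m1}
    merged = list(m1)
    for cand in m2:
        key = (cand.start, cand.end, cand.strand, cand.sequence)
        if key in keyed:
            idx = merged.index(keyed[key])
            merged[idx] = replace(merged[idx], method="both")
        else:
            merged.append(cand)
    merged.sort(key=lambda c: (c.start, c.end, c.strand))
    return merged


def scan_all(
    regions: Sequence[GenomicRegion],
    *,
    min_orf_aa: int = DEFAULT_MIN_ORF_AA,
    max_gene_bp: int = METHOD1_MAX_GENE_BP,
    min_cst1: float = METHOD1_MIN_CST,
    max_len_aa: int = METHOD2_MAX_LEN_AA,
    min_cst2: float = METHOD2_MIN_CST,
    include_gly: bool = False,
    exclude_gene_ids: Iterable[str] = (),
) -> tuple[list[PrecursorCandidate], dict[str, bool]]:
    """Run both methods on every region; returns the merged candidate list
    and the per-region ``has_precursor`` flag."""
    excluded = set(exclude_gene_ids)
    candidates: list[PrecursorCandidate] = []
    flags: dict[str, bool] = {}
    for region in regions:
        m1 = method1_annotated(
            region,
            max_gene_bp=max_gene_bp,
            min_cst=min_cst1,
            include_gly=include_gly,
            exclude_gene_ids=excluded,
        )
        m2 = method2_sixframe(
            region,
            min_len_aa=min_orf_aa,
            max_len_aa=max_len_aa,
            min_cst=min_cst2,
            include_gly=include_gly,
        )
        merged = merge_candidates(m1, m2)
        candidates.extend(merged)
        flags[region.region_id] = bool(merged)
    return candidates, flags


def write_candidates_tsv(candidates: Iterable[PrecursorCandidate], path) -> None:
    """Candidate table (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write(
            "region_id\tmethod\tstart\tend\tstrand\tframe\tlength_aa\t"
            "cst_fraction\tsequence\n"
        )
        for c in candidates:
            fh.write(
                f"{c.region_id}\t{c.method}\t{c.start + 1}\t{c.end}\t{c.strand}\t"
                f"{c.frame}\t{c.length_aa}\t{c.cst():.4f}\t{c.sequence}\n"
            )
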
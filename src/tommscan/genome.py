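"""Genome/annotation I/O and anchor-centred neighborhood extraction.

Internal coordinates are 0-based half-open throughout; GFF3 I/O converts
to and from the format's 1-based inclusive convention.  GFF3 support is a
deliberately thin reader/writer for the CDS-feature subset this pipeline
emits and consumes (malformed lines are reported with their line number).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence
from urllib.parse import quote, unquote

from Bio import SeqIO
from Bio.Seq import Seq

from . import align

_DNA_ALPHABET = set("ACGTN")
DEFAULT_WINDOW = 10_000


@dataclass
class GenomeRecord:
    """A replicon: id + DNA sequence."""

    id: str
    sequence: str
    source: str = "tommscan"

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise ValueError(f"genome {self.id}: non-ACGTN characters {sorted(bad)}")

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass
class GeneAnnotation:
    """A located, stranded CDS with its protein translation.

    ``start``/``end`` are 0-based half-open on the forward strand; the span
    includes the stop codon when one is annotated.
    """

    gene_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    protein: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.gene_id}: bad span [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and self.end > start


def translate_cds(genome_sequence: str, start: int, end: int, strand: str) -> str:
    """Translate a CDS span with the bacterial code (table 11), stop stripped."""
    dna = Seq(genome_sequence[start:end])
    if strand == "-":
        dna = dna.reverse_complement()
    prot = str(dna.translate(table=11))
    return prot[:-1] if prot.endswith("*") else prot


# ---------------------------------------------------------------------------
# FASTA / GFF3 I/O


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(annotations: Iterable[GeneAnnotation], path) -> None:
    """Write CDS features (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ann in annotations:
            attrs = f"ID={quote(ann.gene_id)};product={quote(ann.product)}"
            fh.write(
                f"{ann.genome_id}\ttommscan\tCDS\t{ann.start + 1}\t{ann.end}\t.\t"
                f"{ann.strand}\t0\t{attrs}\n"
            )


def read_gff3(path) -> list[GeneAnnotation]:
    """Parse CDS features; coordinates converted to 0-based half-open.

    Raises ``ValueError`` naming the offending line number on malformed
    input.
    """
    out: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: malformed GFF3 line {lineno}: expected 9 columns")
            seqid, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype != "CDS":
                continue
            try:
                start_i = int(start)
                end_i = int(end)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed GFF3 line {lineno}: {exc}") from exc
            if strand not in "+-":
                raise ValueError(f"{path}: malformed GFF3 line {lineno}: bad strand {strand!r}")
            attr_map = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr_map[k] = unquote(v)
            gene_id = attr_map.get("ID")
            if not gene_id:
                raise ValueError(f"{path}: malformed GFF3 line {lineno}: missing ID attribute")
            out.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    genome_id=seqid,
                    start=start_i - 1,
                    end=end_i,
                    strand=strand,
                    product=attr_map.get("product", ""),
                )
            )
    return out


def read_genome_bundle(
    fasta_path, gff3_path, protein_fasta_path
) -> tuple[dict[str, GenomeRecord], list[GeneAnnotation]]:
    """Read genome FASTA + GFF3 + protein FASTA into linked records.

    Each CDS is linked to its protein by ID; a CDS whose ID is absent from
    the protein FASTA is translated on the fly (with a warning).
    """
    genomes = {
        gid: GenomeRecord(id=gid, sequence=seq) for gid, seq in read_fasta(fasta_path).items()
    }
    proteins = read_fasta(protein_fasta_path)
    annotations = read_gff3(gff3_path)
    for ann in annotations:
        if ann.genome_id not in genomes:
            raise ValueError(f"{ann.gene_id}: unknown genome {ann.genome_id}")
        genome = genomes[ann.genome_id]
        if ann.end > genome.length_bp:
            raise ValueError(f"{ann.gene_id}: span exceeds genome length")
        if ann.gene_id in proteins:
            ann.protein = proteins[ann.gene_id]
        else:
            warnings.warn(
                f"{ann.gene_id}: no protein FASTA entry, translating on the fly",
                stacklevel=2,
            )
            ann.protein = translate_cds(genome.sequence, ann.start, ann.end, ann.strand)
    return genomes, annotations


# ---------------------------------------------------------------------------
# Anchor calling


def find_anchors(
    annotations: Sequence[GeneAnnotation],
    d_references: Mapping[str, str],
    evalue_cutoff: float = 1e-10,
    params: align.ScoringParams = align.DEFAULT_PARAMS,
) -> list[GeneAnnotation]:
    """Genes whose best local-alignment e-value against any D reference
    passes the cutoff, ordered by (genome, coordinate)."""
    if not d_references:
        raise ValueError("d_references must be non-empty")
    import math

    n_db = sum(len(s) for s in d_references.values())
    max_le = math.log10(evalue_cutoff)
    anchors = []
    for ann in sorted(annotations, key=lambda a: (a.genome_id, a.start, a.gene_id)):
        if not ann.protein:
            continue
        for ref in d_references.values():
            score = align.raw_score(ann.protein, ref, params)
            if align.log10_evalue(score, len(ann.protein), n_db, params) <= max_le:
                anchors.append(ann)
                break
    return anchors


def anchors_from_tsv(path, annotations: Sequence[GeneAnnotation]) -> list[GeneAnnotation]:
    """Adapter: (genome_id, gene_id) TSV listing anchor genes directly."""
    wanted = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            wanted.add((parts[0], parts[1]))
    return [a for a in annotations if (a.genome_id, a.gene_id) in wanted]


def anchors_from_domtbl(
    path, annotations: Sequence[GeneAnnotation], evalue_cutoff: float = 1e-10
) -> list[GeneAnnotation]:
    """Adapter: HMMER domtblout-style tabular file; listed targets become
    anchors (full-sequence e-value column 7 filtered at the cutoff)."""
    hits = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if float(fields[6]) <= evalue_cutoff:
                hits.add(fields[0])
    return [a for a in annotations if a.gene_id in hits]


# ---------------------------------------------------------------------------
# Region extraction


@dataclass
class GenomicRegion:
    """An anchor-centred window with member proteins and intergenic DNA."""

    region_id: str
    genome_id: str
    anchor_gene_id: str
    window_start: int
    window_end: int
    member_proteins: list[GeneAnnotation]
    intergenic_segments: list[tuple[int, int]]
    dna: str
    nearby_anchor_ids: list[str] = field(default_factory=list)

    @property
    def gene_order(self) -> list[str]:
        return [g.gene_id for g in self.member_proteins]

    def proteins(self) -> dict[str, str]:
        return {g.gene_id: g.protein for g in self.member_proteins}


def _intergenic(window_start: int, window_end: int, members: Sequence[GeneAnnotation]):
    """Window minus CDS spans (clipped to the window), sorted, non-overlapping."""
    segments = []
    pos = window_start
    bounds = sorted((max(g.start, window_start), min(g.end, window_end)) for g in members)
    for s, e in bounds:
        if s > pos:
            segments.append((pos, s))
        pos = max(pos, e)
    if pos < window_end:
        segments.append((pos, window_end))
    return segments


def extract_region(
    genome: GenomeRecord,
    annotations: Sequence[GeneAnnotation],
    anchor: GeneAnnotation,
    window: int = DEFAULT_WINDOW,
    region_id: str | None = None,
) -> GenomicRegion:
    """±``window`` bp neighborhood around an anchor gene.

    The window is clamped to the contig; genes partially overlapping the
    window boundary are included whole (translations are never clipped).
    """
    if anchor not in annotations:
        raise ValueError(f"anchor {anchor.gene_id} not among annotations")
    window_start = max(0, anchor.start - window)
    window_end = min(genome.length_bp, anchor.end + window)
    members = sorted(
        (g for g in annotations if g.genome_id == genome.id and g.overlaps(window_start, window_end)),
        key=lambda g: (g.start, g.gene_id),
    )
    return GenomicRegion(
        region_id=region_id or f"{genome.id}:{anchor.gene_id}",
        genome_id=genome.id,
        anchor_gene_id=anchor.gene_id,
        window_start=window_start,
        window_end=window_end,
        member_proteins=members,
        intergenic_segments=_intergenic(window_start, window_end, members),
        dna=genome.sequence[window_start:window_end],
    )


def extract_all_regions(
    genomes: Mapping[str, GenomeRecord],
    annotations: Sequence[GeneAnnotation],
    anchors: Sequence[GeneAnnotation],
    window: int = DEFAULT_WINDOW,
) -> list[GenomicRegion]:
    """One region per anchor (overlapping tandem-anchor regions are kept
    separate; adjacency within the window is recorded)."""
    regions = []
    for anchor in anchors:
        region = extract_region(genomes[anchor.genome_id], annotations, anchor, window)
        region.nearby_anchor_ids = [
            a.gene_id
            for a in anchors
            if a.genome_id == anchor.genome_id
            and a.gene_id != anchor.gene_id
            and a.overlaps(region.window_start, region.window_end)
        ]
        regions.append(region)
    return regions
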
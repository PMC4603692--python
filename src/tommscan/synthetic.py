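"""Ground-truthed synthetic genomes with planted TOMM-like clusters.

Archetypes mirror the documented cluster architectures: discrete C+D,
fused CD, fused CD with an F protein, stand-alone-D bottromycin-like, and
a decoy non-TOMM YcaO context.  Precursor genes can be annotated, present
but unannotated (intergenic), absent, or planted >10 kb away ("distal")
to exercise the documented false-negative mode.

Determinism: every random draw flows through one ``numpy.random.Generator``
seeded by the caller, and back-translation uses a fixed codon per residue,
so identical (config, seed) produces byte-identical outputs.

Filler DNA is drawn over {A, T} only — there is no G, hence no ATG/GTG/TTG
start codon on either strand — and a ``TAATTAATTAAT`` block is stamped
every 120 bp so all six frames see an in-frame stop at least every 150
codons.  Six-frame ORF scans of filler therefore yield nothing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome import GeneAnnotation, GenomeRecord, write_fasta, write_gff3
from .seeds import AMINO_ACIDS, SEEDS

# fixed codon per residue (bacterial table 11); codons are chosen so that no
# codon's reverse complement encodes Cys/Ser/Thr, otherwise reverse-strand
# reading frames of ordinary genes would be systematically C/S/T-enriched
# and spawn spurious six-frame precursor candidates (e.g. GCA(Ala) -> TGC(Cys))
CODON_OF = {
    "A": "GCG", "R": "CGC", "N": "AAC", "D": "GAT", "C": "TGC",
    "Q": "CAG", "E": "GAA", "G": "GGC", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCG",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAT", "V": "GTT",
}
STOP_CODON = "TAA"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

LEADER_ALPHABET = "ADEFGHIKLNPQRVWY"  # no C/S/T (and no M, avoiding nested starts)
CST = "CST"


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def back_translate(protein: str) -> str:
    """Deterministic back-translation; appends a TAA stop codon."""
    return "".join(CODON_OF[a] for a in protein) + STOP_CODON


# ---------------------------------------------------------------------------
# Archetype plans


@dataclass(frozen=True)
class GenePlan:
    role: str  # C, D, CD_fusion, B, F, radical_SAM, transporter, protease,
    #            methyltransferase, other, precursor
    seed_key: str | None
    strand: str = "+"


@dataclass(frozen=True)
class PrecursorParams:
    leader_length_aa: int = 20
    core_length_aa: int = 26
    target_cst_fraction: float = 0.5
    gly_linker_length: int = 4

    def __post_init__(self) -> None:
        if self.leader_length_aa <= 0 or self.core_length_aa <= 0:
            raise ValueError("precursor lengths must be positive")
        if not 0.0 <= self.target_cst_fraction <= 1.0:
            raise ValueError("target_cst_fraction must be in [0, 1]")


PLACEMENTS = ("annotated", "unannotated_intergenic", "absent", "distal")


@dataclass(frozen=True)
class ClusterArchetype:
    """A planted cluster blueprint: ordered gene plan + precursor plan."""

    name: str
    gene_plan: tuple[GenePlan, ...]
    precursor_plan: str = "absent"
    precursor_params: PrecursorParams | None = None
    is_tomm: bool = True

    def __post_init__(self) -> None:
        if self.precursor_plan not in PLACEMENTS:
            raise ValueError(f"unknown precursor_plan {self.precursor_plan!r}")
        n_d = sum(1 for g in self.gene_plan if g.role in ("D", "CD_fusion"))
        if self.is_tomm:
            expected = 2 if self.name.startswith("standalone_D") else 1
            if n_d != expected:
                raise ValueError(f"{self.name}: expected {expected} D-domain genes, got {n_d}")
        else:
            if n_d != 1:
                raise ValueError(f"{self.name}: decoy needs exactly one D gene")
            if any(g.role in ("C", "CD_fusion", "precursor") for g in self.gene_plan):
                raise ValueError(f"{self.name}: decoy must not carry C/CD/precursor")
        if self.precursor_plan != "absent" and self.precursor_params is None:
            raise ValueError(f"{self.name}: precursor_params required")

    @property
    def n_genes(self) -> int:
        return sum(1 for g in self.gene_plan if g.role != "precursor")


def _plan(*entries: tuple[str, str | None, str]) -> tuple[GenePlan, ...]:
    return tuple(GenePlan(role=r, seed_key=k, strand=s) for r, k, s in entries)


def default_archetypes() -> dict[str, ClusterArchetype]:
    """The five bundled architectures (Cys/Ser/Thr-rich precursors except
    for the bottromycin-like plan, whose precursor is deliberately poor in
    heterocyclizable residues)."""
    arch = {}
    arch["discrete_CD"] = ClusterArchetype(
        name="discrete_CD",
        gene_plan=_plan(
            ("transporter", "transporter_A1", "+"),
            ("transporter", "transporter_A2", "+"),
            ("protease", "protease_A", "+"),
            ("B", "B", "+"),
            ("C", "C_A", "+"),
            ("D", "D_A", "+"),
            ("precursor", None, "+"),
            ("methyltransferase", "methyltransferase_A", "-"),
            ("other", "hypothetical_A1", "+"),
            ("other", "hypothetical_A2", "-"),
            ("other", "regulator_A", "+"),
            ("other", "hypothetical_A3", "+"),
            ("other", "hypothetical_A4", "+"),
            ("other", "hypothetical_A5", "+"),
        ),
        precursor_plan="annotated",
        precursor_params=PrecursorParams(target_cst_fraction=0.5),
    )
    arch["fused_CD"] = ClusterArchetype(
        name="fused_CD",
        gene_plan=_plan(
            ("CD_fusion", "CD_B", "+"),
            ("precursor", None, "+"),
            ("B", "B", "+"),
            ("protease", "protease_B", "+"),
            ("transporter", "transporter_B1", "-"),
            ("transporter", "transporter_B2", "-"),
            ("methyltransferase", "methyltransferase_B", "+"),
            ("other", "regulator_B", "+"),
            ("other", "hypothetical_B1", "+"),
            ("other", "hypothetical_B2", "-"),
            ("other", "hypothetical_B3", "+"),
            ("other", "hypothetical_B4", "+"),
            ("other", "hypothetical_B5", "+"),
            ("other", "hypothetical_B6", "+"),
        ),
        precursor_plan="unannotated_intergenic",
        precursor_params=PrecursorParams(target_cst_fraction=0.7),
    )
    arch["fused_CD_with_F"] = ClusterArchetype(
        name="fused_CD_with_F",
        gene_plan=_plan(
            ("CD_fusion", "CD_C", "+"),
            ("F", "F", "+"),
            ("B", "B", "+"),
            ("methyltransferase", "methyltransferase_C", "+"),
            ("transporter", "transporter_C1", "+"),
            ("transporter", "transporter_C2", "-"),
            ("protease", "protease_C", "+"),
            ("other", "regulator_C", "+"),
            ("other", "hypothetical_C1", "+"),
            ("other", "hypothetical_C2", "+"),
            ("other", "hypothetical_C3", "-"),
            ("other", "hypothetical_C4", "+"),
            ("other", "hypothetical_C5", "+"),
        ),
        precursor_plan="distal",
        precursor_params=PrecursorParams(target_cst_fraction=0.7),
    )
    arch["standalone_D_bottromycin"] = ClusterArchetype(
        name="standalone_D_bottromycin",
        gene_plan=_plan(
            ("D", "D_D", "+"),
            ("D", "D_D", "+"),
            ("radical_SAM", "radical_SAM", "+"),
            ("radical_SAM", "radical_SAM", "+"),
            ("methyltransferase", "methyltransferase_D", "+"),
            ("protease", "protease_D", "-"),
            ("transporter", "transporter_D1", "-"),
            ("transporter", "transporter_D2", "-"),
            ("other", "regulator_D", "+"),
            ("precursor", None, "+"),
            ("other", "hypothetical_D1", "+"),
            ("other", "hypothetical_D2", "+"),
            ("other", "hypothetical_D3", "+"),
            ("other", "hypothetical_D4", "+"),
        ),
        precursor_plan="annotated",
        precursor_params=PrecursorParams(target_cst_fraction=0.1),
    )
    arch["decoy_nonTOMM"] = ClusterArchetype(
        name="decoy_nonTOMM",
        gene_plan=_plan(
            ("D", "D_E", "+"),
            ("other", "hypothetical_E1", "+"),
            ("transporter", "transporter_E1", "-"),
            ("protease", "protease_E", "+"),
            ("other", "hypothetical_E2", "+"),
        ),
        is_tomm=False,
    )
    return arch


# ---------------------------------------------------------------------------
# Sequence-level operations


def mutate_protein(seed_seq: str, target_identity: float, rng: np.random.Generator) -> str:
    """Substitute uniformly chosen positions so that exactly
    ``round(target_identity * len)`` positions match the seed."""
    if not seed_seq:
        raise ValueError("seed_seq must be non-empty")
    if not 0.0 < target_identity <= 1.0:
        raise ValueError("target_identity must be in (0, 1]")
    bad = set(seed_seq) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"non-standard residues {sorted(bad)}")
    n = len(seed_seq)
    n_keep = round(target_identity * n)
    n_mut = n - n_keep
    if n_mut == 0:
        return seed_seq
    positions = rng.choice(n, size=n_mut, replace=False)
    out = list(seed_seq)
    for pos in sorted(positions):
        choices = [a for a in AMINO_ACIDS if a != out[pos]]
        out[pos] = choices[rng.integers(len(choices))]
    return "".join(out)


def sample_precursor(
    leader_length: int,
    core_length: int,
    target_cst_fraction: float,
    gly_linker: int,
    rng: np.random.Generator,
) -> str:
    """leader + poly-Gly linker + core, with the C-terminal half of the full
    peptide carrying at least ``target_cst_fraction`` Cys/Ser/Thr.

    The required heterocyclizable residues are placed at the very C-terminus
    (inside the core); remaining core positions and the whole leader use a
    C/S/T-free alphabet, so a target of 0 yields a C/S/T-free C-terminal half.
    """
    if leader_length <= 0 or core_length <= 0 or gly_linker < 0:
        raise ValueError("lengths must be positive (linker >= 0)")
    if not 0.0 <= target_cst_fraction <= 1.0:
        raise ValueError("target_cst_fraction must be in [0, 1]")
    total = leader_length + gly_linker + core_length
    half = total // 2
    required = math.ceil(target_cst_fraction * half)
    if required > min(core_length, half):
        raise ValueError(
            f"core of {core_length} aa cannot satisfy {target_cst_fraction:.2f} "
            f"C/S/T over a {half}-residue C-terminal half"
        )
    leader = "M" + "".join(rng.choice(list(LEADER_ALPHABET), size=leader_length - 1))
    n_plain = core_length - required
    core_plain = "".join(rng.choice(list(LEADER_ALPHABET), size=n_plain))
    core_cst = "".join(rng.choice(list(CST), size=required))
    return leader + "G" * gly_linker + core_plain + core_cst


def make_filler(length: int, rng: np.random.Generator) -> str:
    """Start-codon-free, stop-saturated spacer DNA (see module docstring)."""
    if length <= 0:
        return ""
    stamp = "TAATTAATTAAT"  # in-frame stops in all six frames
    if length < len(stamp):
        return ("TAAT" * 4)[:length]
    chars = rng.choice(["A", "T"], size=length)
    filler = list("".join(chars))
    for offset in range(0, length - len(stamp) + 1, 120):
        filler[offset : offset + len(stamp)] = stamp
    filler[length - len(stamp) :] = stamp
    return "".join(filler)


# ---------------------------------------------------------------------------
# Truth table


@dataclass
class PlantedGene:
    genome_id: str
    cluster_id: str
    gene_id: str
    role: str
    archetype: str
    start: int
    end: int
    strand: str


@dataclass
class PlantedPrecursor:
    genome_id: str
    cluster_id: str
    archetype: str
    placement: str
    start: int
    end: int
    strand: str
    sequence: str
    expected_detection_method: str  # "1", "2", or "none"


@dataclass
class PlantedCluster:
    genome_id: str
    cluster_id: str
    archetype: str
    is_tomm: bool
    start: int
    end: int
    anchor_gene_ids: list[str]


@dataclass
class TruthTable:
    clusters: list[PlantedCluster] = field(default_factory=list)
    genes: list[PlantedGene] = field(default_factory=list)
    precursors: list[PlantedPrecursor] = field(default_factory=list)

    def validate(self, genomes: dict[str, GenomeRecord]) -> None:
        seen: set[tuple] = set()
        for g in self.genes:
            key = (g.genome_id, g.gene_id)
            if key in seen:
                raise ValueError(f"duplicate planted gene {key}")
            seen.add(key)
            if not (0 <= g.start < g.end <= genomes[g.genome_id].length_bp):
                raise ValueError(f"gene {g.gene_id} outside genome")
        for p in self.precursors:
            if not (0 <= p.start < p.end <= genomes[p.genome_id].length_bp):
                raise ValueError("precursor outside genome")

    def to_json(self) -> str:
        from dataclasses import asdict

        payload = {
            "clusters": [asdict(c) for c in self.clusters],
            "genes": [asdict(g) for g in self.genes],
            "precursors": [asdict(p) for p in self.precursors],
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def write(self, json_path, tsv_path) -> None:
        Path(json_path).write_text(self.to_json() + "\n")
        with open(tsv_path, "w") as fh:
            fh.write(
                "genome_id\tcluster_id\telement\tid\trole\tarchetype\tstart\tend\t"
                "strand\tis_tomm\texpected_detection_method\n"
            )
            for c in self.clusters:
                fh.write(
                    f"{c.genome_id}\t{c.cluster_id}\tcluster\t{c.cluster_id}\t.\t"
                    f"{c.archetype}\t{c.start}\t{c.end}\t.\t{int(c.is_tomm)}\t.\n"
                )
            for g in self.genes:
                fh.write(
                    f"{g.genome_id}\t{g.cluster_id}\tgene\t{g.gene_id}\t{g.role}\t"
                    f"{g.archetype}\t{g.start}\t{g.end}\t{g.strand}\t.\t.\n"
                )
            for p in self.precursors:
                fh.write(
                    f"{p.genome_id}\t{p.cluster_id}\tprecursor\t{p.cluster_id}_pre\t"
                    f"precursor\t{p.archetype}\t{p.start}\t{p.end}\t{p.strand}\t.\t"
                    f"{p.expected_detection_method}\n"
                )


# ---------------------------------------------------------------------------
# Genome assembly


def _expected_method(placement: str, peptide: str, min_orf_aa: int = 25) -> str:
    from .precursors import cst_fraction

    frac = cst_fraction(peptide)
    if placement == "annotated":
        gene_bp = 3 * (len(peptide) + 1)
        if gene_bp < 450 and frac >= 0.45:
            return "1"
        return "none"
    if placement == "unannotated_intergenic":
        if len(peptide) < 150 and len(peptide) >= min_orf_aa and frac >= 0.65:
            return "2"
        return "none"
    return "none"  # absent / distal (>10 kb false-negative mode)


def generate_genome(
    archetypes: Sequence[ClusterArchetype],
    spacing_bp: int,
    rng: np.random.Generator,
    *,
    genome_id: str = "synth1",
    identity: float = 0.85,
    intergap_bp: tuple[int, int] = (60, 150),
) -> tuple[GenomeRecord, list[GeneAnnotation], dict[str, str], TruthTable]:
    """Lay archetype instances end to end with filler spacing.

    Each listed archetype becomes one planted cluster whose proteins are
    fresh mutants (at ``identity``) of the archetype's seed sequences.
    Distal precursors are appended in a tail at least 12 kb past the last
    cluster and from each other.
    """
    if not archetypes:
        raise ValueError("archetype list must be non-empty")
    if spacing_bp < 0:
        raise ValueError("spacing_bp must be >= 0")
    parts: list[str] = []
    cursor = 0

    def emit(dna: str) -> tuple[int, int]:
        nonlocal cursor
        start = cursor
        parts.append(dna)
        cursor += len(dna)
        return start, cursor

    def gap() -> None:
        emit(make_filler(int(rng.integers(intergap_bp[0], intergap_bp[1] + 1)), rng))

    annotations: list[GeneAnnotation] = []
    proteins: dict[str, str] = {}
    truth = TruthTable()
    distal_queue: list[tuple[str, str, str]] = []  # (cluster_id, archetype, peptide)

    emit(make_filler(spacing_bp, rng))
    for idx, arch in enumerate(archetypes):
        cluster_id = f"cl{idx:03d}"
        cluster_start = cursor
        anchor_ids: list[str] = []
        gene_no = 0
        for plan in arch.gene_plan:
            gap()
            if plan.role == "precursor":
                pp = arch.precursor_params
                peptide = sample_precursor(
                    pp.leader_length_aa,
                    pp.core_length_aa,
                    pp.target_cst_fraction,
                    pp.gly_linker_length,
                    rng,
                )
                dna = back_translate(peptide)
                if plan.strand == "-":
                    dna = reverse_complement(dna)
                start, end = emit(dna)
                if arch.precursor_plan == "annotated":
                    gene_id = f"{genome_id}_{cluster_id}_pre"
                    annotations.append(
                        GeneAnnotation(
                            gene_id=gene_id,
                            genome_id=genome_id,
                            start=start,
                            end=end,
                            strand=plan.strand,
                            product="precursor peptide",
                            protein=peptide,
                        )
                    )
                    proteins[gene_id] = peptide
                    truth.genes.append(
                        PlantedGene(
                            genome_id, cluster_id, gene_id, "precursor", arch.name,
                            start, end, plan.strand,
                        )
                    )
                truth.precursors.append(
                    PlantedPrecursor(
                        genome_id, cluster_id, arch.name, arch.precursor_plan,
                        start, end, plan.strand, peptide,
                        _expected_method(arch.precursor_plan, peptide),
                    )
                )
                continue
            protein = mutate_protein(SEEDS[plan.seed_key], identity, rng)
            dna = back_translate(protein)
            if plan.strand == "-":
                dna = reverse_complement(dna)
            start, end = emit(dna)
            gene_id = f"{genome_id}_{cluster_id}_g{gene_no:02d}"
            gene_no += 1
            annotations.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    genome_id=genome_id,
                    start=start,
                    end=end,
                    strand=plan.strand,
                    product=plan.role,
                    protein=protein,
                )
            )
            proteins[gene_id] = protein
            truth.genes.append(
                PlantedGene(
                    genome_id, cluster_id, gene_id, plan.role, arch.name,
                    start, end, plan.strand,
                )
            )
            if plan.role in ("D", "CD_fusion"):
                anchor_ids.append(gene_id)
        if arch.precursor_plan == "distal":
            pp = arch.precursor_params
            peptide = sample_precursor(
                pp.leader_length_aa,
                pp.core_length_aa,
                pp.target_cst_fraction,
                pp.gly_linker_length,
                rng,
            )
            distal_queue.append((cluster_id, arch.name, peptide))
        gap()
        truth.clusters.append(
            PlantedCluster(
                genome_id, cluster_id, arch.name, arch.is_tomm,
                cluster_start, cursor, anchor_ids,
            )
        )
        emit(make_filler(spacing_bp, rng))
    # distal precursors: in DNA, >10 kb from every anchor window
    for cluster_id, arch_name, peptide in distal_queue:
        emit(make_filler(max(spacing_bp, 12_000), rng))
        dna = back_translate(peptide)
        start, end = emit(dna)
        truth.precursors.append(
            PlantedPrecursor(
                genome_id, cluster_id, arch_name, "distal", start, end, "+",
                peptide, "none",
            )
        )
    emit(make_filler(max(spacing_bp, 1_000), rng))

    genome = GenomeRecord(id=genome_id, sequence="".join(parts))
    # layout is sequential by construction; verify anyway
    spans = sorted((g.start, g.end) for g in truth.genes)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError("overlapping planted elements")
    truth.validate({genome_id: genome})
    return genome, annotations, proteins, truth


def write_bundle(
    outdir,
    genome: GenomeRecord,
    annotations: Sequence[GeneAnnotation],
    proteins: dict[str, str],
    truth: TruthTable,
) -> dict[str, Path]:
    """Write genome FASTA, GFF3, protein FASTA and TruthTable (TSV + JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fna",
        "gff3": outdir / "genome.gff3",
        "proteins": outdir / "proteins.faa",
        "truth_json": outdir / "truth.json",
        "truth_tsv": outdir / "truth.tsv",
    }
    write_fasta({genome.id: genome.sequence}, paths["fasta"])
    write_gff3(annotations, paths["gff3"])
    write_fasta(proteins, paths["proteins"])
    truth.write(paths["truth_json"], paths["truth_tsv"])
    return paths
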
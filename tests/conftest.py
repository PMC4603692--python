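import numpy as np
import pytest

from tommscan import synthetic
from tommscan.genome import GeneAnnotation, GenomicRegion
from tommscan.pipeline import run_pipeline

ARCH_ORDER = (
    "discrete_CD",
    "fused_CD",
    "fused_CD_with_F",
    "standalone_D_bottromycin",
    "decoy_nonTOMM",
)


def _plan(counts: dict[str, int]):
    arch = synthetic.default_archetypes()
    plan = []
    for name in ARCH_ORDER:
        plan.extend([arch[name]] * counts.get(name, 0))
    return plan


@pytest.fixture(scope="session")
def small_bundle():
    """One cluster per archetype, seed 1."""
    rng = np.random.default_rng(1)
    plan = _plan({name: 1 for name in ARCH_ORDER})
    return synthetic.generate_genome(plan, 15_000, rng)


@pytest.fixture(scope="session")
def e2e_bundle():
    """Multi-instance genome used for end-to-end classification checks."""
    rng = np.random.default_rng(7)
    plan = _plan(
        {
            "discrete_CD": 3,
            "fused_CD": 3,
            "fused_CD_with_F": 3,
            "standalone_D_bottromycin": 2,
            "decoy_nonTOMM": 3,
        }
    )
    return synthetic.generate_genome(plan, 15_000, rng)


@pytest.fixture(scope="session")
def e2e_result(e2e_bundle):
    genome, annotations, _, _ = e2e_bundle
    return run_pipeline({genome.id: genome}, annotations)


def make_region(
    proteins,
    region_id="rg",
    genome_id="gtest",
    gene_span=300,
    dna="",
):
    """Build a GenomicRegion from (gene_id, protein, strand) triples laid
    out left to right (coordinates are synthetic but consistent)."""
    members = []
    pos = 0
    for gene_id, protein, strand in proteins:
        members.append(
            GeneAnnotation(
                gene_id=gene_id,
                genome_id=genome_id,
                start=pos,
                end=pos + gene_span,
                strand=strand,
                protein=protein,
            )
        )
        pos += gene_span + 50
    window_end = max(pos, len(dna))
    return GenomicRegion(
        region_id=region_id,
        genome_id=genome_id,
        anchor_gene_id=members[0].gene_id if members else "none",
        window_start=0,
        window_end=window_end,
        member_proteins=members,
        intergenic_segments=[],
        dna=dna,
    )


def make_dna_region(dna, region_id="rdna", anchor="none"):
    """A region that is pure DNA (no annotated members) for ORF scanning."""
    return GenomicRegion(
        region_id=region_id,
        genome_id="gtest",
        anchor_gene_id=anchor,
        window_start=0,
        window_end=len(dna),
        member_proteins=[],
        intergenic_segments=[(0, len(dna))],
        dna=dna,
    )


def random_protein(rng, length):
    from tommscan.seeds import AMINO_ACIDS

    return "M" + "".join(rng.choice(list(AMINO_ACIDS), size=length - 1))
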
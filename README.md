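# tommscan

Genome mining for **thiazole/oxazole-modified microcin (TOMM)** biosynthetic
gene clusters: from annotated genomes to classified cluster families and
protein similarity networks, with a ground-truthed synthetic-genome
generator so the whole pipeline is testable offline.

## What it does

1. **Anchor detection** — find YcaO/D-protein genes by local-alignment
   similarity to bundled reference sequences (or take an anchor list /
   HMMER domtblout file).
2. **Region extraction** — cut a ±10 kb neighborhood around each anchor,
   keeping member proteins whole and tracking intergenic DNA.
3. **Precursor finding** — two routes: annotated genes < 450 bp whose
   C-terminal half is ≥ 45 % Cys/Ser/Thr, and six-frame ORFs < 150 aa with
   a ≥ 65 % C/S/T C-terminal half; duplicates merged.
4. **Family grouping** — pairwise region scores
   `0.5·(one-to-one homology hits, identity ≥ 30 %, coverage ≥ 25, ≤ 100
   mapped) + 0.5·(conserved adjacencies, inversion-tolerant)`; single-linkage
   families at score > 10.
5. **Classification** — a family is a TOMM if any member region has a
   C/CD-fusion protein, a precursor candidate, or looks bottromycin-like
   (two stand-alone D proteins + radical-SAM, or similarity to a
   bottromycin reference region); verdicts propagate family-wide.
6. **Similarity networks** — D-protein network at e ≤ 1e-54 and
   all-protein network at e ≤ 1e-30, with 100 %-identity node collapsing,
   small-component removal and GraphML export.
7. **Reporting** — per-family tables, cleavage-site estimation (last
   Gly/Ala in a mid-peptide zone) and C-terminus-anchored position
   frequency matrices for precursor cores.

Pairwise comparison is a self-contained Smith–Waterman engine
(BLOSUM62, affine gaps 11/1, numba-compiled) with Karlin–Altschul
e-values (λ = 0.267, K = 0.041 by default, configurable); an adapter
ingests precomputed BLAST `-outfmt 6` tables instead.

The `synthetic` module plants clusters of five architectures — discrete
C+D, fused CD, fused CD+F, stand-alone-D bottromycin-like, and a decoy
non-TOMM YcaO context — with annotated, unannotated-intergenic, absent or
distal (> 10 kb) precursor genes, and emits FASTA/GFF3/protein FASTA plus
a truth table (TSV + JSON) for verification.

## CLI

```bash
# generate a seeded synthetic genome bundle with ground truth
tommscan simulate --seed 1 --out sim/

# run the whole pipeline on any genome bundle
tommscan run-all --fasta sim/genome.fna --gff sim/genome.gff3 \
    --proteins sim/proteins.faa --out results/

# individual stages
tommscan extract         --fasta ... --gff ... --proteins ... --out regions/
tommscan find-precursors --fasta ... --gff ... --proteins ... --out cands.tsv
tommscan cluster         --fasta ... --gff ... --proteins ... --threshold 10 --out fams/
tommscan ssn             --fasta ... --gff ... --proteins ... --subset d-only --out net/
```

All thresholds (450 bp / 45 %, 150 aa / 65 %, identity 30 / coverage 25,
family score 10, network e-values) are exposed as flags with the defaults
above.

## Layout

```
src/tommscan/
  synthetic.py   # ground-truthed genome generator (archetypes, truth table)
  genome.py      # FASTA/GFF3 I/O, anchor calling, region extraction
  precursors.py  # composition filters + six-frame ORF enumeration
  align.py       # Smith–Waterman engine, e-values, all-vs-all
  grouping.py    # homology+synteny region scores, family grouping
  classify.py    # role calling, bottromycin rule, TOMM verdicts
  ssn.py         # similarity networks
  report.py      # PFMs, cleavage estimation, family tables
  pipeline.py    # orchestration; cli.py  # click CLI
```
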
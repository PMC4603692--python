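"""Pipeline summaries: cleavage-site estimation, precursor core
position-frequency matrices (C-terminus-anchored), per-family tables and
run manifests."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .classify import DomainCall, TOMMVerdict
from .grouping import FamilyAssignment
from .precursors import PrecursorCandidate, cst_fraction
from .seeds import AMINO_ACIDS

GAP = "-"
DEFAULT_CLEAVAGE_ZONE = (0.35, 0.65)

CORE_ROLE_ORDER = ["C", "CD_fusion", "D", "B", "F", "radical_SAM"]
_ROLE_SHORT = {"CD_fusion": "CD", "radical_SAM": "rSAM"}


def estimate_cleavage(
    precursor: str, zone: tuple[float, float] = DEFAULT_CLEAVAGE_ZONE
) -> int:
    """Estimated core start: position after the last Gly/Ala in the leader
    search zone (fractions of peptide length); midpoint if none found."""
    if len(precursor) < 10:
        raise ValueError("precursor too short for cleavage estimation")
    lo = int(zone[0] * len(precursor))
    hi = int(zone[1] * len(precursor))
    for i in range(hi, lo - 1, -1):
        if i < len(precursor) and precursor[i] in "GA":
            return i + 1
    return len(precursor) // 2


@dataclass
class PositionFrequencyMatrix:
    columns: list[dict[str, float]]  # per-position residue -> frequency
    gap_fractions: list[float]
    n_sequences: int
    source_family: str | None = None

    @property
    def length(self) -> int:
        return len(self.columns)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_sequences": self.n_sequences,
                "source_family": self.source_family,
                "columns": self.columns,
                "gap_fractions": self.gap_fractions,
            },
            indent=2,
            sort_keys=True,
        )

    def write_jaspar(self, path) -> None:
        """JASPAR-style tab-delimited matrix: one row per residue."""
        with open(path, "w") as fh:
            name = self.source_family or "pfm"
            fh.write(f">{name}\t{self.n_sequences} sequences\n")
            for aa in AMINO_ACIDS:
                vals = "\t".join(f"{col.get(aa, 0.0):.4f}" for col in self.columns)
                fh.write(f"{aa}\t{vals}\n")


def build_pfm(
    cores: Sequence[str], source_family: str | None = None
) -> PositionFrequencyMatrix:
    """Column frequencies of right-aligned (C-terminus-anchored) cores.

    Shorter cores are left-padded with gaps; gaps are tracked separately
    and excluded from the residue simplex, so every column with at least
    one residue sums to 1.
    """
    if not cores:
        raise ValueError("need at least one core")
    width = max(len(c) for c in cores)
    padded = [GAP * (width - len(c)) + c for c in cores]
    columns: list[dict[str, float]] = []
    gap_fractions: list[float] = []
    for j in range(width):
        col = [p[j] for p in padded]
        residues = [a for a in col if a != GAP]
        gap_fractions.append((len(col) - len(residues)) / len(col))
        counts: dict[str, float] = {}
        for a in residues:
            counts[a] = counts.get(a, 0.0) + 1.0
        total = sum(counts.values())
        columns.append({a: v / total for a, v in sorted(counts.items())} if total else {})
    return PositionFrequencyMatrix(
        columns=columns,
        gap_fractions=gap_fractions,
        n_sequences=len(cores),
        source_family=source_family,
    )


def precursor_cores(candidates: Iterable[PrecursorCandidate]) -> list[str]:
    return [c.sequence[estimate_cleavage(c.sequence) :] for c in candidates]


def _role_inventory(calls: Iterable[DomainCall]) -> str:
    present = {c.role for c in calls}
    parts = [_ROLE_SHORT.get(r, r) for r in CORE_ROLE_ORDER if r in present]
    return "+".join(parts) if parts else "."


def family_report(
    families: Sequence[FamilyAssignment],
    verdicts: Sequence[TOMMVerdict],
    role_calls_by_region: Mapping[str, Sequence[DomainCall]],
    candidates: Sequence[PrecursorCandidate],
) -> pd.DataFrame:
    """One row per family: member count, evidence, role inventory of the
    modification enzymes, precursor count and mean core C/S/T fraction."""
    verdict_by_family = {v.family_id: v for v in verdicts}
    cands_by_region: dict[str, list[PrecursorCandidate]] = {}
    for c in candidates:
        cands_by_region.setdefault(c.region_id, []).append(c)
    rows = []
    for family in sorted(families, key=lambda f: f.family_id):
        verdict = verdict_by_family.get(family.family_id)
        calls: list[DomainCall] = []
        fam_cands: list[PrecursorCandidate] = []
        for rid in family.member_region_ids:
            calls.extend(role_calls_by_region.get(rid, ()))
            fam_cands.extend(cands_by_region.get(rid, ()))
        core_csts = [
            cst_fraction(c.sequence[estimate_cleavage(c.sequence) :])
            for c in fam_cands
            if len(c.sequence) >= 10
        ]
        rows.append(
            {
                "family_id": family.family_id,
                "n_members": len(family.member_region_ids),
                "is_tomm": bool(verdict.is_tomm) if verdict else False,
                "evidence": ",".join(verdict.evidence) if verdict and verdict.evidence else ".",
                "role_inventory": _role_inventory(calls),
                "n_precursors": len(fam_cands),
                "mean_core_cst": round(sum(core_csts) / len(core_csts), 4) if core_csts else 0.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "family_id",
            "n_members",
            "is_tomm",
            "evidence",
            "role_inventory",
            "n_precursors",
            "mean_core_cst",
        ],
    )


def run_manifest(parameters: Mapping, seed: int | None = None) -> dict:
    from . import __version__

    manifest = {"tool": "tommscan", "version": __version__, "parameters": dict(parameters)}
    if seed is not None:
        manifest["seed"] = seed
    return manifest


def write_report(outdir, table: pd.DataFrame, manifest: Mapping) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "families": outdir / "family_report.tsv",
        "manifest": outdir / "manifest.json",
    }
    table.to_csv(paths["families"], sep="\t", index=False)
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths
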
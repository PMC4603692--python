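"""Bundled seed proteins for role calling and synthetic cluster construction.

One founder sequence per modification-enzyme role (plus archetype-private
ancillary founders).  Seeds are generated once at import time from a fixed
numpy PCG64 stream, which is stable across platforms and numpy versions,
so the bundle is byte-reproducible without shipping long literals.

The fused CD seed is the literal concatenation of the C and D seeds, so a
fused gene genuinely carries both domains and is found both by D-anchor
search and by CD role calling.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_SEED_STREAM = 20141028  # fixed founder stream


def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = "".join(rng.choice(list(AMINO_ACIDS), size=length - 1))
    return "M" + body


def _diverge(seq: str, identity: float, rng: np.random.Generator) -> str:
    """Derive a variant at the given identity to ``seq`` (position 0 kept)."""
    n = len(seq)
    n_mut = n - round(identity * n)
    positions = rng.choice(np.arange(1, n), size=n_mut, replace=False)
    out = list(seq)
    for pos in sorted(positions):
        choices = [a for a in AMINO_ACIDS if a != out[pos]]
        out[pos] = choices[rng.integers(len(choices))]
    return "".join(out)


def _build() -> dict[str, str]:
    rng = np.random.default_rng(_SEED_STREAM)
    seeds: dict[str, str] = {}
    # shared role founders (role-defining domains)
    seeds["C"] = _random_protein(rng, 300)
    seeds["D"] = _random_protein(rng, 330)
    seeds["CD"] = seeds["C"] + seeds["D"][1:]  # true two-domain fusion
    seeds["B"] = _random_protein(rng, 300)
    seeds["F"] = _random_protein(rng, 210)
    seeds["radical_SAM"] = _random_protein(rng, 380)
    # family-level C/D variants: ~45 % identity to the founder keeps anchor
    # and role calls strong (e-values far below 1e-10) while putting
    # different families in different similarity-network components at the
    # 1e-54 D-network threshold
    for arch in ("A", "B", "C", "D", "E"):
        seeds[f"D_{arch}"] = _diverge(seeds["D"], 0.45, rng)
        seeds[f"C_{arch}"] = _diverge(seeds["C"], 0.45, rng)
    for arch in ("B", "C"):
        seeds[f"CD_{arch}"] = seeds[f"C_{arch}"] + seeds[f"D_{arch}"][1:]
    # archetype-private ancillary founders (unrelated across archetypes so
    # that only same-archetype regions score above the family threshold)
    for arch in ("A", "B", "C", "D", "E"):
        seeds[f"transporter_{arch}1"] = _random_protein(rng, 250)
        seeds[f"transporter_{arch}2"] = _random_protein(rng, 245)
        seeds[f"protease_{arch}"] = _random_protein(rng, 230)
        seeds[f"methyltransferase_{arch}"] = _random_protein(rng, 260)
        seeds[f"regulator_{arch}"] = _random_protein(rng, 220)
        for k in range(1, 7):
            seeds[f"hypothetical_{arch}{k}"] = _random_protein(rng, 200 + 5 * k)
    return seeds


SEEDS: dict[str, str] = _build()

#: references used by anchor calling (any YcaO-domain carrier)
D_REFERENCES: dict[str, str] = {"D_ref": SEEDS["D"]}


def seed_role(seed_key: str) -> str:
    """Map a seed key to its gene role label."""
    base = seed_key.split("_")[0]
    if base in ("C", "D", "CD") and (len(seed_key) == len(base) or seed_key[len(base)] == "_"):
        return {"C": "C", "D": "D", "CD": "CD_fusion"}[base]
    if seed_key in ("B", "F"):
        return seed_key
    if seed_key == "radical_SAM":
        return "radical_SAM"
    for role in ("transporter", "protease", "methyltransferase", "regulator", "hypothetical"):
        if seed_key.startswith(role):
            return role if role != "hypothetical" and role != "regulator" else "other"
    return "other"


def role_panel() -> dict[str, tuple[str, str]]:
    """Reference panel for role calling: ref_id -> (role, sequence)."""
    panel: dict[str, tuple[str, str]] = {}
    for key, seq in SEEDS.items():
        panel[key] = (seed_role(key), seq)
    return panel
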
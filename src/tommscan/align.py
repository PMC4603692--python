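"""Pairwise protein comparison engine.

Smith-Waterman local alignment with a substitution matrix and affine gaps
(Gotoh recurrences, numba-compiled), Karlin-Altschul e-values computed in
log10 space, and an all-vs-all driver with identity / coverage / e-value
filters.  This is the workhorse behind anchor calling, role calling,
region-pair hit mapping, and similarity networks.

Conventions
-----------
* A gap of length ``k`` costs ``gap_open + k * gap_extend`` (BLASTP 11/1
  convention).
* Traceback tie-breaking is deterministic: diagonal > up (gap in subject)
  > left (gap in query).  The best cell is the highest-scoring cell with
  the smallest ``(i, j)``.
* ``evalue = K * m * n * exp(-lambda * raw_score)``; ``log10_evalue`` is
  exact even when ``evalue`` underflows (the stored float is clamped to
  the smallest positive double so that ``evalue > 0`` always holds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

_LN10 = math.log(10.0)
_TINY = 5e-324  # smallest positive subnormal double

# ---------------------------------------------------------------------------
# Alphabet / matrix handling


@lru_cache(maxsize=None)
def load_matrix(name: str = "BLOSUM62") -> tuple[str, np.ndarray]:
    """Return (alphabet, square int32 score matrix) for a named matrix."""
    mat = substitution_matrices.load(name)
    alphabet = str(mat.alphabet)
    n = len(alphabet)
    arr = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(alphabet):
        for j, b in enumerate(alphabet):
            arr[i, j] = int(mat[a, b])
    return alphabet, arr


@lru_cache(maxsize=None)
def _index_table(alphabet: str) -> np.ndarray:
    """256-entry lookup from ASCII byte to matrix row (unknown -> 'X')."""
    x = alphabet.index("X") if "X" in alphabet else 0
    table = np.full(256, x, dtype=np.int8)
    for i, c in enumerate(alphabet):
        table[ord(c)] = i
    return table


def encode(seq: str, alphabet: str) -> np.ndarray:
    return _index_table(alphabet)[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScoringParams:
    """Substitution matrix, gap penalties and Karlin-Altschul constants.

    Defaults correspond to gapped BLOSUM62 with gap open 11 / extend 1
    (lambda = 0.267, K = 0.041).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    k: float = 0.041

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("lambda and K must be positive")

    @property
    def alphabet(self) -> str:
        return load_matrix(self.matrix_name)[0]

    @property
    def matrix(self) -> np.ndarray:
        return load_matrix(self.matrix_name)[1]


DEFAULT_PARAMS = ScoringParams()


# ---------------------------------------------------------------------------
# Core DP


@njit(cache=True, fastmath=False)
def _sw_fill(a, b, sub, gap_open, gap_extend):  # pragma: no cover - jitted
    m = a.shape[0]
    n = b.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), -1_000_000, dtype=np.int32)  # gap in query (left)
    F = np.full((m + 1, n + 1), -1_000_000, dtype=np.int32)  # gap in subject (up)
    best = 0
    bi = 0
    bj = 0
    go = gap_open + gap_extend
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            e = H[i, j - 1] - go
            e2 = E[i, j - 1] - gap_extend
            if e2 > e:
                e = e2
            E[i, j] = e
            f = H[i - 1, j] - go
            f2 = F[i - 1, j] - gap_extend
            if f2 > f:
                f = f2
            F[i, j] = f
            h = H[i - 1, j - 1] + sub[ai, b[j - 1]]
            if f > h:
                h = f
            if e > h:
                h = e
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, H, E, F


@dataclass
class LocalAlignment:
    """One optimal local alignment (gapped strings + half-open coordinates)."""

    score: int
    aligned_query: str
    aligned_subject: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int

    @property
    def n_columns(self) -> int:
        return len(self.aligned_query)

    @property
    def n_identical(self) -> int:
        return sum(
            1 for x, y in zip(self.aligned_query, self.aligned_subject) if x == y and x != "-"
        )


def smith_waterman(
    a: str, b: str, params: ScoringParams = DEFAULT_PARAMS
) -> tuple[int, LocalAlignment]:
    """Optimal local alignment of two protein sequences.

    Returns ``(raw_score, LocalAlignment)``.  Empty input yields score 0
    and an empty alignment.  Tie-breaking in both the best-cell choice and
    the traceback is deterministic (diagonal > up > left).
    """
    if not a or not b:
        return 0, LocalAlignment(0, "", "", 0, 0, 0, 0)
    alphabet, sub = load_matrix(params.matrix_name)
    ea = encode(a, alphabet)
    eb = encode(b, alphabet)
    best, bi, bj, H, E, F = _sw_fill(ea, eb, sub, params.gap_open, params.gap_extend)
    if best <= 0:
        return 0, LocalAlignment(0, "", "", 0, 0, 0, 0)
    # stateful traceback: M (in H), E (gap in query), F (gap in subject)
    go = params.gap_open + params.gap_extend
    ge = params.gap_extend
    i, j = bi, bj
    qa: list[str] = []
    sa: list[str] = []
    state = "M"
    while True:
        if state == "M":
            h = H[i, j]
            if h == 0:
                break
            diag = H[i - 1, j - 1] + sub[ea[i - 1], eb[j - 1]]
            if h == diag:
                qa.append(a[i - 1])
                sa.append(b[j - 1])
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = "F"
            elif h == E[i, j]:
                state = "E"
            else:  # pragma: no cover - DP consistency guard
                raise AssertionError("inconsistent traceback")
        elif state == "F":
            qa.append(a[i - 1])
            sa.append("-")
            opened = H[i - 1, j] - go
            if F[i, j] != F[i - 1, j] - ge or F[i, j] == opened:
                state = "M"
            i -= 1
        else:  # state == "E"
            qa.append("-")
            sa.append(b[j - 1])
            opened = H[i, j - 1] - go
            if E[i, j] != E[i, j - 1] - ge or E[i, j] == opened:
                state = "M"
            j -= 1
    aln = LocalAlignment(
        score=int(best),
        aligned_query="".join(reversed(qa)),
        aligned_subject="".join(reversed(sa)),
        query_start=i,
        query_end=bi,
        subject_start=j,
        subject_end=bj,
    )
    return int(best), aln


def raw_score(a: str, b: str, params: ScoringParams = DEFAULT_PARAMS) -> int:
    """Score-only Smith-Waterman (no traceback)."""
    if not a or not b:
        return 0
    alphabet, sub = load_matrix(params.matrix_name)
    best, _, _, _, _, _ = _sw_fill(
        encode(a, alphabet), encode(b, alphabet), sub, params.gap_open, params.gap_extend
    )
    return int(best)


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics


def log10_evalue(score: int, m: int, n: int, params: ScoringParams = DEFAULT_PARAMS) -> float:
    """log10 of the Karlin-Altschul e-value (exact, no underflow)."""
    if m <= 0 or n <= 0:
        raise ValueError("m and n must be positive")
    return (math.log(params.k) + math.log(m) + math.log(n) - params.lam * score) / _LN10


def evalue(score: int, m: int, n: int, params: ScoringParams = DEFAULT_PARAMS) -> float:
    """E = K*m*n*exp(-lambda*score), clamped to the smallest positive double."""
    le = log10_evalue(score, m, n, params)
    if le < -323:
        return _TINY
    return max(10.0**le, _TINY)


def bit_score(score: int, params: ScoringParams = DEFAULT_PARAMS) -> float:
    return (params.lam * score - math.log(params.k)) / math.log(2.0)


# ---------------------------------------------------------------------------
# Hits and all-vs-all


@dataclass
class AlignmentHit:
    """A filtered pairwise hit with identity / coverage / e-value statistics."""

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    evalue: float
    log10_evalue: float
    identity_pct: float
    query_coverage_pct: float
    subject_coverage_pct: float
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int

    def swapped(self) -> "AlignmentHit":
        return replace(
            self,
            query_id=self.subject_id,
            subject_id=self.query_id,
            query_coverage_pct=self.subject_coverage_pct,
            subject_coverage_pct=self.query_coverage_pct,
            query_start=self.subject_start,
            query_end=self.subject_end,
            subject_start=self.query_start,
            subject_end=self.query_end,
        )


def compare(
    query_id: str,
    query: str,
    subject_id: str,
    subject: str,
    n_database_residues: int,
    params: ScoringParams = DEFAULT_PARAMS,
) -> AlignmentHit | None:
    """Align one pair and compute full hit statistics (None if score 0)."""
    score, aln = smith_waterman(query, subject, params)
    if score <= 0:
        return None
    ncol = aln.n_columns
    ident = 100.0 * aln.n_identical / ncol if ncol else 0.0
    qcov = 100.0 * (aln.query_end - aln.query_start) / len(query)
    scov = 100.0 * (aln.subject_end - aln.subject_start) / len(subject)
    le = log10_evalue(score, len(query), n_database_residues, params)
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=score,
        bit_score=bit_score(score, params),
        evalue=evalue(score, len(query), n_database_residues, params),
        log10_evalue=le,
        identity_pct=ident,
        query_coverage_pct=qcov,
        subject_coverage_pct=scov,
        query_start=aln.query_start,
        query_end=aln.query_end,
        subject_start=aln.subject_start,
        subject_end=aln.subject_end,
    )


def _passes(
    hit: AlignmentHit,
    min_identity_pct: float | None,
    min_coverage_pct: float | None,
    max_log10_evalue: float | None,
    coverage_mode: str,
) -> bool:
    if min_identity_pct is not None and hit.identity_pct < min_identity_pct:
        return False
    if min_coverage_pct is not None:
        if coverage_mode == "query":
            cov = hit.query_coverage_pct
        elif coverage_mode == "both":
            cov = min(hit.query_coverage_pct, hit.subject_coverage_pct)
        else:
            raise ValueError(f"unknown coverage_mode {coverage_mode!r}")
        if cov < min_coverage_pct:
            return False
    if max_log10_evalue is not None and hit.log10_evalue > max_log10_evalue:
        return False
    return True


def all_vs_all(
    proteins: dict[str, str] | Sequence[tuple[str, str]],
    params: ScoringParams = DEFAULT_PARAMS,
    *,
    min_identity_pct: float | None = None,
    min_coverage_pct: float | None = None,
    max_evalue: float | None = None,
    coverage_mode: str = "query",
) -> list[AlignmentHit]:
    """All unordered pairs passing every filter; self-hits excluded.

    The e-value database size ``n`` is the total residue count of the input
    set.  Each unordered pair is evaluated once with the lexicographically
    smaller id as query; ordering of the result is deterministic.
    """
    items = sorted(dict(proteins).items())
    if not items:
        raise ValueError("need at least one protein")
    n_db = sum(len(s) for _, s in items)
    max_le = math.log10(max_evalue) if max_evalue is not None else None
    hits: list[AlignmentHit] = []
    for i in range(len(items)):
        qid, q = items[i]
        for j in range(i + 1, len(items)):
            sid, s = items[j]
            hit = compare(qid, q, sid, s, n_db, params)
            if hit is None:
                continue
            if _passes(hit, min_identity_pct, min_coverage_pct, max_le, coverage_mode):
                hits.append(hit)
    return hits


# ---------------------------------------------------------------------------
# Tabular I/O (12-column BLAST outfmt-6 style)

_TAB_COLUMNS = [
    "query",
    "subject",
    "identity_pct",
    "coverage_pct",
    "raw_score",
    "bit_score",
    "evalue",
]


def write_hits_tsv(hits: Iterable[AlignmentHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TAB_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.identity_pct:.2f}\t"
                f"{h.query_coverage_pct:.2f}\t{h.raw_score}\t{h.bit_score:.2f}\t"
                f"{h.evalue:.3g}\n"
            )


def read_external_tabular(path) -> list[AlignmentHit]:
    """Adapter: read 12-column BLAST ``-outfmt 6`` lines into AlignmentHits.

    Coverage is not derivable from the 12 standard columns and is set to
    100 so downstream identity/e-value filters still apply.
    """
    hits = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            ev = float(f[10])
            hits.append(
                AlignmentHit(
                    query_id=f[0],
                    subject_id=f[1],
                    raw_score=int(round(float(f[11]))),
                    bit_score=float(f[11]),
                    evalue=max(ev, _TINY),
                    log10_evalue=math.log10(ev) if ev > 0 else -324.0,
                    identity_pct=float(f[2]),
                    query_coverage_pct=100.0,
                    subject_coverage_pct=100.0,
                    query_start=int(f[6]) - 1,
                    query_end=int(f[7]),
                    subject_start=int(f[8]) - 1,
                    subject_end=int(f[9]),
                )
            )
    return hits
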
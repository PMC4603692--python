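"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results through different algorithms than the
package: local alignment as a maximum of global (Needleman-Wunsch-style)
affine alignments over all substring pairs; ORF enumeration by direct
(start, stop) pair search; synteny by literal adjacency recount; and
connected components by union-find.
"""

from __future__ import annotations

from tommscan.align import ScoringParams, encode, load_matrix

NEG = -(10**9)


def global_affine_score(a, b, sub, gap_open, gap_extend):
    """Global alignment score with gap cost open + k*extend (iterative DP,
    distinct formulation from the package's local Gotoh kernel)."""
    m, n = len(a), len(b)
    go = gap_open + gap_extend
    ge = gap_extend
    # rows over a; M/X = last pair aligned, Ga = gap in a (consume b), Gb = gap in b
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    Ga = [[NEG] * (n + 1) for _ in range(m + 1)]
    Gb = [[NEG] * (n + 1) for _ in range(m + 1)]
    M[0][0] = 0
    for j in range(1, n + 1):
        Ga[0][j] = -(go + ge * (j - 1))
    for i in range(1, m + 1):
        Gb[i][0] = -(go + ge * (i - 1))
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            best_prev = max(M[i - 1][j - 1], Ga[i - 1][j - 1], Gb[i - 1][j - 1])
            if best_prev > NEG:
                M[i][j] = best_prev + sub[a[i - 1], b[j - 1]]
            Ga[i][j] = max(
                M[i][j - 1] - go if M[i][j - 1] > NEG else NEG,
                Ga[i][j - 1] - ge if Ga[i][j - 1] > NEG else NEG,
                Gb[i][j - 1] - go if Gb[i][j - 1] > NEG else NEG,
            )
            Gb[i][j] = max(
                M[i - 1][j] - go if M[i - 1][j] > NEG else NEG,
                Gb[i - 1][j] - ge if Gb[i - 1][j] > NEG else NEG,
                Ga[i - 1][j] - go if Ga[i - 1][j] > NEG else NEG,
            )
    return max(M[m][n], Ga[m][n], Gb[m][n])


def brute_local_score(a: str, b: str, params: ScoringParams) -> int:
    """Exhaustive local alignment: max over every substring pair of the
    global affine score (empty alignment scores 0)."""
    alphabet, sub = load_matrix(params.matrix_name)
    ea = encode(a, alphabet)
    eb = encode(b, alphabet)
    best = 0
    for i in range(len(a)):
        for j in range(i + 1, len(a) + 1):
            for k in range(len(b)):
                for l in range(k + 1, len(b) + 1):
                    score = global_affine_score(
                        ea[i:j], eb[k:l], sub, params.gap_open, params.gap_extend
                    )
                    if score > best:
                        best = score
    return best


# ---------------------------------------------------------------------------


def brute_orfs(dna: str, min_len_aa: int, max_len_aa: int, all_starts: bool):
    """Enumerate ORFs by testing every (start codon, next in-frame stop)
    pair directly on both strands."""
    from Bio.Seq import Seq

    starts = {"ATG", "GTG", "TTG"}
    stops = {"TAA", "TAG", "TGA"}

    def scan(seq):
        found = []
        n = len(seq)
        for p in range(n - 2):
            if seq[p : p + 3] not in starts:
                continue
            q = p + 3
            while q + 3 <= n and seq[q : q + 3] not in stops:
                q += 3
            if q + 3 > n:
                continue  # unterminated
            length = (q - p) // 3
            if not (min_len_aa <= length < max_len_aa):
                continue
            if not all_starts:
                # longest per (frame, stop): no earlier start codon in the
                # same frame after the previous in-frame stop
                r = p - 3
                shadowed = False
                while r >= 0:
                    codon = seq[r : r + 3]
                    if codon in stops:
                        break
                    if codon in starts:
                        shadowed = True
                        break
                    r -= 3
                if shadowed:
                    continue
            found.append((str(Seq(seq[p:q]).translate(table=11)), p, q + 3, p % 3))
        return found

    dna = dna.upper()
    out = [(pep, s, e, "+", f) for pep, s, e, f in scan(dna)]
    rc = str(Seq(dna).reverse_complement())
    out.extend((pep, len(dna) - e, len(dna) - s, "-", f) for pep, s, e, f in scan(rc))
    out.sort(key=lambda t: (t[1], t[2], t[3], t[4]))
    return out


# ---------------------------------------------------------------------------


def brute_synteny(order_a, order_b, strands_a, strands_b, mapping):
    """Literal recount of conserved adjacencies for a given mapping."""
    pos_a = {g: i for i, g in enumerate(order_a)}
    pos_b = {g: i for i, g in enumerate(order_b)}
    count = 0
    mapped = sorted(mapping, key=lambda g: pos_a[g])
    for g1, g2 in zip(mapped, mapped[1:]):
        if pos_a[g2] - pos_a[g1] != 1:
            continue
        p1, p2 = mapping[g1], mapping[g2]
        delta = pos_b[p2] - pos_b[p1]
        keep1 = strands_a[g1] == strands_b[p1]
        keep2 = strands_a[g2] == strands_b[p2]
        if (delta == 1 and keep1 and keep2) or (delta == -1 and not keep1 and not keep2):
            count += 1
    return count


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x, y):
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[rx] = ry

    def groups(self):
        out = {}
        for x in self.parent:
            out.setdefault(self.find(x), set()).add(x)
        return sorted([sorted(g) for g in out.values()])
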
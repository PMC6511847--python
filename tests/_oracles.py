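"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the definition of each operation, not from
the library code paths it checks.
"""

from __future__ import annotations

import math

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}

# Standard bacterial codon translation (table 11 translates like the standard
# table; only the start-codon set differs).
CODON_AA = {}
_BASES = "TCAG"
_AAS = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            CODON_AA[_b1 + _b2 + _b3] = _AAS[16 * _i + 4 * _j + _k]

STARTS = {"ATG", "GTG", "TTG"}
STOPS = {"TAA", "TAG", "TGA"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def translate_oracle(nt: str) -> str:
    """Character-by-character codon-table lookup; start rendered as M."""
    aa = "".join(CODON_AA.get(nt[i : i + 3], "X") for i in range(0, len(nt), 3))
    if aa.endswith("*"):
        aa = aa[:-1]
    if nt[:3] in STARTS and aa:
        aa = "M" + aa[1:]
    return aa


def brute_orf_scan(seq: str, min_nt: int = 60, max_aa: int = 120) -> set:
    """Exhaustive six-frame start→stop scan; returns {(start, end, strand)}
    on the forward axis. Every in-frame start upstream of a stop counts."""
    max_pep_nt = 2 * max_aa * 3
    n = len(seq)
    out = set()
    for strand in (1, -1):
        s = seq if strand == 1 else revcomp(seq)
        for i in range(n - 2):
            if s[i : i + 3] not in STARTS:
                continue
            j = i
            while j + 3 <= n:
                codon = s[j : j + 3]
                if codon in STOPS:
                    length = j + 3 - i
                    if length >= min_nt and (length - 3) <= max_pep_nt:
                        if strand == 1:
                            out.add((i, j + 3, 1))
                        else:
                            out.add((n - (j + 3), n - i, -1))
                    break
                j += 3
    return out


def count_inframe_hexamers(seq_spans: list[str]) -> dict[str, int]:
    """Brute 6-mer counter over coding-strand spans, codon-phase steps."""
    counts: dict[str, int] = {}
    for span in seq_spans:
        for i in range(0, len(span) - 5, 3):
            h = span[i : i + 6]
            if "N" not in h:
                counts[h] = counts.get(h, 0) + 1
    return counts


def sw_score_oracle(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Gotoh local-alignment score; a gap of length k costs open + k*extend."""
    n, m = len(a), len(b)
    neg = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] - gap_extend, H[i][j - 1] - gap_open - gap_extend)
            F[i][j] = max(F[i - 1][j] - gap_extend, H[i - 1][j] - gap_open - gap_extend)
            sub = matrix[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def components_oracle(nodes, edges) -> list[frozenset]:
    """Connected components by iterated transitive closure over the edge set."""
    comp = {n: {n} for n in nodes}
    changed = True
    while changed:
        changed = False
        for u, v in edges:
            merged = comp[u] | comp[v]
            if merged != comp[u] or merged != comp[v]:
                for w in merged:
                    comp[w] = merged
                changed = True
    return list({frozenset(c) for c in comp.values()})


def select_oracle(items, limit: int, thresh: float, max_dist: int):
    """Sort, slice, threshold-union, dedup — the retrieval rule as stated."""
    pool = [it for it in items if it["dist"] <= max_dist]
    order = sorted(pool, key=lambda it: (-it["score"], it["dist"], it["start"]))
    picked = order[:limit] + [it for it in order[limit:] if it["score"] >= thresh]
    seen, out = set(), []
    for it in picked:
        if it["key"] not in seen:
            seen.add(it["key"])
            out.append(it["key"])
    return out


def pssm_best_window_oracle(peptide: str, columns, alphabet: str):
    """Exhaustive all-offset ungapped profile scan; returns best score or None."""
    L = len(columns)
    if len(peptide) < L:
        return None
    best = None
    for off in range(len(peptide) - L + 1):
        s = 0.0
        for i, col in enumerate(columns):
            idx = alphabet.find(peptide[off + i])
            if idx >= 0:
                s += col[idx]
        if best is None or s > best:
            best = s
    return best


def evalue_oracle(raw: float, m: int, n: int, lam: float, k: float) -> float:
    bit = (lam * raw - math.log(k)) / math.log(2)
    return m * n * 2.0 ** (-bit)
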
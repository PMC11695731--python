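"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (exhaustive DP, sliding windows,
pairwise graph search) and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import re

# standard nuclear genetic code, written out for table-lookup translation
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_RC = str.maketrans("ACGT", "TGCA")


def rc(s: str) -> str:
    return s.translate(_RC)[::-1]


def translate_by_table(seq: str) -> tuple[str, int | None]:
    """Codon-by-codon table lookup; returns (protein, stop codon index)."""
    aa = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        res = CODON_TABLE[seq[i : i + 3]]
        if res == "*":
            return "".join(aa), i // 3 + 1
        aa.append(res)
    return "".join(aa), None


def levenshtein(a: str, b: str) -> int:
    """Exhaustive unit-cost edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j - 1] + (ca != cb), prev[j] + 1, cur[-1] + 1))
        prev = cur
    return prev[-1]


IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def iupac_match_positions(seq: str, pattern: str) -> list[int]:
    """Sliding-window IUPAC match start positions (overlapping)."""
    out = []
    for i in range(len(seq) - len(pattern) + 1):
        if all(seq[i + j] in IUPAC_SETS[p] for j, p in enumerate(pattern)):
            out.append(i)
    return out


def hamming_scan(genome: dict[str, str], spacer: str, max_mm: int):
    """All NGG-adjacent 20-mers within max_mm of the spacer, both strands.

    Returns a set of (chrom, plus_strand_position, strand, mismatches).
    """
    hits = set()
    for chrom, seq in genome.items():
        for strand in "+-":
            s = seq if strand == "+" else rc(seq)
            for i in range(len(s) - 22):
                if s[i + 21 : i + 23] != "GG":
                    continue
                mm = sum(a != b for a, b in zip(s[i : i + 20], spacer))
                if mm <= max_mm:
                    pos = i if strand == "+" else len(s) - (i + 23)
                    hits.add((chrom, pos, strand, mm))
    return hits


def scan_protospacers(allele: str) -> set[tuple[str, str, str, int]]:
    """Regex-based enumeration of 20-mer+NGG on both strands."""
    out = set()
    for m in re.finditer(r"(?=([ACGT]{20})([ACGT]GG))", allele):
        out.add((m.group(1), m.group(2), "+", m.start()))
    rcseq = rc(allele)
    for m in re.finditer(r"(?=([ACGT]{20})([ACGT]GG))", rcseq):
        start_plus = len(allele) - (m.start() + 20)
        out.add((m.group(1), m.group(2), "-", start_plus))
    return out


def overlap_components(intervals: list[tuple[int, int]]) -> list[set[int]]:
    """Connected components of intervals under >=1 bp overlap (pairwise
    graph + depth-first search)."""
    n = len(intervals)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = intervals[i], intervals[j]
            if a[0] < b[1] and b[0] < a[1]:
                adj[i].append(j)
                adj[j].append(i)
    seen = [False] * n
    comps = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], set()
        seen[i] = True
        while stack:
            u = stack.pop()
            comp.add(u)
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        comps.append(comp)
    return comps


def affine_global_score(
    ref: str,
    read: str,
    match: int = 2,
    mismatch: int = -4,
    gap_open: int = -10,
    gap_extend: int = -1,
) -> float:
    """Gotoh affine-gap global alignment score with free end gaps on the
    reference side (the read must be consumed end-to-end).

    Mirrors the quantifier's scoring contract; three-state DP, no
    heuristics.  ``gap_open`` is the cost of the first gap base
    (open + extend collapsed, matching PairwiseAligner's convention).
    """
    NEG = float("-inf")
    m, n = len(ref), len(read)
    # state M: ref[i] aligned to read[j]; D: gap in read (ref skipped);
    # I: gap in ref (read base inserted)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    D = [[NEG] * (n + 1) for _ in range(m + 1)]
    I = [[NEG] * (n + 1) for _ in range(m + 1)]
    M[0][0] = 0.0
    for i in range(1, m + 1):
        D[i][0] = 0.0  # free leading deletion (read starts inside ref)
    for j in range(1, n + 1):
        I[0][j] = (gap_open + (j - 1) * gap_extend)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if ref[i - 1] == read[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], D[i - 1][j - 1], I[i - 1][j - 1]) + s
            D[i][j] = max(M[i - 1][j] + gap_open, D[i - 1][j] + gap_extend,
                          I[i - 1][j] + gap_open)
            I[i][j] = max(M[i][j - 1] + gap_open, I[i][j - 1] + gap_extend,
                          D[i][j - 1] + gap_open)
    # free trailing deletion: best over all ref suffixes at full read
    best = max(max(M[i][n], I[i][n]) for i in range(m + 1))
    best = max(best, max(D[i][n] for i in range(m + 1)))
    return best
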
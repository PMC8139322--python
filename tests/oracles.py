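"""Independent brute-force oracles used to validate the package.

Everything here is deliberately written from first principles (plain
dynamic programming, exhaustive enumeration, exact integer arithmetic)
and never calls into :mod:`bacpan` internals, so tests can compare the
package's optimised paths against genuinely independent computations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_AA_INDEX = {aa: i for i, aa in enumerate(_BLOSUM62.alphabet)}
_NEG = -1e9


def gotoh_score(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Optimal affine-gap semi-global (free end gaps) alignment score.

    Independent Gotoh dynamic program.  Free end gaps mean an alignment
    may skip any prefix/suffix of either sequence at no cost (the empty
    alignment scores 0), matching columns score BLOSUM62, and internal
    gap runs cost open + (len-1)*extend.
    """
    la, lb = len(a), len(b)
    ai = np.array([_AA_INDEX[c] for c in a])
    bi = np.array([_AA_INDEX[c] for c in b])
    sub = np.asarray(_BLOSUM62, dtype=float)[np.ix_(ai, bi)]  # la x lb

    # overlap model: a leading gap may skip a prefix of ONE sequence and a
    # trailing gap a suffix of ONE sequence; no double-gap columns.
    j_idx = np.arange(lb + 1, dtype=float)
    prev_m = np.zeros(lb + 1)  # M[0][j] = 0: skip any b-prefix for free
    prev_x = np.full(lb + 1, _NEG)  # gap run in b (consumes a)
    prev_y = np.full(lb + 1, _NEG)  # gap run in a (consumes b)
    best = 0.0  # the empty alignment
    for i in range(1, la + 1):
        cur_m = np.full(lb + 1, _NEG)
        cur_m[0] = 0.0  # M[i][0] = 0: skip any a-prefix for free
        start = np.maximum.reduce([prev_m[:-1], prev_x[:-1], prev_y[:-1]])
        cur_m[1:] = sub[i - 1] + start
        # paid gap runs may not follow a free leading gap of the other
        # sequence (no adjacent insertion/deletion runs): mask boundary cells
        m_real = cur_m.copy()
        m_real[0] = _NEG
        prev_m_real = prev_m.copy()
        prev_m_real[0] = _NEG
        if i == 1:
            prev_m_real[:] = _NEG
        cur_x = np.maximum(prev_m_real - gap_open, prev_x - gap_extend)
        # cur_y[j] = max_{j'<j} m[j'] - open - (j-1-j')*extend
        run = np.maximum.accumulate(m_real + j_idx * gap_extend)
        cur_y = np.full(lb + 1, _NEG)
        cur_y[1:] = run[:-1] - gap_open - (j_idx[1:] - 1.0) * gap_extend
        # trailing free gap in b: alignment may end at (i, lb) for any i
        best = max(best, float(cur_m[lb]))
        prev_m, prev_x, prev_y = cur_m, cur_x, cur_y
    # trailing free gap in a: alignment may end anywhere on the last row
    best = max(best, float(prev_m[1:].max()))
    return best


def global_identity(a: str, b: str) -> float:
    """Unit-cost global alignment identity: matches / alignment length.

    Uses plain Needleman-Wunsch with match=1, mismatch/gap=0 score and
    divides the longest common subsequence-style match count by the
    global alignment length (max of lengths is a lower bound; here
    computed as LCS matches over max(len)).  A blunt instrument used only
    to check that unrelated sequences stay far below 50% identity.
    """
    la, lb = len(a), len(b)
    prev = np.zeros(lb + 1, dtype=int)
    for i in range(1, la + 1):
        cur = np.zeros(lb + 1, dtype=int)
        ca = a[i - 1]
        for j in range(1, lb + 1):
            cur[j] = max(prev[j], cur[j - 1], prev[j - 1] + (ca == b[j - 1]))
        prev = cur
    return prev[lb] / max(la, lb)


def hamming_identity(a: str, b: str) -> float:
    """Identity of two equal-length sequences without gaps."""
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)


def brute_force_families(
    proteomes: dict[str, dict[str, str]],
    identity_min: float = 0.5,
    coverage_min: float = 0.5,
    pair_passes=None,
) -> set[frozenset]:
    """Transitive closure of threshold-passing pairs, computed pairwise.

    ``pair_passes(seq1, seq2) -> bool`` defaults to equal-length Hamming
    identity >= identity_min (adequate for simulator output where family
    members share a common ancestor of fixed length), falling back to a
    global-identity bound for unequal lengths.
    """
    if pair_passes is None:
        def pair_passes(s1: str, s2: str) -> bool:
            if len(s1) == len(s2):
                ident = hamming_identity(s1, s2)
            else:
                ident = global_identity(s1, s2)
                if min(len(s1), len(s2)) / max(len(s1), len(s2)) < coverage_min:
                    return False
            return ident >= identity_min

    genes = [
        (genome, gene, seq)
        for genome in sorted(proteomes)
        for gene, seq in sorted(proteomes[genome].items())
    ]
    parent = list(range(len(genes)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if pair_passes(genes[i][2], genes[j][2]):
                union(i, j)
    clusters: dict[int, set] = {}
    for idx, (genome, gene, _) in enumerate(genes):
        clusters.setdefault(find(idx), set()).add((genome, gene))
    return {frozenset(v) for v in clusters.values()}


def exhaustive_rarefaction(presence: np.ndarray):
    """Mean pan/core/new trajectories over every genome ordering.

    ``presence`` is a genomes x families boolean array; feasible for
    <= ~6 genomes (n! orderings).
    """
    n = presence.shape[0]
    pans = []
    cores = []
    news = []
    for order in itertools.permutations(range(n)):
        rows = presence[list(order)]
        pan = np.logical_or.accumulate(rows, axis=0).sum(axis=1)
        core = np.logical_and.accumulate(rows, axis=0).sum(axis=1)
        new = np.diff(pan, prepend=0)
        pans.append(pan)
        cores.append(core)
        news.append(new)
    return (
        np.mean(pans, axis=0),
        np.mean(cores, axis=0),
        np.mean(news, axis=0),
    )


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    Sums the probabilities of all outcomes with the observed margins whose
    probability does not exceed the observed outcome's (with the standard
    1 + 1e-7 relative tie tolerance).  Exact integer arithmetic.
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    weights = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)}
    total = sum(weights.values())
    observed = weights[a]
    kept = sum(w for w in weights.values() if w <= observed * (1 + 1e-7))
    return kept / total


def canonical_kmer_set(sequence: str, k: int) -> set[str]:
    comp = str.maketrans("ACGT", "TGCA")
    rc = sequence.translate(comp)[::-1]
    L = len(sequence)
    return {
        min(sequence[i : i + k], rc[L - k - i : L - i])
        for i in range(L - k + 1)
        if set(sequence[i : i + k]) <= set("ACGT")
    }


def exact_jaccard(seq_a: str, seq_b: str, k: int = 21) -> float:
    A, B = canonical_kmer_set(seq_a, k), canonical_kmer_set(seq_b, k)
    return len(A & B) / len(A | B)
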
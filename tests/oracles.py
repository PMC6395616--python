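"""Independent brute-force oracles used to validate the implementations.

Each oracle recomputes a quantity from first principles (explicit enumeration
or direct recursion over definitions) without touching the package's
vectorised tables or DP code paths.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_BASES = "ACGT"


def _aa(codon: str) -> str:
    return "*" if codon in _TABLE.stop_codons else _TABLE.forward_table[codon]


# ---------------------------------------------------------------------------
# NG86 by direct enumeration
# ---------------------------------------------------------------------------


def oracle_syn_sites(codon: str) -> float:
    """Synonymous site count: per position, fraction of the three possible
    single-nucleotide changes that preserve the amino acid (changes creating a
    stop codon count as nonsynonymous)."""
    s = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if _aa(mut) == _aa(codon):
                s += 1 / 3
    return s


def oracle_codon_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Expected (synonymous, nonsynonymous) differences between two codons,
    averaged over all orderings of the differing positions; orderings that
    pass through a stop codon are discarded unless every ordering does."""
    diff = [p for p in range(3) if c1[p] != c2[p]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        syn = nonsyn = 0
        blocked = False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if _aa(nxt) == "*" and nxt != c2:
                blocked = True
            if _aa(cur) == _aa(nxt):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        paths.append((blocked, syn, nonsyn))
    usable = [(s, n) for b, s, n in paths if not b] or [(s, n) for _, s, n in paths]
    sd = sum(s for s, _ in usable) / len(usable)
    nd = sum(n for _, n in usable) / len(usable)
    return sd, nd


def oracle_ng86(seq_a: str, seq_b: str) -> tuple[float, float]:
    """(ka, ks) by direct per-codon enumeration plus Jukes-Cantor."""
    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    codons = [
        (seq_a[i : i + 3], seq_b[i : i + 3]) for i in range(0, len(seq_a), 3)
    ]
    codons = [(x, y) for x, y in codons if _aa(x) != "*" and _aa(y) != "*"]
    s_sites = sum((oracle_syn_sites(x) + oracle_syn_sites(y)) / 2 for x, y in codons)
    n_sites = 3 * len(codons) - s_sites
    sd = nd = 0.0
    for x, y in codons:
        d_s, d_n = oracle_codon_diffs(x, y)
        sd += d_s
        nd += d_n

    def jc(p: float) -> float:
        # proportions within 1e-12 of 3/4 count as saturated (float ties)
        if p >= 0.75 - 1e-12:
            return math.inf
        if p <= 0:
            return 0.0
        return -0.75 * math.log(1 - 4 * p / 3)

    return jc(nd / n_sites if n_sites else 0.0), jc(sd / s_sites if s_sites else 0.0)


# ---------------------------------------------------------------------------
# Mann-Whitney U by exhaustive relabelling
# ---------------------------------------------------------------------------


def oracle_mwu(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """(U_a, two-sided exact p) by enumerating every split of the pooled
    sample into groups of the observed sizes.  Two-sided p is the fraction of
    splits whose min(U, n_a*n_b - U) is at most the observed one."""

    def u_stat(x, y):
        u = 0.0
        for xi in x:
            for yi in y:
                if xi > yi:
                    u += 1.0
                elif xi == yi:
                    u += 0.5
        return u

    pooled = list(a) + list(b)
    n_a = len(a)
    nm = n_a * len(b)
    u_obs = u_stat(a, b)
    m_obs = min(u_obs, nm - u_obs)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(ga, gb)
        if min(u, nm - u) <= m_obs + 1e-12:
            count += 1
        total += 1
    return u_obs, count / total


# ---------------------------------------------------------------------------
# Chain enumeration on toy anchor sets
# ---------------------------------------------------------------------------


def oracle_best_chain(anchors, match_score=50.0, gap_penalty=-1.0, max_gaps=25):
    """Best-scoring strictly increasing chain by exhaustive DFS.

    ``anchors`` is a list of (order_a, order_b) tuples (one chromosome pair,
    collinear orientation).  Returns (score, chain as tuple list).
    """
    best = (-math.inf, [])

    def extend(chain, score):
        nonlocal best
        if score > best[0] or (score == best[0] and len(chain) > len(best[1])):
            best = (score, list(chain))
        last = chain[-1]
        for nxt in anchors:
            if nxt[0] <= last[0] or nxt[1] <= last[1]:
                continue
            ga, gb = nxt[0] - last[0] - 1, nxt[1] - last[1] - 1
            if ga > max_gaps or gb > max_gaps:
                continue
            extend(chain + [nxt], score + match_score + gap_penalty * (ga + gb))

    for a in anchors:
        extend([a], match_score)
    return best


def oracle_tandem_arrays(pairs, positions, max_intervening=1):
    """Transitive closure of near-adjacent hit pairs by repeated expansion.

    ``pairs``: iterable of (gene1, gene2); ``positions``: gene -> (chrom,
    rank).  Returns the set of genes in any array.
    """
    edges = set()
    for g1, g2 in pairs:
        c1, o1 = positions[g1]
        c2, o2 = positions[g2]
        if c1 == c2 and abs(o1 - o2) <= max_intervening + 1:
            edges.add(frozenset((g1, g2)))
    groups = [set(e) for e in edges]
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if groups[i] & groups[j]:
                    groups[i] |= groups[j]
                    groups.pop(j)
                    changed = True
                    break
            if changed:
                break
    out = set()
    for g in groups:
        out |= g
    return out
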
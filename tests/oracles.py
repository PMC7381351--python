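"""Independent reference implementations used only to cross-check the
package: written from first principles, sharing no tables or helper code
with baeocomp itself."""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

_BASES = "TCAG"
_AMINO = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_CODE = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def translate(codon: str) -> str:
    return _CODE[codon]


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon: per position,
    the fraction of non-stop single-nucleotide changes that are synonymous."""
    if _CODE[codon] == "*":
        raise ValueError("stop codon")
    syn_total = 0.0
    for pos in range(3):
        changes = []
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if _CODE[mut] != "*":
                changes.append(_CODE[mut] == _CODE[codon])
        syn_total += sum(changes) / len(changes)
    return syn_total, 3.0 - syn_total


@lru_cache(maxsize=None)
def codon_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two codons,
    averaged over minimal substitution pathways that avoid stop codons
    (falling back to all pathways, stop steps nonsynonymous, if none)."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0

    def walk(allow_stops: bool):
        results = []
        for order in itertools.permutations(positions):
            cur, syn, non, ok = c1, 0, 0, True
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if _CODE[nxt] == "*" and nxt != c2 and not allow_stops:
                    ok = False
                    break
                if _CODE[cur] != "*" and _CODE[nxt] != "*" and _CODE[cur] == _CODE[nxt]:
                    syn += 1
                else:
                    non += 1
                cur = nxt
            if ok:
                results.append((syn, non))
        return results

    results = walk(allow_stops=False)
    if not results:
        results = walk(allow_stops=True)
    syn = sum(r[0] for r in results) / len(results)
    non = sum(r[1] for r in results) / len(results)
    return syn, non


def ng86_bruteforce(seq1: str, seq2: str) -> dict:
    """Nei–Gojobori counts and Jukes–Cantor-corrected rates, recomputed by
    explicit enumeration over codons and pathways."""
    assert len(seq1) == len(seq2) and len(seq1) % 3 == 0
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3].upper(), seq2[i : i + 3].upper()
        if not (set(c1) <= set("ACGT") and set(c2) <= set("ACGT")):
            continue
        if _CODE[c1] == "*" or _CODE[c2] == "*":
            continue
        s1, n1 = codon_sites(c1)
        s2, n2 = codon_sites(c2)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        sd, nd = codon_diffs(c1, c2)
        Sd += sd
        Nd += nd
    p_s = Sd / S if S else 0.0
    p_n = Nd / N if N else 0.0

    def jc(p):
        if p == 0:
            return 0.0
        arg = 1 - 4 * p / 3
        return float("nan") if arg <= 0 else -0.75 * math.log(arg)

    return dict(S=S, N=N, Sd=Sd, Nd=Nd, p_s=p_s, p_n=p_n, Ks=jc(p_s), Ka=jc(p_n))


def fisher_twosided_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration: sum of
    probabilities of all same-margin tables no more probable than observed."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    total = 0.0
    for x in range(lo, hi + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


def mannwhitney_exact_enum(x: list[float], y: list[float]) -> float:
    """Two-sided exact Mann–Whitney p by enumerating every assignment of the
    pooled observations to the two groups (assumes no ties)."""
    pooled = sorted(x + y)
    n1 = len(x)

    def u_stat(group_x):
        group_y = [v for v in pooled if v not in group_x]
        return sum(1 for xi in group_x for yi in group_y if xi > yi)

    u_obs = sum(1 for xi in x for yi in y if xi > yi)
    us = [
        u_stat(set(combo)) for combo in itertools.combinations(pooled, n1)
    ]
    n = len(us)
    lower = sum(1 for u in us if u <= u_obs) / n
    upper = sum(1 for u in us if u >= u_obs) / n
    return min(1.0, 2 * min(lower, upper))


def count_synonymous_events(events, families=None) -> int:
    """Per-site substitution counter over the simulator's event log: counts
    accepted events whose old and new codons translate identically."""
    from baeocomp._codon import CODONS  # only to decode the log's indices

    n = 0
    for row in events.itertuples():
        if families is not None and row.family not in families:
            continue
        if translate(CODONS[row.old_codon]) == translate(CODONS[row.new_codon]):
            n += 1
    return n
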
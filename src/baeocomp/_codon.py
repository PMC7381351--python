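"""Shared codon tables for the standard genetic code.

Everything here is precomputed once at import: codon <-> index maps, the
amino-acid translation of each codon, single-nucleotide neighbour lookups,
and the Nei–Gojobori site/difference tables used by both the simulator and
the divergence estimator.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

NUCS = "ACGT"
NUC_INDEX = {n: i for i, n in enumerate(NUCS)}

CODONS = ["".join(c) for c in itertools.product(NUCS, repeat=3)]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

_table = unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_table.stop_codons)

#: amino acid per codon index; '*' for stops
AA = np.array(
    ["*" if c in STOP_CODONS else _table.forward_table[c] for c in CODONS]
)
IS_STOP = np.array([c in STOP_CODONS for c in CODONS])

# NEIGHBOR[c, pos, a] = codon index after replacing position pos of codon c
# with the a-th alternative nucleotide (alternatives in ACGT order, skipping
# the incumbent).  ALT_NUC gives the nucleotide index actually substituted.
NEIGHBOR = np.zeros((64, 3, 3), dtype=np.int8)
ALT_NUC = np.zeros((64, 3, 3), dtype=np.int8)
for ci, codon in enumerate(CODONS):
    for pos in range(3):
        alts = [n for n in NUCS if n != codon[pos]]
        for ai, alt in enumerate(alts):
            new = codon[:pos] + alt + codon[pos + 1 :]
            NEIGHBOR[ci, pos, ai] = CODON_INDEX[new]
            ALT_NUC[ci, pos, ai] = NUC_INDEX[alt]

#: True where the mutation is synonymous (same amino acid, neither a stop)
IS_SYN_MUT = np.zeros((64, 3, 3), dtype=bool)
#: True where the mutation creates a stop codon
IS_STOP_MUT = np.zeros((64, 3, 3), dtype=bool)
for ci in range(64):
    for pos in range(3):
        for ai in range(3):
            nj = NEIGHBOR[ci, pos, ai]
            IS_STOP_MUT[ci, pos, ai] = IS_STOP[nj]
            IS_SYN_MUT[ci, pos, ai] = (not IS_STOP[nj]) and AA[nj] == AA[ci]

# --- Nei–Gojobori site counts ------------------------------------------------
# Per codon, each position contributes a synonymous-site fraction equal to the
# share of its possible single-nucleotide changes that are synonymous, with
# stop-creating changes removed from the denominator.  The three positions sum
# to a per-codon (syn, nonsyn) pair with syn + nonsyn == 3 exactly.
SYN_SITES = np.zeros(64)
for ci in range(64):
    if IS_STOP[ci]:
        continue
    total = 0.0
    for pos in range(3):
        nonstop = (~IS_STOP_MUT[ci, pos]).sum()
        if nonstop == 0:  # cannot happen in the standard code
            continue
        total += IS_SYN_MUT[ci, pos].sum() / nonstop
    SYN_SITES[ci] = total
NONSYN_SITES = np.where(IS_STOP, 0.0, 3.0 - SYN_SITES)


def _path_steps(a: int, b: int) -> tuple[float, float] | None:
    """Average (syn, nonsyn) step counts over minimal mutational pathways
    from codon ``a`` to codon ``b``, excluding pathways through stop codons.

    Returns ``None`` for the (rare) pairs where every minimal pathway passes
    through a stop; callers fall back to including those pathways.
    """
    ca, cb = CODONS[a], CODONS[b]
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    syn_sum = non_sum = 0.0
    n_paths = 0
    for order in itertools.permutations(diff):
        cur = ca
        syn = non = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != cb:
                blocked = True
                break
            if AA[CODON_INDEX[nxt]] == AA[CODON_INDEX[cur]]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if not blocked:
            syn_sum += syn
            non_sum += non
            n_paths += 1
    if n_paths == 0:
        return None
    return syn_sum / n_paths, non_sum / n_paths


def _path_steps_all(a: int, b: int) -> tuple[float, float]:
    """Like :func:`_path_steps` but averaging over every minimal pathway,
    counting a step into or out of a stop codon as nonsynonymous."""
    ca, cb = CODONS[a], CODONS[b]
    diff = [i for i in range(3) if ca[i] != cb[i]]
    syn_sum = non_sum = 0.0
    n_paths = 0
    for order in itertools.permutations(diff):
        cur = ca
        syn = non = 0
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            i, j = CODON_INDEX[cur], CODON_INDEX[nxt]
            if not IS_STOP[i] and not IS_STOP[j] and AA[i] == AA[j]:
                syn += 1
            else:
                non += 1
            cur = nxt
        syn_sum += syn
        non_sum += non
        n_paths += 1
    return syn_sum / n_paths, non_sum / n_paths


# SYN_DIFFS[a, b] / NONSYN_DIFFS[a, b]: pathway-averaged synonymous and
# nonsynonymous difference counts between two non-stop codons.
SYN_DIFFS = np.zeros((64, 64))
NONSYN_DIFFS = np.zeros((64, 64))
for a in range(64):
    if IS_STOP[a]:
        continue
    for b in range(64):
        if IS_STOP[b]:
            continue
        steps = _path_steps(a, b)
        if steps is None:
            steps = _path_steps_all(a, b)
        SYN_DIFFS[a, b], NONSYN_DIFFS[a, b] = steps


def codons_to_indices(seq: str) -> np.ndarray:
    """Encode an ungapped, unambiguous nucleotide string (length divisible by
    three) as an array of codon indices."""
    if len(seq) % 3:
        raise ValueError("sequence length is not a multiple of three")
    idx = np.empty(len(seq) // 3, dtype=np.int8)
    for i in range(0, len(seq), 3):
        idx[i // 3] = CODON_INDEX[seq[i : i + 3]]
    return idx


def indices_to_seq(idx: np.ndarray) -> str:
    return "".join(CODONS[i] for i in idx)
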
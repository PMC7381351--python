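"""Convenience codon alignment for synthetic gene families.

Real analyses align families with an external aligner and feed the aligned
FASTA to the divergence stage; this helper covers the synthetic fixtures.
Frame-intact families (every member length divisible by three) are aligned
at the amino-acid level and back-mapped to codons, which guarantees a
multiple-of-three alignment.  Families containing a frameshifted member are
returned as a right-padded placeholder alignment whose length reflects the
longest (shifted) member; such alignments fail the multiple-of-three screen
downstream, emulating the nucleotide-alignment frameshift filter.
"""

from __future__ import annotations

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .divergence import CodonAlignment
from .homology import GeneRecord


def _aa_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _aa_aligner()


def _translate(seq: str) -> str:
    aa = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        aa.append(str(Seq(codon).translate()) if set(codon) <= set("ACGT") else "X")
    return "".join(aa)


def _backmap(nt: str, aa_gapped: str) -> str:
    out = []
    k = 0
    for ch in aa_gapped:
        if ch == "-":
            out.append("---")
        else:
            out.append(nt[k : k + 3])
            k += 3
    return "".join(out)


def family_alignment(records: list[GeneRecord], name: str = "") -> CodonAlignment:
    """Codon alignment of one gene family (used on simulated fixtures)."""
    if not records:
        raise ValueError("empty family")
    seqs = [(r.gene_id, r.sequence.upper()) for r in records]
    if any(len(s) % 3 for _, s in seqs):
        # frameshifted member: placeholder padding, dropped by the frame screen
        maxlen = max(len(s) for _, s in seqs)
        return CodonAlignment(
            records=[(rid, s + "-" * (maxlen - len(s))) for rid, s in seqs],
            name=name,
        )
    lengths = {len(s) for _, s in seqs}
    if len(lengths) == 1:
        return CodonAlignment(records=seqs, name=name)
    if len(seqs) == 2:
        (id1, s1), (id2, s2) = seqs
        aln = _ALIGNER.align(_translate(s1), _translate(s2))[0]
        a1, a2 = str(aln[0]), str(aln[1])
        return CodonAlignment(
            records=[(id1, _backmap(s1, a1)), (id2, _backmap(s2, a2))], name=name
        )
    raise ValueError(
        "multi-sequence families with unequal lengths need an external aligner"
    )
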
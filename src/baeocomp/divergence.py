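"""Codon-level divergence estimation and rate tests.

Synonymous and nonsynonymous divergence (Ks, Ka) is estimated by the
Nei–Gojobori (1986) counting method with the Jukes–Cantor multiple-hit
correction.  Synonymous site counts treat each codon position as
contributing the fraction of its possible single-nucleotide changes that
are synonymous, with stop-creating changes excluded from the denominator;
multi-nucleotide codon differences are averaged over all minimal
substitution pathways, excluding pathways through stop codons.

On top of the estimator sit the horizontal-transfer screen — Ks computed in
non-overlapping windows of (at least) 500 synonymous sites along a
concatenated alignment, with an All-vs-Pair Mann–Whitney comparison — and
Tajima's relative rate test, which compares lineage-specific substitution
counts between two ingroup sequences against an outgroup with a 1-df
chi-square.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from scipy import stats

from ._codon import CODON_INDEX, IS_STOP, NONSYN_DIFFS, NONSYN_SITES, SYN_DIFFS, SYN_SITES

_ACGT = frozenset("ACGT")


@dataclass
class CodonAlignment:
    """A (possibly gapped) nucleotide alignment, one sequence per taxon."""

    records: list[tuple[str, str]]
    name: str = ""

    def __post_init__(self):
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) > 1:
            raise ValueError(f"{self.name or 'alignment'}: ragged sequence lengths {lengths}")

    @property
    def length(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    @property
    def multiple_of_three(self) -> bool:
        return self.length % 3 == 0

    @property
    def taxa(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def sequence(self, taxon: str) -> str:
        for rid, seq in self.records:
            if rid == taxon:
                return seq
        raise KeyError(taxon)


@dataclass(frozen=True)
class PairwiseDivergence:
    """NG86 site and difference counts with Jukes–Cantor-corrected rates."""

    S: float  # synonymous sites
    N: float  # nonsynonymous sites
    Sd: float  # synonymous differences
    Nd: float  # nonsynonymous differences
    p_s: float
    p_n: float
    Ks: float  # nan when the correction is undefined
    Ka: float
    n_codons: int

    @property
    def ks_defined(self) -> bool:
        return not math.isnan(self.Ks)

    @property
    def ka_defined(self) -> bool:
        return not math.isnan(self.Ka)


@dataclass
class KsWindowSeries:
    windows: list[tuple[int, float, float]]  # (index, syn_sites, Ks)
    source: str  # "all" or "pair:<strain>"

    @property
    def ks_values(self) -> list[float]:
        return [w[2] for w in self.windows]


@dataclass(frozen=True)
class RateTestResult:
    m1: int  # sites unique to lineage A
    m2: int  # sites unique to lineage B
    chi_square: float
    p_value: float
    mode: str  # third_codon | amino_acid
    n_sites: int


def _jc_correct(p: float) -> float:
    if p == 0.0:
        return 0.0
    arg = 1.0 - (4.0 / 3.0) * p
    if arg <= 0.0:
        return float("nan")
    return -0.75 * math.log(arg)


def _iter_codon_pairs(seq1: str, seq2: str):
    """Yield comparable codon-index pairs, skipping codons with gaps,
    ambiguity, or stop codons in either sequence."""
    for i in range(0, len(seq1) - len(seq1) % 3, 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if not (set(c1) <= _ACGT and set(c2) <= _ACGT):
            continue
        i1, i2 = CODON_INDEX[c1], CODON_INDEX[c2]
        if IS_STOP[i1] or IS_STOP[i2]:
            continue
        yield i1, i2


def ng86(seq1: str, seq2: str) -> PairwiseDivergence:
    """Nei–Gojobori divergence between two aligned coding sequences.

    The alignment must be a multiple of three; codons containing gaps or
    ambiguous bases in either sequence are skipped.
    """
    if len(seq1) != len(seq2):
        raise ValueError("aligned sequences differ in length")
    if len(seq1) % 3:
        raise ValueError("alignment length is not a multiple of three")
    seq1, seq2 = seq1.upper(), seq2.upper()
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i1, i2 in _iter_codon_pairs(seq1, seq2):
        S += 0.5 * (SYN_SITES[i1] + SYN_SITES[i2])
        N += 0.5 * (NONSYN_SITES[i1] + NONSYN_SITES[i2])
        Sd += SYN_DIFFS[i1, i2]
        Nd += NONSYN_DIFFS[i1, i2]
        n_codons += 1
    if n_codons == 0:
        raise ValueError("no comparable codons between the two sequences")
    p_s = Sd / S if S > 0 else 0.0
    p_n = Nd / N if N > 0 else 0.0
    return PairwiseDivergence(
        S=S, N=N, Sd=Sd, Nd=Nd, p_s=p_s, p_n=p_n,
        Ks=_jc_correct(p_s), Ka=_jc_correct(p_n), n_codons=n_codons,
    )


def filter_multiple_of_three(
    alignments: list[CodonAlignment],
) -> tuple[list[CodonAlignment], list[tuple[CodonAlignment, str]]]:
    """Split alignments into frame-intact ones (length divisible by three)
    and dropped ones; a non-multiple-of-three alignment indicates at least
    one frameshifted member."""
    kept, dropped = [], []
    for aln in alignments:
        if aln.multiple_of_three:
            kept.append(aln)
        else:
            dropped.append(
                (aln, f"length {aln.length} not a multiple of three (frameshift)")
            )
    return kept, dropped


def concatenate(
    alignments: list[CodonAlignment],
    ordering: list[str] | None = None,
    name: str = "concatenated",
) -> CodonAlignment:
    """Column-wise concatenation of same-taxa alignments in a given order."""
    if not alignments:
        raise ValueError("nothing to concatenate")
    by_name = {aln.name: aln for aln in alignments}
    if ordering is not None:
        missing = [n for n in ordering if n not in by_name]
        if missing:
            raise ValueError(f"unknown alignment name(s): {missing}")
        alignments = [by_name[n] for n in ordering]
    taxa = set(alignments[0].taxa)
    for aln in alignments[1:]:
        if set(aln.taxa) != taxa:
            raise ValueError(
                f"taxa mismatch: {sorted(taxa)} vs {sorted(aln.taxa)} in {aln.name}"
            )
    order = alignments[0].taxa
    parts = {t: [] for t in order}
    for aln in alignments:
        for t in order:
            parts[t].append(aln.sequence(t))
    return CodonAlignment(
        records=[(t, "".join(parts[t])) for t in order], name=name
    )


def windowed_ks(
    concatenated: CodonAlignment,
    taxon_a: str,
    taxon_b: str,
    window_syn_sites: float = 500.0,
    source: str = "all",
) -> KsWindowSeries:
    """Ks in non-overlapping windows along a concatenated alignment.

    Codons are scanned in order, accumulating pairwise synonymous sites; the
    first codon that pushes the cumulative count to ``window_syn_sites``
    closes the window (windows may slightly exceed the nominal size).  The
    trailing partial window is discarded.
    """
    if not concatenated.multiple_of_three:
        raise ValueError("concatenated alignment is not a multiple of three")
    seq1 = concatenated.sequence(taxon_a).upper()
    seq2 = concatenated.sequence(taxon_b).upper()
    windows = []
    cum_s = cum_sd = 0.0
    total_s = 0.0
    idx = 0
    for i1, i2 in _iter_codon_pairs(seq1, seq2):
        s = 0.5 * (SYN_SITES[i1] + SYN_SITES[i2])
        cum_s += s
        total_s += s
        cum_sd += SYN_DIFFS[i1, i2]
        if cum_s >= window_syn_sites:
            windows.append((idx, cum_s, _jc_correct(cum_sd / cum_s)))
            idx += 1
            cum_s = cum_sd = 0.0
    if not windows:
        warnings.warn(
            f"total synonymous sites {total_s:.1f} below the window size "
            f"{window_syn_sites:g}; empty series"
        )
    return KsWindowSeries(windows=windows, source=source)


def mann_whitney(
    all_series: list[float], pair_series: list[float]
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U comparison of two Ks samples.

    Exact enumeration when the combined sample size is at most 20 and there
    are no ties; otherwise the normal approximation with tie correction.
    """
    x, y = list(all_series), list(pair_series)
    if not x or not y:
        raise ValueError("both samples must be non-empty")
    combined = x + y
    no_ties = len(set(combined)) == len(combined)
    method = "exact" if (len(combined) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _clean_columns(seqs: list[str], positions) -> list[tuple]:
    cols = []
    for i in positions:
        col = tuple(s[i] for s in seqs)
        if all(c in _ACGT for c in col):
            cols.append(col)
    return cols


def tajima_rrt(
    seq_a: str, seq_b: str, outgroup: str, mode: str = "third_codon"
) -> RateTestResult:
    """Tajima's relative rate test for two lineages against an outgroup.

    ``m1`` counts sites where A alone differs (B agrees with the outgroup),
    ``m2`` the symmetric count; under equal rates m1 and m2 have equal
    expectation and (m1-m2)^2/(m1+m2) is approximately chi-square with one
    degree of freedom.
    """
    if not (len(seq_a) == len(seq_b) == len(outgroup)):
        raise ValueError("the three sequences must have equal aligned length")
    if mode not in ("third_codon", "amino_acid"):
        raise ValueError(f"unknown mode {mode}")
    seqs = [seq_a.upper(), seq_b.upper(), outgroup.upper()]
    n_codons = len(seq_a) // 3
    if mode == "third_codon":
        cols = _clean_columns(seqs, range(2, 3 * n_codons, 3))
    else:
        cols = []
        for i in range(0, 3 * n_codons, 3):
            codons = [s[i : i + 3] for s in seqs]
            if all(set(c) <= _ACGT for c in codons):
                cols.append(tuple(str(Seq(c).translate()) for c in codons))
    m1 = sum(1 for a, b, o in cols if a != b and a != o and b == o)
    m2 = sum(1 for a, b, o in cols if a != b and b != o and a == o)
    if m1 + m2 == 0:
        chi = 0.0
        p = 1.0
    else:
        chi = (m1 - m2) ** 2 / (m1 + m2)
        p = float(stats.chi2.sf(chi, df=1))
    return RateTestResult(
        m1=m1, m2=m2, chi_square=chi, p_value=p, mode=mode, n_sites=len(cols)
    )


# ---------------------------------------------------------------------------
# IO


def read_alignment(path: str | Path, name: str | None = None) -> CodonAlignment:
    """Read an aligned FASTA file into a :class:`CodonAlignment`."""
    path = Path(path)
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]
    if not records:
        raise ValueError(f"{path}: no sequences")
    return CodonAlignment(records=records, name=name or path.stem)


def divergence_to_dict(div: PairwiseDivergence) -> dict:
    return dict(
        S=div.S, N=div.N, Sd=div.Sd, Nd=div.Nd,
        p_s=div.p_s, p_n=div.p_n, Ks=div.Ks, Ka=div.Ka, n_codons=div.n_codons,
    )
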
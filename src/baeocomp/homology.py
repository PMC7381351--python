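"""Reciprocal-best-hit homology classification.

Every gene of a query strain is labeled against each subject strain as
``ortholog`` (forward best hit whose own best hit back into the query strain
is the original gene), ``paralog`` (forward hit exists but the reciprocal
search lands on a different query gene, typically a closer duplicate), or
``no_similarity`` (no forward hit above the score threshold).

The built-in scorer compares the translations of the two nucleotide
sequences in all three forward reading frames of each and takes the best
frame-pair local alignment score under BLOSUM62 with affine gaps.  A raw
score threshold stands in for a search-tool E-value; precomputed tabular
hits can be substituted through :func:`rbh_from_tables`.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

ANNOTATION_CATEGORIES = (
    "conserved_or_function",
    "transposase",
    "nonconserved_unknown",
    "unannotated",
)

COMPARTMENTS = ("chromosome", "plasmid", "unclassified")

DEFAULT_SCORE_MIN = 50.0


@dataclass(frozen=True)
class GeneRecord:
    """One coding sequence with its strain and annotation labels."""

    gene_id: str
    strain_id: str
    sequence: str
    compartment: str = "unclassified"
    annotation_category: str = "unannotated"

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.gene_id}: empty sequence")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"{self.gene_id}: bad compartment {self.compartment}")
        if self.annotation_category not in ANNOTATION_CATEGORIES:
            raise ValueError(
                f"{self.gene_id}: bad annotation category {self.annotation_category}"
            )


@dataclass(frozen=True)
class HomologyCall:
    query_gene: str
    subject_strain: str
    label: str  # ortholog | paralog | no_similarity
    forward_best: str | None
    reverse_best: str | None
    forward_score: float

    def __post_init__(self):
        if self.label not in ("ortholog", "paralog", "no_similarity"):
            raise ValueError(f"bad label {self.label}")
        if (self.label == "no_similarity") != (self.forward_best is None):
            raise ValueError("no_similarity iff no forward best hit")


def _make_aligner() -> Align.PairwiseAligner:
    matrix = substitution_matrices.load("BLOSUM62")
    arr = np.array(matrix)
    alphabet = matrix.alphabet
    x = alphabet.index("X")
    arr[x, :] = 0.0  # unknown residues score 0 against everything
    arr[:, x] = 0.0
    matrix = substitution_matrices.Array(alphabet=alphabet, dims=2, data=arr)
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()
_ALPHABET = set(_ALIGNER.substitution_matrix.alphabet)


@functools.lru_cache(maxsize=100000)
def translate_frames(sequence: str, include_reverse: bool = False) -> tuple[str, ...]:
    """Translations of a nucleotide sequence in its three forward frames
    (optionally also the three reverse-complement frames).

    Codons containing N or other ambiguity translate to X.  Frames shorter
    than one codon are dropped; an error is raised if no frame survives.
    """
    strands = [sequence.upper()]
    if include_reverse:
        strands.append(str(Seq(sequence.upper()).reverse_complement()))
    frames = []
    for strand in strands:
        for f in range(3):
            sub = strand[f:]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            aa = []
            for i in range(0, len(sub), 3):
                codon = sub[i : i + 3]
                if set(codon) <= set("ACGT"):
                    aa.append(str(Seq(codon).translate()))
                else:
                    aa.append("X")
            frames.append("".join(aa))
    if not frames:
        raise ValueError("sequence shorter than one codon in every frame")
    return tuple(frames)


@functools.lru_cache(maxsize=1 << 20)
def _cached_pair_score(seq1: str, seq2: str, include_reverse: bool) -> float:
    best = 0.0
    for qf in translate_frames(seq1, include_reverse):
        for sf in translate_frames(seq2, include_reverse):
            s = _ALIGNER.score(qf, sf)
            if s > best:
                best = s
    return best


def pair_score(query_seq: str, subject_seq: str, include_reverse: bool = False) -> float:
    """Best frame-pair local alignment score between two coding sequences.

    The score is symmetric in the two sequences, so forward and reciprocal
    searches share one cache entry per pair.
    """
    a, b = sorted((query_seq.upper(), subject_seq.upper()))
    return _cached_pair_score(a, b, include_reverse)


def best_hit(
    query: GeneRecord,
    subject_set: list[GeneRecord],
    score_threshold: float = DEFAULT_SCORE_MIN,
    include_reverse: bool = False,
) -> tuple[str | None, float]:
    """Subject gene with the maximal translated-similarity score to the
    query, or ``None`` if no subject reaches the threshold.

    Ties are broken by lexicographically smallest gene id.
    """
    if not subject_set:
        raise ValueError("subject set is empty")
    best_id: str | None = None
    best_score = -np.inf
    for rec in subject_set:
        s = pair_score(query.sequence, rec.sequence, include_reverse)
        if s > best_score or (s == best_score and best_id is not None and rec.gene_id < best_id):
            best_id, best_score = rec.gene_id, s
    if best_score < score_threshold:
        return None, best_score
    return best_id, best_score


def classify_rbh(
    query: GeneRecord,
    query_strain_set: list[GeneRecord],
    subject_set: list[GeneRecord],
    score_threshold: float = DEFAULT_SCORE_MIN,
    include_reverse: bool = False,
) -> HomologyCall:
    """Reciprocal-best-hit label of one query gene against one subject strain."""
    if all(rec.gene_id != query.gene_id for rec in query_strain_set):
        raise ValueError(f"{query.gene_id} not in its own strain set")
    fwd_id, fwd_score = best_hit(query, subject_set, score_threshold, include_reverse)
    if fwd_id is None:
        return HomologyCall(
            query_gene=query.gene_id,
            subject_strain=subject_set[0].strain_id,
            label="no_similarity",
            forward_best=None,
            reverse_best=None,
            forward_score=fwd_score,
        )
    fwd_rec = next(rec for rec in subject_set if rec.gene_id == fwd_id)
    rev_id, _ = best_hit(fwd_rec, query_strain_set, score_threshold, include_reverse)
    label = "ortholog" if rev_id == query.gene_id else "paralog"
    return HomologyCall(
        query_gene=query.gene_id,
        subject_strain=fwd_rec.strain_id,
        label=label,
        forward_best=fwd_id,
        reverse_best=rev_id,
        forward_score=fwd_score,
    )


def classify_all(
    query_strain_set: list[GeneRecord],
    subject_sets: dict[str, list[GeneRecord]],
    score_threshold: float = DEFAULT_SCORE_MIN,
    include_reverse: bool = False,
) -> list[HomologyCall]:
    """RBH calls for every (query gene, subject strain) pair."""
    calls = []
    for strain, subject_set in subject_sets.items():
        for query in query_strain_set:
            calls.append(
                classify_rbh(
                    query, query_strain_set, subject_set, score_threshold, include_reverse
                )
            )
    return calls


def summarize_homology(
    calls: list[HomologyCall],
    total_query_genes: int,
    strains: list[str] | None = None,
) -> pd.DataFrame:
    """Per-subject-strain ortholog/paralog/no-similarity counts and
    percentages of the query-strain gene count (one decimal).

    The three labels partition the query genes for every strain; the table
    mirrors the classic shared-gene summary of comparative studies.
    """
    seen = set()
    for c in calls:
        key = (c.query_gene, c.subject_strain)
        if key in seen:
            raise ValueError(f"duplicate call for {key}")
        seen.add(key)
    df = pd.DataFrame(
        [(c.subject_strain, c.label) for c in calls], columns=["strain", "label"]
    )
    present = set(df.strain.unique())
    if strains is not None:
        missing = set(strains) - present
        if missing:
            raise ValueError(f"no calls for strain(s): {sorted(missing)}")
        order = list(strains)
    else:
        order = sorted(present)
    counts = (
        df.groupby(["strain", "label"]).size().unstack(fill_value=0).reindex(order)
    )
    for col in ("ortholog", "paralog", "no_similarity"):
        if col not in counts:
            counts[col] = 0
    counts = counts[["ortholog", "paralog", "no_similarity"]]
    bad = counts.sum(axis=1) != total_query_genes
    if bad.any():
        raise ValueError(
            f"labels do not partition {total_query_genes} query genes for "
            f"strain(s) {list(counts.index[bad])}"
        )
    out = counts.rename(
        columns={
            "ortholog": "orthologs",
            "paralog": "paralogs",
            "no_similarity": "no_similarity",
        }
    )
    for col in ("orthologs", "paralogs", "no_similarity"):
        out[f"{col}_pct"] = (100.0 * out[col] / total_query_genes).round(1)
    return out


def union_no_similarity(calls: list[HomologyCall]) -> set[str]:
    """Genes labeled ``no_similarity`` against every subject strain."""
    strains = {c.subject_strain for c in calls}
    by_gene: dict[str, dict[str, str]] = {}
    for c in calls:
        by_gene.setdefault(c.query_gene, {})[c.subject_strain] = c.label
    for gene, labels in by_gene.items():
        if set(labels) != strains:
            raise ValueError(f"{gene}: calls do not cover every strain")
    return {
        gene
        for gene, labels in by_gene.items()
        if all(lbl == "no_similarity" for lbl in labels.values())
    }


# ---------------------------------------------------------------------------
# precomputed-hit-table route


def rbh_from_tables(
    forward: pd.DataFrame,
    reverse: pd.DataFrame,
    subject_strain: str,
    query_genes: list[str],
    score_threshold: float = DEFAULT_SCORE_MIN,
) -> list[HomologyCall]:
    """RBH calls from precomputed tabular hits (columns: query, subject,
    score), e.g. parsed search-tool output, instead of the built-in scorer."""

    def best_map(df: pd.DataFrame) -> dict[str, tuple[str, float]]:
        out: dict[str, tuple[str, float]] = {}
        for row in df.itertuples():
            cur = out.get(row.query)
            if (
                cur is None
                or row.score > cur[1]
                or (row.score == cur[1] and row.subject < cur[0])
            ):
                out[row.query] = (row.subject, float(row.score))
        return out

    fwd = best_map(forward)
    rev = best_map(reverse)
    calls = []
    for gene in query_genes:
        hit = fwd.get(gene)
        if hit is None or hit[1] < score_threshold:
            calls.append(
                HomologyCall(gene, subject_strain, "no_similarity", None, None,
                             hit[1] if hit else 0.0)
            )
            continue
        subj, score = hit
        back = rev.get(subj)
        rev_id = back[0] if back and back[1] >= score_threshold else None
        label = "ortholog" if rev_id == gene else "paralog"
        calls.append(HomologyCall(gene, subject_strain, label, subj, rev_id, score))
    return calls


def calls_to_frame(calls: list[HomologyCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                query_gene=c.query_gene,
                subject_strain=c.subject_strain,
                label=c.label,
                forward_best=c.forward_best or "",
                reverse_best=c.reverse_best or "",
                forward_score=c.forward_score,
            )
            for c in calls
        ]
    )


def calls_from_frame(df: pd.DataFrame) -> list[HomologyCall]:
    return [
        HomologyCall(
            query_gene=row.query_gene,
            subject_strain=row.subject_strain,
            label=row.label,
            forward_best=row.forward_best or None,
            reverse_best=row.reverse_best or None,
            forward_score=float(row.forward_score),
        )
        for row in df.itertuples()
    ]
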
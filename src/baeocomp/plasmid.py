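"""Plasmid-location screening and enrichment testing.

Plasmid-prediction probabilities (as produced by composition-based
classifiers) are thresholded into chromosome / plasmid / unclassified
labels; following the convention that a prediction below threshold is not
evidence of plasmid origin, unclassified sequences are treated as
chromosomal when computing effective fractions and contingency tables.

The enrichment question: genes shared between the focal strain and exactly
one other strain ("pair-specific", the HGT candidates) versus genes with
orthologs in every strain — are the former more often plasmid-located?
Tested per subject strain with a two-sided Fisher exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats


@dataclass
class CompartmentCall:
    entity_id: str  # contig or gene id
    label: str  # chromosome | plasmid | unclassified
    plasmid_probability: float | None = None
    chromosome_probability: float | None = None

    @property
    def effective_label(self) -> str:
        return "plasmid" if self.label == "plasmid" else "chromosome"


@dataclass(frozen=True)
class Contingency2x2:
    """Rows: (pair_specific, all_strain_orthologs); columns: (plasmid, chromosome)."""

    a: int  # pair-specific, plasmid
    b: int  # pair-specific, chromosome
    c: int  # all-strain orthologs, plasmid
    d: int  # all-strain orthologs, chromosome

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative count")
        if (self.a + self.b + self.c + self.d) == 0:
            raise ValueError("empty table")


@dataclass(frozen=True)
class FisherResult:
    p_two_sided: float
    odds_ratio: float  # inf when b*c == 0 and a*d > 0

    @property
    def odds_ratio_infinite(self) -> bool:
        return math.isinf(self.odds_ratio)


def apply_threshold(
    probabilities: pd.DataFrame, threshold: float = 0.7
) -> list[CompartmentCall]:
    """Threshold classifier probabilities into compartment labels.

    ``probabilities`` needs columns id (or gene_id/contig_id),
    chromosome_prob, plasmid_prob.  A sequence is called plasmid
    (chromosome) when that class's probability reaches the threshold, and
    unclassified otherwise.
    """
    if not 0.5 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0.5, 1]")
    id_col = next(
        c for c in ("id", "gene_id", "contig_id") if c in probabilities.columns
    )
    calls = []
    for row in probabilities.itertuples():
        p_pl = float(getattr(row, "plasmid_prob"))
        p_chr = float(getattr(row, "chromosome_prob"))
        if p_pl >= threshold:
            label = "plasmid"
        elif p_chr >= threshold:
            label = "chromosome"
        else:
            label = "unclassified"
        calls.append(
            CompartmentCall(
                entity_id=str(getattr(row, id_col)),
                label=label,
                plasmid_probability=p_pl,
                chromosome_probability=p_chr,
            )
        )
    return calls


def plasmid_fraction(
    calls: list[CompartmentCall], weights: dict[str, float] | None = None
) -> float:
    """Fraction of genome base pairs (or of sequences, when unweighted)
    whose effective label is plasmid."""
    if not calls:
        raise ValueError("no compartment calls")
    if weights is None:
        weights = {c.entity_id: 1.0 for c in calls}
    total = sum(weights[c.entity_id] for c in calls)
    if total == 0:
        raise ValueError("zero total length")
    plasmid = sum(
        weights[c.entity_id] for c in calls if c.effective_label == "plasmid"
    )
    return plasmid / total


def fisher_exact(table: Contingency2x2) -> FisherResult:
    """Two-sided Fisher exact test (minimum-likelihood rule) on a 2x2 table."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError("a margin of the table is zero")
    res = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = math.inf if a * d > 0 else 0.0
    else:
        odds = (a * d) / (b * c)
    return FisherResult(p_two_sided=float(res.pvalue), odds_ratio=odds)


def enrichment_pipeline(
    pair_gene_sets: dict[str, set[str]],
    all_ortholog_sets: dict[str, set[str]],
    compartments: dict[str, str],
) -> dict[str, tuple[Contingency2x2, FisherResult]]:
    """Per-strain plasmid-location enrichment of pair-specific genes.

    ``pair_gene_sets`` maps each subject strain to the gene ids shared with
    the focal strain only; ``all_ortholog_sets`` maps it to the genes with
    orthologs in every strain (the core); ``compartments`` gives each gene's
    effective label (unclassified already folded into chromosome).
    """
    results = {}
    for strain, pair_genes in pair_gene_sets.items():
        core = all_ortholog_sets[strain]
        overlap = pair_genes & core
        if overlap:
            raise ValueError(
                f"{strain}: genes in both pair-specific and core sets: "
                f"{sorted(overlap)[:5]}"
            )
        missing = [g for g in (pair_genes | core) if g not in compartments]
        if missing:
            raise ValueError(f"{strain}: no compartment for {missing[:5]}")

        def n_plasmid(genes):
            return sum(
                1 for g in genes
                if ("plasmid" if compartments[g] == "plasmid" else "chromosome")
                == "plasmid"
            )

        a = n_plasmid(pair_genes)
        b = len(pair_genes) - a
        c = n_plasmid(core)
        d = len(core) - c
        table = Contingency2x2(a=a, b=b, c=c, d=d)
        results[strain] = (table, fisher_exact(table))
    return results


def threshold_sweep(
    probabilities: pd.DataFrame,
    thresholds: tuple[float, ...] = (0.7, 0.75, 0.8, 0.85),
    weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Plasmid genome fraction at each probability threshold."""
    rows = []
    for t in thresholds:
        calls = apply_threshold(probabilities, t)
        rows.append(dict(threshold=t, plasmid_fraction=plasmid_fraction(calls, weights)))
    return pd.DataFrame(rows)
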
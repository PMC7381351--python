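"""Presence/absence inventory of focal-strain genes across comparison strains.

A gene is *present* in a subject strain when its homology label there is
ortholog or paralog, and *absent* when it is no_similarity.  Genes are
grouped into absence classes: class k collects genes absent in exactly k of
the comparison strains (class 0 = present everywhere, class 6 = focal-strain
specific when six strains are compared).  Per-class annotation-category
profiles and per-strain absence frequencies summarize which kinds of genes
go missing and from which lineages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .homology import GeneRecord, HomologyCall

PROFILE_CATEGORIES = ("conserved_or_function", "transposase", "nonconserved_unknown")


@dataclass
class PresenceMatrix:
    """Boolean genes x strains presence with per-gene class and category."""

    presence: pd.DataFrame  # index gene_id, columns strains, bool
    classes: pd.Series  # per gene: number of absent strains
    categories: pd.Series  # per gene: annotation category

    @property
    def strains(self) -> list[str]:
        return list(self.presence.columns)

    def genes_in_class(self, k: int) -> list[str]:
        return list(self.classes.index[self.classes == k])


def build_matrix(
    calls: list[HomologyCall], genes: list[GeneRecord]
) -> PresenceMatrix:
    """Presence/absence matrix from RBH calls over the focal strain's genes."""
    strains = sorted({c.subject_strain for c in calls})
    gene_ids = [g.gene_id for g in genes]
    label_map: dict[tuple[str, str], str] = {}
    for c in calls:
        label_map[(c.query_gene, c.subject_strain)] = c.label
    data = {}
    for s in strains:
        col = []
        for gid in gene_ids:
            label = label_map.get((gid, s))
            if label is None:
                raise ValueError(f"missing call for ({gid}, {s})")
            col.append(label != "no_similarity")
        data[s] = col
    presence = pd.DataFrame(data, index=gene_ids)
    classes = (~presence).sum(axis=1)
    categories = pd.Series(
        {g.gene_id: g.annotation_category for g in genes}, name="category"
    ).reindex(gene_ids)
    return PresenceMatrix(presence=presence, classes=classes, categories=categories)


def class_category_profile(matrix: PresenceMatrix) -> pd.DataFrame:
    """Per-class fractions of the three annotated categories.

    Unannotated genes are excluded (with a warning); fractions per class sum
    to one over the included categories.  Empty classes yield all-NaN rows.
    """
    n_unannot = int((matrix.categories == "unannotated").sum())
    if n_unannot:
        warnings.warn(f"excluding {n_unannot} unannotated gene(s) from the profile")
    keep = matrix.categories.isin(PROFILE_CATEGORIES)
    classes = matrix.classes[keep]
    cats = matrix.categories[keep]
    n_strains = len(matrix.strains)
    rows = {}
    for k in range(n_strains + 1):
        in_class = cats[classes == k]
        if len(in_class) == 0:
            rows[k] = {c: np.nan for c in PROFILE_CATEGORIES}
        else:
            counts = in_class.value_counts()
            rows[k] = {
                c: counts.get(c, 0) / len(in_class) for c in PROFILE_CATEGORIES
            }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "class"
    return out


def strain_absence_frequency(matrix: PresenceMatrix) -> pd.DataFrame:
    """For classes 1-5: per-strain counts of membership in the absent set.

    Row k sums to k times the number of genes in class k.  Class 6 carries
    no informative strain pattern and is omitted; for the class of genes
    shared with exactly one other strain, see
    :func:`class5_presence_frequency`.
    """
    n_strains = len(matrix.strains)
    top = min(5, n_strains - 1)
    rows = {}
    for k in range(1, top + 1):
        gene_ids = matrix.genes_in_class(k)
        absent = ~matrix.presence.loc[gene_ids]
        rows[k] = absent.sum(axis=0)
    out = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    out.index.name = "class"
    return out


def class5_presence_frequency(matrix: PresenceMatrix) -> pd.Series:
    """For genes absent in all but one comparison strain: how often each
    strain is the single one retaining the gene (the present-in-pair view)."""
    k = len(matrix.strains) - 1
    gene_ids = matrix.genes_in_class(k)
    present = matrix.presence.loc[gene_ids]
    return present.sum(axis=0)


def class_sizes(matrix: PresenceMatrix) -> pd.Series:
    n_strains = len(matrix.strains)
    return matrix.classes.value_counts().reindex(
        range(n_strains + 1), fill_value=0
    ).rename("n_genes")
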
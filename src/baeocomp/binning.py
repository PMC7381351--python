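"""Taxonomic contig binning by hit-profile decision rules.

A non-axenic cyanobacterial culture sequenced as a metagenome yields an
assembly mixing cyanobacterial contigs with proteobacterial/CFB
contaminants.  Each contig carries the top hits (at most 20) of a
translated search against a mixed proteome database; the rules are:

* every hit cyanobacterial -> retain outright;
* a strict majority of cyanobacterial hits AND fold-coverage above the
  cutoff AND a best cyanobacterial identity clearly above the best
  non-cyanobacterial identity -> retain after curation;
* otherwise discard.

A second, composition-based binner's labels are then reconciled: contigs it
calls cyanobacterial but that the hit rules discarded for having mixed
high-identity hits are excluded as ambiguous; contigs the hit rules retained
against the second binner's vote are kept but flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

TAXON_GROUPS = ("cyanobacteria", "proteobacteria", "cfb", "other")

HIGH_IDENTITY = 70.0  # both-sides identity floor for the ambiguity rule


@dataclass
class ContigHitProfile:
    """Top translated-search hits for one contig, sorted by descending score."""

    contig_id: str
    length_bp: int
    coverage: float
    hits: list[tuple[str, float, float]]  # (taxon_group, percent_identity, score)

    def __post_init__(self):
        if len(self.hits) > 20:
            raise ValueError(f"{self.contig_id}: more than 20 hits")
        for grp, ident, score in self.hits:
            if grp not in TAXON_GROUPS:
                raise ValueError(f"{self.contig_id}: unknown taxon group {grp}")
            if not 0.0 <= ident <= 100.0:
                raise ValueError(f"{self.contig_id}: identity {ident} outside [0, 100]")
        scores = [h[2] for h in self.hits]
        if scores != sorted(scores, reverse=True):
            raise ValueError(f"{self.contig_id}: hits not sorted by descending score")


@dataclass(frozen=True)
class BinDecision:
    contig_id: str
    decision: str  # retain_all_cyano | retain_curated | discard | excluded_ambiguous
    reason: str


@dataclass
class CongruenceResult:
    retained: list[str]
    congruence_fraction: float
    excluded: list[str]
    flagged: list[str] = field(default_factory=list)
    decisions: dict[str, BinDecision] = field(default_factory=dict)


def classify_contig(
    profile: ContigHitProfile,
    coverage_min: float = 70.0,
    identity_margin: float = 10.0,
) -> BinDecision:
    """Apply the hit-profile rules to one contig."""
    if not profile.hits:
        return BinDecision(profile.contig_id, "discard", "no hits")
    cyano = [h for h in profile.hits if h[0] == "cyanobacteria"]
    other = [h for h in profile.hits if h[0] != "cyanobacteria"]
    if not other:
        return BinDecision(
            profile.contig_id, "retain_all_cyano", "all hits cyanobacterial"
        )
    if len(cyano) <= len(other):
        return BinDecision(
            profile.contig_id, "discard", "no cyanobacterial hit majority"
        )
    best_cyano = max(h[1] for h in cyano)
    best_other = max(h[1] for h in other)
    margin = best_cyano - best_other
    if profile.coverage <= coverage_min:
        return BinDecision(
            profile.contig_id,
            "discard",
            f"coverage {profile.coverage:.1f} not above {coverage_min:g}",
        )
    if margin >= identity_margin:
        return BinDecision(
            profile.contig_id,
            "retain_curated",
            f"cyano majority, coverage ok, identity margin {margin:.1f}",
        )
    if best_cyano >= HIGH_IDENTITY and best_other >= HIGH_IDENTITY:
        return BinDecision(
            profile.contig_id,
            "discard",
            "mixed_high_identity",
        )
    return BinDecision(
        profile.contig_id,
        "discard",
        f"identity margin {margin:.1f} below {identity_margin:g}",
    )


def congruence_filter(
    decisions: list[BinDecision],
    binner2_labels: dict[str, str],
) -> CongruenceResult:
    """Reconcile hit-rule decisions with a second binner's labels.

    The congruence fraction is the share of contigs retained by either
    method on which the two agree.  Contigs the second binner calls
    cyanobacterial but the hit rules discarded for mixed high-identity
    profiles are excluded as ambiguous (neither retained nor counted as
    cyanobacterial); contigs retained by the hit rules against the second
    binner's vote are retained but flagged.
    """
    missing = [d.contig_id for d in decisions if d.contig_id not in binner2_labels]
    if missing:
        raise ValueError(f"missing second-binner label for: {missing[:5]}")
    final: dict[str, BinDecision] = {}
    retained, excluded, flagged = [], [], []
    either = agree = 0
    for d in decisions:
        hit_retain = d.decision in ("retain_all_cyano", "retain_curated")
        b2_cyano = binner2_labels[d.contig_id] == "cyanobacterial"
        if hit_retain or b2_cyano:
            either += 1
            if hit_retain and b2_cyano:
                agree += 1
        if hit_retain:
            retained.append(d.contig_id)
            if not b2_cyano:
                flagged.append(d.contig_id)
            final[d.contig_id] = d
        elif b2_cyano and d.reason == "mixed_high_identity":
            final[d.contig_id] = BinDecision(
                d.contig_id,
                "excluded_ambiguous",
                "second binner cyanobacterial but hit profile mixed at high identity",
            )
            excluded.append(d.contig_id)
        else:
            final[d.contig_id] = d
    fraction = agree / either if either else 1.0
    return CongruenceResult(
        retained=retained,
        congruence_fraction=fraction,
        excluded=excluded,
        flagged=flagged,
        decisions=final,
    )


# ---------------------------------------------------------------------------
# tabular IO


def load_hit_profiles(hits_path: str | Path, contigs_path: str | Path) -> list[ContigHitProfile]:
    """Read hit profiles from a tab-separated hit table (contig_id,
    taxon_group, percent_identity, score) plus a contig metadata table
    (contig_id, length_bp, coverage)."""
    hits = pd.read_csv(hits_path, sep="\t")
    meta = pd.read_csv(contigs_path, sep="\t").set_index("contig_id")
    profiles = []
    for contig_id, grp in hits.groupby("contig_id", sort=True):
        grp = grp.sort_values("score", ascending=False).head(20)
        row = meta.loc[contig_id]
        profiles.append(
            ContigHitProfile(
                contig_id=str(contig_id),
                length_bp=int(row.length_bp),
                coverage=float(row.coverage),
                hits=[
                    (h.taxon_group, float(h.percent_identity), float(h.score))
                    for h in grp.itertuples()
                ],
            )
        )
    # contigs with metadata but no hits at all
    for contig_id in meta.index.difference(hits.contig_id.unique()):
        row = meta.loc[contig_id]
        profiles.append(
            ContigHitProfile(
                contig_id=str(contig_id),
                length_bp=int(row.length_bp),
                coverage=float(row.coverage),
                hits=[],
            )
        )
    return profiles


def decisions_to_frame(decisions: list[BinDecision] | dict[str, BinDecision]) -> pd.DataFrame:
    if isinstance(decisions, dict):
        decisions = list(decisions.values())
    return pd.DataFrame(
        [dict(contig_id=d.contig_id, decision=d.decision, reason=d.reason) for d in decisions]
    )
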
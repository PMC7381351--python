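"""Synthetic multi-strain coding-sequence sets with known ground truth.

The generator emulates the structure of a small clade of baeocyte-forming
cyanobacteria: seven strains related by a fixed rooted tree, per-gene codon
evolution with separately tunable synonymous and nonsynonymous rates, gene
duplication in a focal lineage, lineage-specific losses, pair-restricted
horizontal transfers with reduced divergence, chromosome/plasmid compartment
labels, and frameshift corruption in a fraction of emitted sequences.  Every
stochastic choice flows from one integer seed, and the full substitution
event log is retained so that realized divergence can be audited
independently of the Ks estimator.

Branch lengths are expected *proposed* substitutions per nucleotide site.
Synonymous proposals are always accepted, so the synonymous divergence per
synonymous site between two tips is, to first order, their patristic
distance; nonsynonymous proposals are thinned by ``omega``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from ._codon import (
    ALT_NUC,
    CODONS,
    IS_STOP,
    IS_STOP_MUT,
    IS_SYN_MUT,
    NEIGHBOR,
    indices_to_seq,
)
from .homology import ANNOTATION_CATEGORIES, GeneRecord

# plain-Python copies: scalar indexing in the event loop is much faster on
# nested lists than on numpy arrays
_NEIGH = NEIGHBOR.tolist()
_SYN = IS_SYN_MUT.tolist()
_STOPM = IS_STOP_MUT.tolist()
_NONSTOP_CODONS = [i for i in range(64) if not IS_STOP[i]]

#: seven-strain rooted tree whose patristic distances span the synonymous
#: divergence range observed among baeocyte-forming cyanobacteria
#: (sister pairs at ~0.28 and ~1.8 synonymous substitutions per site)
DEFAULT_TREE = (
    "((Hyella:0.25,(Chroococcidiopsis:0.20,Xenococcus:0.25):0.10):0.15,"
    "((Myxosarcina:0.90,Pleurocapsa:0.90):0.20,"
    "(Stanieria_PCC7437:0.14,Stanieria_NIES3757:0.14):0.30):0.05);"
)

DEFAULT_CATEGORY_PROBS = {
    "conserved_or_function": 0.65,
    "transposase": 0.05,
    "nonconserved_unknown": 0.25,
    "unannotated": 0.05,
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic strain set.

    Fractions are in [0, 1]; the tree must have exactly ``n_strains`` leaves.
    The first leaf (in newick order) is the focal strain: duplications land
    there by default, and it is the donor of every transfer.
    """

    n_strains: int = 7
    tree: str = DEFAULT_TREE
    n_families: int = 60
    codon_length: int = 150
    omega: float = 0.2
    dup_fraction: float = 0.20
    loss_fraction: float = 0.15
    hgt_fraction: float = 0.10
    hgt_divergence_scale: float = 0.3
    plasmid_fraction: float = 0.15
    frameshift_fraction: float = 0.10
    seed: int = 0
    dup_strain: str | None = None
    loss_strains: tuple[str, ...] | None = None
    hgt_recipient: str | None = None
    hgt_plasmid_boost: float = 5.0
    dup_extra_branch: float = 0.05
    ambiguous_compartment_rate: float = 0.15
    category_probs: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORY_PROBS))

    def validate(self) -> None:
        for name in (
            "dup_fraction",
            "loss_fraction",
            "hgt_fraction",
            "plasmid_fraction",
            "frameshift_fraction",
            "ambiguous_compartment_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.codon_length < 10:
            raise ValueError("codon_length must be at least 10")
        if not 0.0 < self.omega <= 1.0:
            raise ValueError("omega must be in (0, 1]")
        if not 0.0 < self.hgt_divergence_scale <= 1.0:
            raise ValueError("hgt_divergence_scale must be in (0, 1]")


@dataclass
class SimTruth:
    """Ground truth for one simulated strain set.

    ``genes`` has one row per emitted gene (gene_id, strain, family, copy,
    relation_map, hgt_flag, compartment, frameshift_flag, category and the
    observed compartment probabilities).  ``events`` is the accepted
    substitution log: (family, edge, codon, pos, old_codon, new_codon), with
    codon indices referring to :data:`baeocomp._codon.CODONS`.
    """

    genes: pd.DataFrame
    events: pd.DataFrame
    tree_newick: str
    config: SimConfig

    def relation(self, gene_id: str, strain: str) -> str:
        row = self.genes.loc[self.genes.gene_id == gene_id].iloc[0]
        return dict(
            item.split(":") for item in row.relation_map.split(";")
        )[strain]


def _parse_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return tree


def _leaf_names(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label.replace(" ", "_") for leaf in tree.leaf_node_iter()]


def _mutate(seq: list[int], t: float, omega: float, rng: np.random.Generator,
            family: int, edge: str, events: list) -> list[int]:
    """Evolve a codon-index sequence along a branch of length ``t`` expected
    proposed substitutions per nucleotide site.

    Candidate changes that would create a stop codon are rejected and
    redrawn; nonsynonymous changes are accepted with probability ``omega``.
    Accepted events are appended to ``events``.
    """
    seq = list(seq)
    n_codons = len(seq)
    n_sites = 3 * n_codons
    n_prop = int(rng.poisson(t * n_sites))
    if n_prop == 0:
        return seq
    positions = rng.integers(0, n_sites, size=n_prop)
    alts = rng.integers(0, 3, size=n_prop)
    accept_draws = rng.random(n_prop)
    for k in range(n_prop):
        p = int(positions[k])
        a = int(alts[k])
        ci = p // 3
        off = p - 3 * ci
        old = seq[ci]
        # stop-creating proposals: reject and redraw (position and target)
        while _STOPM[old][off][a]:
            p = int(rng.integers(0, n_sites))
            a = int(rng.integers(0, 3))
            ci = p // 3
            off = p - 3 * ci
            old = seq[ci]
        if _SYN[old][off][a]:
            accepted = True
        else:
            accepted = accept_draws[k] < omega
        if accepted:
            new = _NEIGH[old][off][a]
            seq[ci] = new
            events.append((family, edge, ci, off, old, new))
    return seq


def _random_seq(n_codons: int, rng: np.random.Generator) -> list[int]:
    return [
        _NONSTOP_CODONS[i]
        for i in rng.integers(0, len(_NONSTOP_CODONS), size=n_codons)
    ]


def simulate_strain_set(config: SimConfig) -> tuple[dict[str, list[GeneRecord]], SimTruth]:
    """Simulate gene families along the configured tree.

    Returns per-strain :class:`GeneRecord` lists plus a :class:`SimTruth`
    with the family/relationship/compartment/frameshift ground truth and the
    substitution event log.  Identical config and seed give identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree = _parse_tree(config.tree)
    leaves = _leaf_names(tree)
    if len(leaves) != config.n_strains:
        raise ValueError(
            f"tree has {len(leaves)} leaves but n_strains = {config.n_strains}"
        )
    focal = leaves[0]
    dup_strain = config.dup_strain or focal
    loss_strains = config.loss_strains
    if loss_strains is None:
        loss_strains = (leaves[2],) if len(leaves) > 2 else ()
    recipient = config.hgt_recipient or leaves[-1]
    if recipient == focal:
        raise ValueError("HGT recipient must differ from the focal (donor) strain")

    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label.replace(" ", "_"): t for t in tree.taxon_namespace}
    donor_recipient_dist = pdm.patristic_distance(taxa[focal], taxa[recipient])

    nf = config.n_families
    families = np.arange(nf)
    # family roles
    n_hgt = int(round(config.hgt_fraction * nf))
    hgt_families = set(rng.choice(families, size=n_hgt, replace=False).tolist())
    rest = np.array([f for f in families if f not in hgt_families])
    n_dup = int(round(config.dup_fraction * nf))
    n_dup = min(n_dup, len(rest))
    dup_families = set(rng.choice(rest, size=n_dup, replace=False).tolist())
    lost_in: dict[int, set[str]] = {f: set() for f in families}
    n_loss = int(round(config.loss_fraction * nf))
    for strain in loss_strains:
        if strain == focal:
            raise ValueError("the focal strain cannot be a loss lineage")
        candidates = np.array([f for f in families if f not in hgt_families])
        chosen = rng.choice(candidates, size=min(n_loss, len(candidates)), replace=False)
        for f in chosen:
            lost_in[int(f)].add(strain)
    for f in hgt_families:  # pair-restricted: present in donor and recipient only
        lost_in[f] = {s for s in leaves if s not in (focal, recipient)}

    events: list = []
    tip_seqs: dict[int, dict[str, list[int]]] = {}

    # label internal edges for the event log
    for i, node in enumerate(tree.preorder_node_iter()):
        if node.taxon is None:
            node.label = node.label or f"node{i}"

    def node_edge_label(node) -> str:
        if node.taxon is not None:
            return node.taxon.label.replace(" ", "_")
        return node.label

    for fam in range(nf):
        root_seq = _random_seq(config.codon_length, rng)
        seqs: dict[str, list[int]] = {}

        def walk(node, seq):
            for child in node.child_nodes():
                bl = child.edge.length or 0.0
                child_seq = _mutate(
                    seq, bl, config.omega, rng, fam, node_edge_label(child), events
                )
                if child.is_leaf():
                    seqs[child.taxon.label.replace(" ", "_")] = child_seq
                else:
                    walk(child, child_seq)

        walk(tree.seed_node, root_seq)

        if fam in hgt_families:
            # replacement of the recipient's copy by one re-sourced from the
            # donor lineage close to the present: the pairwise divergence is
            # scaled by hgt_divergence_scale
            seqs[recipient] = _mutate(
                seqs[focal],
                config.hgt_divergence_scale * donor_recipient_dist,
                config.omega,
                rng,
                fam,
                f"hgt_f{fam}",
                events,
            )
        tip_seqs[fam] = seqs

    # duplicate copies in the designated lineage
    dup_seqs: dict[int, list[int]] = {}
    for fam in sorted(dup_families):
        dup_seqs[fam] = _mutate(
            tip_seqs[fam][dup_strain],
            config.dup_extra_branch,
            config.omega,
            rng,
            fam,
            f"dup_f{fam}",
            events,
        )

    # emit genes
    rows = []
    strain_sets: dict[str, list[GeneRecord]] = {s: [] for s in leaves}
    category_names = list(config.category_probs)
    category_p = np.array([config.category_probs[c] for c in category_names])
    category_p = category_p / category_p.sum()

    def present(fam: int, strain: str) -> bool:
        return strain not in lost_in[fam]

    def emit(fam: int, strain: str, copy: int, seq: list[int], hgt: bool):
        gene_id = f"FAM{fam}_{copy}|{strain}"
        relations = []
        for other in leaves:
            if other == strain:
                continue
            if not present(fam, other):
                rel = "absent"
            elif copy == 2:
                rel = "paralog"
            else:
                rel = "ortholog"
            relations.append(f"{other}:{rel}")
        p_plasmid = config.plasmid_fraction
        if hgt and config.hgt_plasmid_boost != 1.0:
            p_plasmid = min(0.95, p_plasmid * config.hgt_plasmid_boost)
        compartment = "plasmid" if rng.random() < p_plasmid else "chromosome"
        # observed classifier probabilities: confident and correct most of the
        # time, ambiguous (neither class reaches a 0.7 threshold) otherwise
        if rng.random() < config.ambiguous_compartment_rate:
            top = rng.uniform(0.40, 0.65)
        else:
            top = rng.uniform(0.75, 0.99)
        other_p = rng.uniform(0.0, 1.0 - top) * 0.5
        if compartment == "plasmid":
            plasmid_prob, chromosome_prob = top, other_p
        else:
            plasmid_prob, chromosome_prob = other_p, top
        category = category_names[
            int(rng.choice(len(category_names), p=category_p))
        ]
        rows.append(
            dict(
                gene_id=gene_id,
                strain=strain,
                family=fam,
                copy=copy,
                relation_map=";".join(relations),
                hgt_flag=hgt,
                compartment=compartment,
                chromosome_prob=round(chromosome_prob, 4),
                plasmid_prob=round(plasmid_prob, 4),
                frameshift_flag=False,
                category=category,
                sequence=indices_to_seq(seq),
            )
        )

    for fam in range(nf):
        hgt = fam in hgt_families
        for strain in leaves:
            if not present(fam, strain):
                continue
            emit(fam, strain, 1, tip_seqs[fam][strain], hgt)
            if fam in dup_families and strain == dup_strain:
                emit(fam, strain, 2, dup_seqs[fam], hgt)

    genes = pd.DataFrame(rows)

    # frameshift corruption: one inserted nucleotide at a uniform position,
    # applied after evolution so truth relationships are unaffected
    n_fs = int(round(config.frameshift_fraction * len(genes)))
    if n_fs:
        fs_idx = rng.choice(len(genes), size=n_fs, replace=False)
        for i in fs_idx:
            seq = genes.at[i, "sequence"]
            pos = int(rng.integers(0, len(seq) + 1))
            nt = "ACGT"[int(rng.integers(0, 4))]
            genes.at[i, "sequence"] = seq[:pos] + nt + seq[pos:]
            genes.at[i, "frameshift_flag"] = True

    for row in genes.itertuples():
        strain_sets[row.strain].append(
            GeneRecord(
                gene_id=row.gene_id,
                strain_id=row.strain,
                sequence=row.sequence,
                compartment=row.compartment,
                annotation_category=row.category,
            )
        )

    events_df = pd.DataFrame(
        events, columns=["family", "edge", "codon", "pos", "old_codon", "new_codon"]
    )
    truth = SimTruth(
        genes=genes, events=events_df, tree_newick=config.tree, config=config
    )
    return strain_sets, truth


# ---------------------------------------------------------------------------
# fixture writing


def write_fixture(
    strain_sets: dict[str, list[GeneRecord]],
    truth: SimTruth,
    out_dir: str | Path,
) -> dict:
    """Write one FASTA per strain plus truth and compartment tables.

    Returns a manifest dict (also written as ``manifest.json``) listing every
    file with its sha256 checksum.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for strain in sorted(strain_sets):
        path = out / f"{strain}.fasta"
        with open(path, "w") as fh:
            for rec in strain_sets[strain]:
                fh.write(f">{rec.gene_id}\n{rec.sequence}\n")
        files.append(path)

    truth_path = out / "truth.tsv"
    truth.genes.drop(columns=["sequence"]).to_csv(truth_path, sep="\t", index=False)
    files.append(truth_path)

    comp_path = out / "compartments.tsv"
    truth.genes[
        ["gene_id", "strain", "chromosome_prob", "plasmid_prob", "compartment"]
    ].to_csv(comp_path, sep="\t", index=False)
    files.append(comp_path)

    manifest = {
        "files": [
            {
                "path": p.name,
                "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
                "bytes": p.stat().st_size,
            }
            for p in files
        ]
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# ---------------------------------------------------------------------------
# mock contig hit profiles for the binning stage


def simulate_contig_profiles(
    n_cyano: int = 50,
    n_contaminant: int = 30,
    seed: int = 0,
    binner2_flip_rate: float = 0.02,
):
    """Generate mock taxonomic hit profiles for assembly contigs.

    True cyanobacterial contigs receive cyanobacteria-dominant hit lists with
    high identity and sequencing coverage around 100x; contaminants receive
    proteobacteria/CFB-dominant hits at lower identity and coverage.  A
    second-binner label map (with a small disagreement rate) and the true
    labels are returned alongside the profiles.

    Returns ``(profiles, binner2_labels, true_labels)`` where profiles are
    :class:`baeocomp.binning.ContigHitProfile`.
    """
    from .binning import ContigHitProfile

    rng = np.random.default_rng(seed)
    profiles = []
    binner2: dict[str, str] = {}
    true_labels: dict[str, str] = {}

    def make_hits(dominant: str, n_dom: int, n_other: int, ident_dom, ident_other):
        others = ["proteobacteria", "cfb", "other"]
        if dominant != "cyanobacteria":
            others = ["cyanobacteria", "other"]
        hits = []
        for _ in range(n_dom):
            hits.append((dominant, float(rng.uniform(*ident_dom)), 0.0))
        for _ in range(n_other):
            grp = others[int(rng.integers(0, len(others)))]
            hits.append((grp, float(rng.uniform(*ident_other)), 0.0))
        # score tracks identity with noise; profiles are sorted by score
        hits = [
            (g, ident, round(ident * 10 + float(rng.uniform(0, 20)), 1))
            for g, ident, _ in hits
        ]
        hits.sort(key=lambda h: -h[2])
        return hits

    for i in range(n_cyano):
        cid = f"cyano_{i}"
        all_cyano = rng.random() < 0.6
        n_other = 0 if all_cyano else int(rng.integers(1, 7))
        hits = make_hits("cyanobacteria", 20 - n_other, n_other, (82, 99), (50, 68))
        coverage = float(rng.normal(105, 10))
        profiles.append(
            ContigHitProfile(
                contig_id=cid,
                length_bp=int(rng.integers(1000, 40000)),
                coverage=max(coverage, 1.0),
                hits=hits,
            )
        )
        true_labels[cid] = "cyanobacterial"
        binner2[cid] = (
            "other" if rng.random() < binner2_flip_rate else "cyanobacterial"
        )
    for i in range(n_contaminant):
        cid = f"contam_{i}"
        dominant = "proteobacteria" if rng.random() < 0.7 else "cfb"
        n_other = int(rng.integers(0, 5))
        hits = make_hits(dominant, 20 - n_other, n_other, (75, 98), (45, 65))
        profiles.append(
            ContigHitProfile(
                contig_id=cid,
                length_bp=int(rng.integers(1000, 40000)),
                coverage=float(rng.uniform(5, 60)),
                hits=hits,
            )
        )
        true_labels[cid] = "other"
        binner2[cid] = (
            "cyanobacterial" if rng.random() < binner2_flip_rate else "other"
        )
    return profiles, binner2, true_labels


def hgt_scenario(seed: int = 0, **overrides) -> SimConfig:
    """Study condition for the windowed-Ks transfer screen.

    Half of the families are pair-restricted transfers at divergence scale
    0.3, and genes are long enough that both the All and the Pair
    concatenations yield at least ten 500-synonymous-site windows.
    """
    defaults = dict(
        n_families=30,
        codon_length=600,
        hgt_fraction=0.5,
        hgt_divergence_scale=0.3,
        dup_fraction=0.0,
        loss_fraction=0.0,
        frameshift_fraction=0.0,
        plasmid_fraction=0.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def equal_rate_triple(seed: int = 0, **overrides) -> SimConfig:
    """Three-taxon configuration with equal ingroup rates, for calibrating
    the relative rate test's type-I error."""
    defaults = dict(
        n_strains=3,
        tree="((A:0.15,B:0.15):0.1,O:0.1);",
        n_families=1,
        codon_length=300,
        dup_fraction=0.0,
        loss_fraction=0.0,
        hgt_fraction=0.0,
        frameshift_fraction=0.0,
        plasmid_fraction=0.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def pair_scenario(seed: int = 0, **overrides) -> SimConfig:
    """Two-strain configuration used for divergence-calibration checks."""
    defaults = dict(
        n_strains=2,
        tree="(A:0.15,B:0.15);",
        n_families=10,
        codon_length=300,
        omega=0.2,
        dup_fraction=0.0,
        loss_fraction=0.0,
        hgt_fraction=0.0,
        frameshift_fraction=0.0,
        plasmid_fraction=0.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)
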
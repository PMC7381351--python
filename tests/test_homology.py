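"""Reciprocal-best-hit scoring, labeling, and summaries."""

import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from baeocomp.homology import (
    GeneRecord,
    best_hit,
    classify_all,
    classify_rbh,
    pair_score,
    summarize_homology,
    union_no_similarity,
)
from baeocomp.simdata import SimConfig, simulate_strain_set

from conftest import random_coding_seq


def _rec(gid, strain, seq):
    return GeneRecord(gene_id=gid, strain_id=strain, sequence=seq)


def _mutate_some(rng, seq, n):
    seq = list(seq)
    for _ in range(n):
        i = int(rng.integers(0, len(seq)))
        seq[i] = "ACGT"[int(rng.integers(0, 4))]
    return "".join(seq)


def test_best_hit_self_similarity_dominates(rng):
    q = _rec("q", "A", random_coding_seq(rng, 60))
    subjects = [
        _rec("s1", "B", random_coding_seq(rng, 60)),
        _rec("s2", "B", q.sequence),
        _rec("s3", "B", random_coding_seq(rng, 60)),
    ]
    hit, score = best_hit(q, subjects, score_threshold=50)
    assert hit == "s2" and score > 100


def test_best_hit_threshold_gate(rng):
    q = _rec("q", "A", random_coding_seq(rng, 40))
    subjects = [_rec("s1", "B", random_coding_seq(rng, 40))]
    hit, score = best_hit(q, subjects, score_threshold=1e6)
    assert hit is None


def test_best_hit_matches_bruteforce_frame_oracle(rng):
    """Returned id equals the argmax of an exhaustive frame-pair alignment
    enumeration performed independently."""
    matrix = substitution_matrices.load("BLOSUM62")
    arr = np.array(matrix)
    x = matrix.alphabet.index("X")
    arr[x, :] = 0.0
    arr[:, x] = 0.0
    oracle_aligner = Align.PairwiseAligner()
    oracle_aligner.mode = "local"
    oracle_aligner.substitution_matrix = substitution_matrices.Array(
        alphabet=matrix.alphabet, dims=2, data=arr
    )
    oracle_aligner.open_gap_score = -11.0
    oracle_aligner.extend_gap_score = -1.0

    def oracle_translate(nt, frame):
        from Bio.Seq import Seq

        sub = nt[frame:]
        sub = sub[: len(sub) - len(sub) % 3]
        return "".join(
            str(Seq(sub[i:i + 3]).translate()) if set(sub[i:i + 3]) <= set("ACGT") else "X"
            for i in range(0, len(sub), 3)
        )

    def oracle_score(s1, s2):
        return max(
            oracle_aligner.score(oracle_translate(s1, f1), oracle_translate(s2, f2))
            for f1 in range(3)
            for f2 in range(3)
        )

    for trial in range(5):
        base = random_coding_seq(rng, 50)
        q = _rec("q", "A", base)
        subjects = [
            _rec(f"s{i}", "B", _mutate_some(rng, base, 20 + 10 * i)) for i in range(3)
        ]
        hit, score = best_hit(q, subjects, score_threshold=0)
        scored = sorted(
            ((oracle_score(q.sequence, s.sequence), s.gene_id) for s in subjects),
            key=lambda t: (-t[0], t[1]),
        )
        assert hit == scored[0][1]
        assert score == pytest.approx(scored[0][0])


def test_classify_rbh_forced_labels(rng):
    base = random_coding_seq(rng, 60)
    a1 = _rec("A1", "A", base)
    b1 = _rec("B1", "B", _mutate_some(rng, base, 10))
    other_a = _rec("A9", "A", random_coding_seq(rng, 60))
    other_b = _rec("B9", "B", random_coding_seq(rng, 60))

    # mutual best pair -> ortholog
    call = classify_rbh(a1, [a1, other_a], [b1, other_b], score_threshold=50)
    assert call.label == "ortholog"
    assert call.forward_best == "B1" and call.reverse_best == "A1"

    # a closer duplicate hijacks the reverse search -> paralog
    a2 = _rec("A2", "A", b1.sequence)  # identical to B1
    call = classify_rbh(a1, [a1, a2, other_a], [b1, other_b], score_threshold=50)
    assert call.label == "paralog" and call.reverse_best == "A2"

    # nothing above threshold -> no_similarity
    lone = _rec("L", "A", random_coding_seq(rng, 60))
    call = classify_rbh(lone, [lone], [other_b], score_threshold=1e6)
    assert call.label == "no_similarity" and call.forward_best is None


def _manual_calls(counts_by_strain, total):
    """Build HomologyCall lists matching given per-strain label counts."""
    from baeocomp.homology import HomologyCall

    calls = []
    for strain, (n_orth, n_para, n_none) in counts_by_strain.items():
        labels = (
            ["ortholog"] * n_orth + ["paralog"] * n_para + ["no_similarity"] * n_none
        )
        assert len(labels) == total
        for i, lbl in enumerate(labels):
            calls.append(
                HomologyCall(
                    query_gene=f"g{i}",
                    subject_strain=strain,
                    label=lbl,
                    forward_best=None if lbl == "no_similarity" else f"s{i}",
                    reverse_best=f"g{i}" if lbl == "ortholog" else None,
                    forward_score=0.0 if lbl == "no_similarity" else 100.0,
                )
            )
    return calls


def test_summary_percentages_match_published_arithmetic():
    calls = _manual_calls({"Pleurocapsa": (3880, 2118, 2106)}, total=8104)
    out = summarize_homology(calls, total_query_genes=8104)
    row = out.loc["Pleurocapsa"]
    assert row.orthologs == 3880 and row.orthologs_pct == 47.9
    assert row.paralogs_pct == 26.1 and row.no_similarity_pct == 26.0


def test_summary_small_arithmetic_and_guards():
    calls = _manual_calls({"B": (4, 3, 3)}, total=10)
    out = summarize_homology(calls, 10)
    assert list(out.loc["B", ["orthologs_pct", "paralogs_pct", "no_similarity_pct"]]) == [
        40.0, 30.0, 30.0,
    ]
    with pytest.raises(ValueError, match="no calls"):
        summarize_homology(calls, 10, strains=["B", "C"])
    with pytest.raises(ValueError, match="duplicate"):
        summarize_homology(calls + calls[:1], 10)
    with pytest.raises(ValueError, match="partition"):
        summarize_homology(calls[:-1], 10)


def test_union_no_similarity_rules():
    calls = _manual_calls({"B": (0, 0, 2), "C": (1, 0, 1)}, total=2)
    # g0 is no_similarity in B but ortholog in C; g1 in both
    got = union_no_similarity(calls)
    assert got == {"g1"}
    all_orth = _manual_calls({"B": (2, 0, 0), "C": (2, 0, 0)}, total=2)
    assert union_no_similarity(all_orth) == set()
    with pytest.raises(ValueError, match="cover"):
        union_no_similarity(calls[:-1])


def test_union_recovers_strain_specific_genes(rng):
    """Genes planted only in the focal strain are exactly the ones labeled
    no-similarity against every subject strain."""
    shared = [random_coding_seq(rng, 80) for _ in range(6)]
    focal = [_rec(f"S{i}", "F", s) for i, s in enumerate(shared)]
    focal += [_rec(f"U{i}", "F", random_coding_seq(rng, 80)) for i in range(12)]
    subject_sets = {}
    for strain in ("B", "C"):
        subject_sets[strain] = [
            _rec(f"{strain}{i}", strain, _mutate_some(rng, s, 15))
            for i, s in enumerate(shared)
        ]
    calls = classify_all(focal, subject_sets, score_threshold=50)
    assert union_no_similarity(calls) == {f"U{i}" for i in range(12)}


def test_rbh_recovery_on_simulated_truth():
    """On simulated data, truth orthologs are recovered as orthologs and
    duplicate-confounded genes as paralogs, with per-strain label counts
    partitioning the focal gene set."""
    cfg = SimConfig(n_families=25, codon_length=100, frameshift_fraction=0.0, seed=17)
    sets, truth = simulate_strain_set(cfg)
    strains = list(sets)
    focal = strains[0]
    calls = classify_all(sets[focal], {s: sets[s] for s in strains[1:]})
    summary = summarize_homology(calls, len(sets[focal]), strains=strains[1:])
    assert (summary[["orthologs", "paralogs", "no_similarity"]].sum(axis=1)
            == len(sets[focal])).all()

    label_map = {(c.query_gene, c.subject_strain): c.label for c in calls}
    g = truth.genes
    n_orth = n_orth_hit = n_para = n_para_hit = 0
    for row in g[g.strain == focal].itertuples():
        rels = dict(item.split(":") for item in row.relation_map.split(";"))
        for other, rel in rels.items():
            got = label_map[(row.gene_id, other)]
            if rel == "ortholog":
                n_orth += 1
                n_orth_hit += got == "ortholog"
            elif rel == "paralog":
                n_para += 1
                n_para_hit += got == "paralog"
    assert n_orth_hit / n_orth >= 0.95
    assert n_para == 0 or n_para_hit / n_para >= 0.90


def test_ortholog_symmetry_at_moderate_divergence(rng):
    """If A1 -> strain B is an ortholog call with forward best B1, then
    B1 -> strain A must come back ortholog with forward best A1."""
    cfg = SimConfig(
        n_strains=2, tree="(A:0.2,B:0.2);", n_families=15, codon_length=100,
        dup_fraction=0, loss_fraction=0, hgt_fraction=0, frameshift_fraction=0,
        seed=23,
    )
    sets, _ = simulate_strain_set(cfg)
    ok = total = 0
    for a_rec, b_rec in zip(sets["A"], sets["B"]):
        fwd = classify_rbh(a_rec, sets["A"], sets["B"])
        if fwd.label != "ortholog":
            continue
        total += 1
        back = classify_rbh(
            next(r for r in sets["B"] if r.gene_id == fwd.forward_best),
            sets["B"], sets["A"],
        )
        ok += back.label == "ortholog" and back.forward_best == a_rec.gene_id
    assert total >= 14 and ok / total >= 0.99


def test_gene_record_validation():
    with pytest.raises(ValueError):
        GeneRecord("g", "s", "")
    with pytest.raises(ValueError):
        GeneRecord("g", "s", "ATG", compartment="mitochondrion")
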
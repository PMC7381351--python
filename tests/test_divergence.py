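"""NG86 divergence, windowed Ks, Mann–Whitney, and the relative rate test."""

import math

import numpy as np
import pytest

from baeocomp.align import family_alignment
from baeocomp.divergence import (
    CodonAlignment,
    concatenate,
    filter_multiple_of_three,
    mann_whitney,
    ng86,
    tajima_rrt,
    windowed_ks,
)
from baeocomp.homology import GeneRecord
from baeocomp.simdata import SimConfig, pair_scenario, simulate_strain_set

from conftest import random_coding_seq
from oracles import mannwhitney_exact_enum, ng86_bruteforce


# --- NG86 -------------------------------------------------------------------


def test_identical_sequences_zero_divergence(rng):
    s = random_coding_seq(rng, 30)
    d = ng86(s, s)
    assert d.Ks == 0.0 and d.Ka == 0.0 and d.Sd == 0.0 and d.Nd == 0.0


def test_hand_counted_single_synonymous_difference():
    s1 = "TTT" * 10
    s2 = "TTT" * 9 + "TTC"
    d = ng86(s1, s2)
    assert d.S == pytest.approx(10 / 3)
    assert d.Sd == 1.0 and d.Nd == 0.0
    assert d.p_s == pytest.approx(0.3)
    assert d.Ks == pytest.approx(-0.75 * math.log(0.6))
    assert d.Ka == 0.0


def test_site_conservation_is_exact(rng):
    for _ in range(20):
        s1 = random_coding_seq(rng, 40)
        s2 = random_coding_seq(rng, 40)
        d = ng86(s1, s2)
        assert d.S + d.N == pytest.approx(3 * d.n_codons, abs=1e-12)


def test_matches_bruteforce_oracle(rng):
    for _ in range(30):
        s1 = random_coding_seq(rng, 50)
        s2 = random_coding_seq(rng, 50)
        d = ng86(s1, s2)
        o = ng86_bruteforce(s1, s2)
        for key in ("S", "N", "Sd", "Nd"):
            assert getattr(d, key) == pytest.approx(o[key], abs=1e-9)
        for key in ("Ks", "Ka"):
            a, b = getattr(d, key), o[key]
            assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b, abs=1e-9)


def test_gap_and_ambiguity_codons_skipped():
    d = ng86("TTT---AANTTC", "TTTTTTAAATTC")
    assert d.n_codons == 2  # only the first and last codons are comparable


def test_ng86_error_cases():
    with pytest.raises(ValueError):
        ng86("TTTT", "TTTT")  # not a multiple of three
    with pytest.raises(ValueError):
        ng86("TTT", "TTTTTT")
    with pytest.raises(ValueError):
        ng86("---", "TTT")  # no comparable codons


# --- frame filter and concatenation ----------------------------------------


def test_frame_filter_by_length():
    a = CodonAlignment([("x", "TTTAAA"), ("y", "TTTAAA")], name="ok")
    b = CodonAlignment([("x", "TTTAAAC"), ("y", "TTTAAAC")], name="shifted")
    kept, dropped = filter_multiple_of_three([a, b])
    assert [k.name for k in kept] == ["ok"]
    assert dropped[0][0].name == "shifted" and "frameshift" in dropped[0][1]


def test_frame_filter_matches_truth_on_simulated_families():
    cfg = SimConfig(n_families=20, codon_length=60, frameshift_fraction=0.2,
                    dup_fraction=0, loss_fraction=0, hgt_fraction=0, seed=31)
    sets, truth = simulate_strain_set(cfg)
    fams = {}
    for recs in sets.values():
        for r in recs:
            fams.setdefault(r.gene_id.split("_")[0], []).append(r)
    alns = [family_alignment(members, name=f) for f, members in sorted(fams.items())]
    kept, dropped = filter_multiple_of_three(alns)
    shifted = {
        "FAM" + str(f)
        for f in truth.genes[truth.genes.frameshift_flag].family.unique()
    }
    assert {d[0].name for d in dropped} == shifted


def test_concatenate_additivity_and_guards(rng):
    taxa = ["a", "b"]
    alns = []
    for i in range(2):
        seqs = [random_coding_seq(rng, 10) for _ in taxa]
        alns.append(CodonAlignment(list(zip(taxa, seqs)), name=f"g{i}"))
    cat = concatenate(alns)
    assert cat.length == 60
    # per-gene synonymous sites add up to the concatenated count
    per_gene = sum(ng86(a.records[0][1], a.records[1][1]).S for a in alns)
    total = ng86(cat.records[0][1], cat.records[1][1]).S
    assert total == pytest.approx(per_gene, abs=1e-9)
    with pytest.raises(ValueError):
        concatenate([])
    bad = CodonAlignment([("a", "TTT"), ("z", "TTT")], name="bad")
    with pytest.raises(ValueError, match="taxa mismatch"):
        concatenate([alns[0], bad])
    with pytest.raises(ValueError, match="ragged"):
        CodonAlignment([("a", "TTT"), ("b", "TTTTTT")])


def test_concatenate_respects_ordering(rng):
    taxa = ["a", "b"]
    a1 = CodonAlignment([("a", "AAATTT"), ("b", "AAATTT")], name="g1")
    a2 = CodonAlignment([("a", "CCCGGG"), ("b", "CCCGGG")], name="g2")
    cat = concatenate([a1, a2], ordering=["g2", "g1"])
    assert cat.records[0][1] == "CCCGGGAAATTT"


# --- windowed Ks ------------------------------------------------------------


def test_window_count_forced_by_closing_rule():
    # identical TTT codons: 1/3 synonymous site each, zero differences
    n_codons = 3120  # total S = 1040
    seq = "TTT" * n_codons
    aln = CodonAlignment([("a", seq), ("b", seq)])
    series = windowed_ks(aln, "a", "b", window_syn_sites=500)
    assert len(series.windows) == 2
    assert all(ks == 0.0 for _, _, ks in series.windows)
    n_codons = 4600  # total S ~ 1533: three full windows plus a remainder
    seq = "TTT" * n_codons
    series = windowed_ks(CodonAlignment([("a", seq), ("b", seq)]), "a", "b", 500)
    assert len(series.windows) == 3
    assert all(s >= 500 for _, s, _ in series.windows)


def test_window_accounting_inequality(rng):
    from baeocomp.simdata import pair_scenario, simulate_strain_set

    sets, _ = simulate_strain_set(
        pair_scenario(seed=55, n_families=1, codon_length=2500, tree="(A:0.2,B:0.2);")
    )
    s1, s2 = sets["A"][0].sequence, sets["B"][0].sequence
    aln = CodonAlignment([("a", s1), ("b", s2)])
    series = windowed_ks(aln, "a", "b", window_syn_sites=300)
    total = ng86(s1, s2)
    windowed_sd = sum(s * (1 - math.exp(-4 * ks / 3)) * 3 / 4 for _, s, ks in series.windows)
    assert windowed_sd <= total.Sd + 1e-9


def test_window_warning_when_too_few_sites():
    aln = CodonAlignment([("a", "TTT" * 10), ("b", "TTT" * 10)])
    with pytest.warns(UserWarning, match="below the window size"):
        series = windowed_ks(aln, "a", "b", 500)
    assert series.windows == []


# --- Mann-Whitney -----------------------------------------------------------


def test_mann_whitney_exact_small_samples():
    u, p = mann_whitney([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.100, abs=1e-9)
    assert p == pytest.approx(mannwhitney_exact_enum([1, 2, 3], [4, 5, 6]), abs=1e-9)


def test_mann_whitney_null_and_guards():
    _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p == pytest.approx(1.0)
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


def test_mann_whitney_matches_enumeration_on_random_draws(rng):
    for _ in range(5):
        x = list(np.round(rng.normal(size=4), 6))
        y = list(np.round(rng.normal(size=5), 6))
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(mannwhitney_exact_enum(x, y), abs=1e-9)


# --- Tajima relative rate test ----------------------------------------------


def _triple_with_unique_diffs(m1, m2, n_codons=200):
    """Aligned triple where A has m1 unique third-position changes and B has
    m2, relative to an outgroup O."""
    base = ["GGT"] * n_codons  # Gly: third position fourfold degenerate
    a, b, o = list(base), list(base), list(base)
    for i in range(m1):
        a[i] = "GGA"
    for i in range(m1, m1 + m2):
        b[i] = "GGC"
    return "".join(a), "".join(b), "".join(o)


def test_tajima_symmetric_counts_give_p_one():
    a, b, o = _triple_with_unique_diffs(4, 4)
    res = tajima_rrt(a, b, o, mode="third_codon")
    assert res.m1 == 4 and res.m2 == 4
    assert res.chi_square == 0.0 and res.p_value == 1.0


def test_tajima_five_zero_chi_square_tail():
    a, b, o = _triple_with_unique_diffs(5, 0)
    res = tajima_rrt(a, b, o, mode="third_codon")
    assert res.m1 == 5 and res.m2 == 0
    assert res.chi_square == pytest.approx(5.0)
    assert res.p_value == pytest.approx(0.02535, abs=1e-5)


def test_tajima_amino_acid_mode_ignores_synonymous_changes():
    a, b, o = _triple_with_unique_diffs(5, 0)  # all changes synonymous
    res = tajima_rrt(a, b, o, mode="amino_acid")
    assert res.m1 == 0 and res.m2 == 0 and res.p_value == 1.0


def test_tajima_guards():
    with pytest.raises(ValueError):
        tajima_rrt("TTT", "TTT", "TTTTTT")
    with pytest.raises(ValueError):
        tajima_rrt("TTT", "TTT", "TTT", mode="codon")


# --- model-limit behaviour ---------------------------------------------------


def test_ka_ks_tracks_omega_limits():
    low = pair_scenario(seed=41, n_families=1, codon_length=6000, omega=0.02)
    neutral = pair_scenario(seed=42, n_families=1, codon_length=6000, omega=1.0)
    for cfg, lo, hi in ((low, 0.0, 0.15), (neutral, 0.8, 1.2)):
        sets, _ = simulate_strain_set(cfg)
        d = ng86(sets["A"][0].sequence, sets["B"][0].sequence)
        ratio = d.Ka / d.Ks
        assert lo <= ratio <= hi
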
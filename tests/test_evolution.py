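"""Clustering, homolog search statistics, synteny, Dollo reconstruction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sealmir._seq import random_seq, revcomp
from sealmir._tree import branch_key, parse_tree
from sealmir.containers import Gene, HairpinLocus
from sealmir.evolution import (HomologHit, build_presence_matrix,
                               cluster_hairpins, dollo_reconstruct,
                               global_identity, homolog_search,
                               karlin_altschul_params, net_gain_rates,
                               synteny_support)

TREE8 = ("(((seal:45,dog:45):33,((cow:62,pig:62):14,horse:76):2):16,"
         "((mouse:82,rabbit:82):8,human:90):4);")


# ---------------------------------------------------------------------------
# clustering


def test_identical_sequences_form_one_cluster():
    seq = random_seq(np.random.default_rng(0), 60)
    ogs = cluster_hairpins([("a", "l1", seq), ("b", "l2", seq),
                            ("c", "l3", seq)])
    assert len(ogs) == 1 and len(ogs[0].members) == 3


def test_thirty_percent_divergence_splits():
    rng = np.random.default_rng(1)
    a = random_seq(rng, 60)
    b = list(a)
    for i in rng.choice(60, size=18, replace=False):
        b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
    ogs = cluster_hairpins([("x", "l1", a), ("y", "l2", "".join(b))])
    assert len(ogs) == 2


def test_greedy_clustering_matches_bruteforce_replay():
    rng = np.random.default_rng(2)
    seqs = []
    for f in range(5):
        base = random_seq(rng, int(rng.integers(45, 70)))
        for c in range(int(rng.integers(1, 4))):
            s = list(base)
            for i in rng.choice(len(s), size=int(rng.integers(0, 5)),
                                replace=False):
                s[i] = str(rng.choice(list("ACGT")))
            seqs.append((f"t{c}", f"fam{f}_{c}", "".join(s)))
    ogs = cluster_hairpins(seqs)
    # independent replay of the greedy definition over an all-pairs matrix
    order = sorted(seqs, key=lambda r: (-len(r[2]), r[2], r[0], r[1]))
    reps: list[str] = []
    assign = []
    for _, _, s in order:
        placed = None
        for ri, r in enumerate(reps):
            if global_identity(r, s) >= 0.80:
                placed = ri
                break
        if placed is None:
            reps.append(s)
            placed = len(reps) - 1
        assign.append(placed)
    got = [next(i for i, og in enumerate(ogs)
                if any(m[2] == s and m[1] == lid for m in og.members))
           for (_, lid, s) in order]
    assert got == assign
    for og in ogs:
        for _, _, s in og.members:
            assert global_identity(og.representative, s) >= 0.80


def test_mixed_composition_classes_as_mirbase():
    seq = random_seq(np.random.default_rng(3), 60)
    ogs = cluster_hairpins([("a", "known", seq), ("b", "new", seq)],
                           annotated={"known"})
    assert ogs[0].annotation_class == "miRBase"


# ---------------------------------------------------------------------------
# Karlin-Altschul and homolog search


def test_karlin_altschul_reference_values():
    # published ungapped values for +1/-2 at uniform composition
    lam, K, H = karlin_altschul_params(1, -2, dict.fromkeys("ACGT", 0.25))
    assert lam == pytest.approx(1.33, abs=0.01)
    assert K == pytest.approx(0.621, abs=0.01)


def test_evalue_monotone_in_score():
    lam, K, _ = karlin_altschul_params(1, -2, dict.fromkeys("ACGT", 0.25))
    ev = [K * 60 * 1e5 * np.exp(-lam * s) for s in (40, 45, 50)]
    assert ev[0] > ev[1] > ev[2]


def test_verbatim_query_found_with_tiny_evalue():
    rng = np.random.default_rng(4)
    q = random_seq(rng, 60)
    genome = {"c": random_seq(rng, 3000) + q + random_seq(rng, 3000)}
    hits = homolog_search({"q": q}, genome)
    best = max(hits, key=lambda h: h.score)
    assert best.length == 60 and best.evalue < 1e-20
    assert genome["c"][best.start:best.end] == q


def test_minus_strand_homolog_found():
    rng = np.random.default_rng(5)
    q = random_seq(rng, 60)
    genome = {"c": random_seq(rng, 2000) + revcomp(q) + random_seq(rng, 2000)}
    hits = homolog_search({"q": q}, genome)
    assert any(h.strand == "-" and h.length == 60 for h in hits)


def test_39nt_match_filtered_by_length_rule():
    rng = np.random.default_rng(6)
    q = random_seq(rng, 39)
    genome = {"c": random_seq(rng, 2000) + q + random_seq(rng, 2000)}
    hits = homolog_search({"q": q}, genome)
    assert hits == []
    # the same embedded segment at 40 nt passes
    q2 = random_seq(rng, 40)
    genome2 = {"c": random_seq(rng, 2000) + q2 + random_seq(rng, 2000)}
    assert any(h.length >= 40 for h in homolog_search({"q": q2}, genome2))


# ---------------------------------------------------------------------------
# synteny


def _gene(gid, start, end, strand):
    return Gene(gid, "c", start, end, strand)


def _locus(start, end, strand="+"):
    return HairpinLocus(id="q", chrom="c", start=start, end=end, strand=strand)


def _hit(start, end, strand="+"):
    return HomologHit(query="q", taxon="t", chrom="c", start=start, end=end,
                      strand=strand, score=60, length=60, evalue=1e-30)


IDENT = {"g1": "g1", "g2": "g2", "g3": "g3"}


def test_identical_flanks_same_relative_strand_supported():
    qg = [_gene("g1", 0, 100, "+"), _gene("g2", 300, 400, "-")]
    tg = [_gene("g1", 0, 100, "+"), _gene("g2", 300, 400, "-")]
    assert synteny_support(_hit(150, 210), _locus(150, 210), qg, tg, IDENT)


def test_flipped_relative_strand_fails_unless_other_side_passes():
    qg = [_gene("g1", 0, 100, "+"), _gene("g2", 300, 400, "-")]
    # upstream homolog flipped relative to the hit, downstream intact
    tg_flip_up = [_gene("g1", 0, 100, "-"), _gene("g2", 300, 400, "-")]
    assert synteny_support(_hit(150, 210), _locus(150, 210), qg, tg_flip_up,
                           IDENT)
    # both flanks flipped: no supporting pair
    tg_flip_both = [_gene("g1", 0, 100, "-"), _gene("g2", 300, 400, "+")]
    assert not synteny_support(_hit(150, 210), _locus(150, 210), qg,
                               tg_flip_both, IDENT)


def test_missing_flank_is_skipped_not_failed():
    qg = [_gene("g2", 300, 400, "-")]  # no upstream gene on the query side
    tg = [_gene("g2", 300, 400, "-")]
    assert synteny_support(_hit(150, 210), _locus(150, 210), qg, tg, IDENT)


def test_relocated_synthetic_loci_break_synteny():
    qg = [_gene("g1", 0, 100, "+"), _gene("g2", 300, 400, "-")]
    # hit relocated between two unrelated genes; g1/g2 are far away
    tg = [_gene("g3", 0, 100, "+"), _gene("g4", 300, 400, "-"),
          _gene("g1", 600, 700, "+"), _gene("g2", 900, 1000, "-")]
    assert not synteny_support(_hit(120, 180), _locus(150, 210), qg, tg,
                               {**IDENT, "g4": "g4"})


def test_neighbor_on_opposite_side_still_supports():
    # an inversion can swap upstream/downstream; a conserved neighbor on
    # either side with matching relative strand counts as support
    qg = [_gene("g1", 0, 100, "+"), _gene("g2", 300, 400, "-")]
    tg = [_gene("g3", 0, 100, "+"), _gene("g1", 600, 700, "+")]
    assert synteny_support(_hit(120, 180), _locus(150, 210), qg, tg, IDENT)


# ---------------------------------------------------------------------------
# presence matrix and Dollo


def test_presence_matrix_rescue_flips_cell():
    from sealmir.evolution import Orthogroup
    og = Orthogroup(id="OG0000", representative="A" * 40)
    og.presence = {"seal": True}
    taxa = ["seal", "dog"]
    base = build_presence_matrix([og], taxa)
    assert base.loc["dog", "OG0000"] == 0
    rescued = build_presence_matrix([og], taxa, {"OG0000": {"dog"}})
    assert rescued.loc["dog", "OG0000"] == 1
    with pytest.raises(ValueError, match="not in taxa"):
        build_presence_matrix([og], taxa, {"OG0000": {"cat"}})


from sealmir.oracles import dollo_min_losses as _loss_oracle


def test_single_leaf_and_full_presence_placements():
    taxa = sorted(l.taxon.label for l in parse_tree(TREE8).leaf_node_iter())
    mat = pd.DataFrame(0, index=taxa, columns=["only_seal", "everywhere"])
    mat.loc["seal", "only_seal"] = 1
    mat["everywhere"] = 1
    table, placements = dollo_reconstruct(mat, TREE8)
    p = placements.set_index("orthogroup")
    assert p.loc["only_seal", "gain_branch"] == "seal"
    assert p.loc["only_seal", "loss_branches"] == ""
    assert p.loc["everywhere", "gain_branch"] == "|".join(taxa)
    assert p.loc["everywhere", "loss_branches"] == ""


def test_all_255_patterns_match_bruteforce_minimum():
    tree = parse_tree(TREE8)
    taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())
    cols = {}
    patterns = []
    for bits in range(1, 256):
        present = {taxa[i] for i in range(8) if bits >> i & 1}
        cols[f"p{bits}"] = [1 if t in present else 0 for t in taxa]
        patterns.append((f"p{bits}", present))
    mat = pd.DataFrame(cols, index=taxa)
    table, placements = dollo_reconstruct(mat, TREE8)
    assert int(table["gains"].sum()) == 255  # one gain per pattern
    per_og = placements.set_index("orthogroup")
    for name, present in patterns:
        n_losses = len([x for x in
                        per_og.loc[name, "loss_branches"].split(",") if x])
        assert n_losses == _loss_oracle(tree, present), name
    # leaf states reproduce the matrix: presence leaves inside gain clade
    for name, present in patterns:
        gain_leaves = set(per_og.loc[name, "gain_branch"].split("|"))
        assert present <= gain_leaves


def test_all_absent_orthogroup_rejected():
    taxa = sorted(l.taxon.label for l in parse_tree(TREE8).leaf_node_iter())
    mat = pd.DataFrame({"dead": [0] * 8}, index=taxa)
    with pytest.raises(ValueError, match="absent"):
        dollo_reconstruct(mat, TREE8)


def test_net_gain_rate_arithmetic():
    table = pd.DataFrame({"branch": ["a", "b", "c"],
                          "length_my": [3.0, 5.0, 0.0],
                          "gains": [10, 4, 1], "losses": [4, 4, 0]})
    out = net_gain_rates(table)
    assert out.loc[0, "net_gain_rate"] == pytest.approx(2.00)
    assert out.loc[1, "net_gain_rate"] == 0.0
    assert out.loc[2, "rate_undefined"]
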
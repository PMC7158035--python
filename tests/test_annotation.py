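"""Candidate calling, classification, merging, curation, arm switching."""

import numpy as np
import pandas as pd
import pytest

from sealmir._seq import random_seq
from sealmir.annotation import (arm_switch_screen, candidate_loci,
                                classify_hairpin, curate, merge_predictions)
from sealmir.containers import CountMatrix, HairpinLocus
from sealmir.fold import fold_sequence
from sealmir.preprocess import ExactHit


# ---------------------------------------------------------------------------
# classification


def test_perfect_stem_is_mir_like():
    arm = "ACGTGGCATCAGGTTACCGGTA"
    from sealmir._seq import revcomp
    f = fold_sequence(arm + "AATCGATTAA" + revcomp(arm))
    assert classify_hairpin(f)


def test_unstructured_ac_sequence_is_not_mir_like():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("AC"), size=60))
    assert not classify_hairpin(fold_sequence(seq))


# ---------------------------------------------------------------------------
# candidate calling


def test_no_hits_no_candidates(toy):
    assert candidate_loci([], toy.genome) == []


def test_stack_below_min_stack_ignored(toy):
    lc = toy.truth.loci[0]
    a5, a3 = lc.arm5p, lc.arm3p
    hits = [
        ExactHit("r" * (a5[1] - a5[0]), 4, lc.chrom, a5[0], a5[1], lc.strand),
        ExactHit("q" * (a3[1] - a3[0]), 4, lc.chrom, a3[0], a3[1], lc.strand),
    ]
    assert candidate_loci(hits, toy.genome, min_stack=5) == []
    assert len(candidate_loci(hits, toy.genome, min_stack=4)) == 1


def test_planted_loci_recovered_as_candidates(toy, pooled_hits):
    cands = candidate_loci(pooled_hits, toy.genome)
    found = 0
    for lc in toy.truth.loci:
        for c in cands:
            if (c.chrom == lc.chrom and c.strand == lc.strand
                    and abs(c.start - lc.start) <= 10
                    and abs(c.end - lc.end) <= 10):
                found += 1
                break
    assert found >= 0.95 * len(toy.truth.loci)


# ---------------------------------------------------------------------------
# merging


def _bed(chrom, s, e, name, strand):
    return f"{chrom}\t{s}\t{e}\t{name}\t0\t{strand}"


def test_merge_disjoint_sets_concatenates():
    a = [_bed("c", 0, 10, "a", "+")]
    b = [_bed("c", 20, 30, "b", "+")]
    assert len(merge_predictions(a, b)) == 2


def test_merge_identical_sets_marks_both():
    a = [_bed("c", 0, 10, "a", "+")]
    merged = merge_predictions(a, list(a))
    assert len(merged) == 1 and merged[0].provenance == "both"


def test_merge_is_strand_aware():
    a = [_bed("c", 0, 10, "a", "+")]
    b = [_bed("c", 5, 15, "b", "-")]
    assert len(merge_predictions(a, b)) == 2


def test_malformed_bed_reports_line_number():
    with pytest.raises(ValueError, match="line 1"):
        merge_predictions(["c\tnotanumber\t5\tx\t0\t+"], [])


def test_merge_equals_bruteforce_components():
    rng = np.random.default_rng(5)
    for _ in range(20):
        ivs = []
        for k in range(rng.integers(2, 15)):
            s = int(rng.integers(0, 200))
            ivs.append(("c", s, s + int(rng.integers(5, 40)), "+"))
        half = len(ivs) // 2
        a = [_bed(*iv[:3], f"a{i}", iv[3]) for i, iv in enumerate(ivs[:half])]
        b = [_bed(*iv[:3], f"b{i}", iv[3]) for i, iv in enumerate(ivs[half:])]
        merged = merge_predictions(a, b)
        # brute force: connected components of the overlap graph
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(range(len(ivs)))
        for i in range(len(ivs)):
            for j in range(i + 1, len(ivs)):
                if ivs[i][1] < ivs[j][2] and ivs[j][1] < ivs[i][2]:
                    g.add_edge(i, j)
        comps = list(nx.connected_components(g))
        assert len(merged) == len(comps)
        spans = sorted((min(ivs[i][1] for i in c), max(ivs[i][2] for i in c))
                       for c in comps)
        assert sorted((m.start, m.end) for m in merged) == spans
        # outputs pairwise disjoint
        ms = sorted((m.start, m.end) for m in merged)
        assert all(ms[i][1] <= ms[i + 1][0] for i in range(len(ms) - 1))


# ---------------------------------------------------------------------------
# curation


def _candidate_with_reads(toy, n5, n3, locus_idx=0):
    lc = toy.truth.loci[locus_idx]
    import copy
    cand = copy.deepcopy(lc)
    cand.extra = {}
    hits = []
    a5, a3 = lc.arm5p, lc.arm3p
    if n5:
        hits.append(ExactHit(lc.mature5p, n5, lc.chrom, a5[0], a5[1], lc.strand))
    if n3:
        hits.append(ExactHit(lc.mature3p, n3, lc.chrom, a3[0], a3[1], lc.strand))
    return cand, hits


def test_single_arm_candidate_rejected(toy):
    cand, hits = _candidate_with_reads(toy, 100, 0)
    assert curate([cand], hits) == []


def test_nine_total_reads_rejected_ten_kept(toy):
    cand, hits = _candidate_with_reads(toy, 5, 4)
    assert curate([cand], hits) == []
    cand, hits = _candidate_with_reads(toy, 5, 5)
    assert len(curate([cand], hits)) == 1


def test_curation_monotone_in_min_reads(toy, pooled_hits):
    cands = candidate_loci(pooled_hits, toy.genome)
    sizes = [len(curate(list(cands), pooled_hits, min_reads=m))
             for m in (1, 10, 50, 500)]
    assert sizes == sorted(sizes, reverse=True)


def test_full_recovery_and_labels(toy, pooled_hits):
    cands = candidate_loci(pooled_hits, toy.genome)
    kept = curate(cands, pooled_hits, mature_db=toy.truth.mature_db)
    planted = {(l.chrom, l.strand, l.start, l.end): l for l in toy.truth.loci}
    keptset = {(l.chrom, l.strand, l.start, l.end): l for l in kept}
    assert set(planted) == set(keptset)  # recall and precision both 100%
    for key, lc in keptset.items():
        annotated = planted[key].id in toy.truth.annotated_families
        assert lc.annotation_class == ("miRBase" if annotated else "novel")


# ---------------------------------------------------------------------------
# arm switching


def _cm(values_5p, values_3p):
    libs = [f"s{i}" for i in range(len(values_5p))]
    counts = pd.DataFrame([values_5p, values_3p],
                          index=["locus-5p", "locus-3p"], columns=libs)
    samples = pd.DataFrame({"sample_type": ["brain"] * len(libs),
                            "age": ["pup"] * len(libs),
                            "replicate": range(1, len(libs) + 1)}, index=libs)
    return CountMatrix(counts, samples)


def test_constant_dominance_is_not_switching():
    cm = _cm([50] * 6, [20] * 6)
    out = arm_switch_screen(cm)
    assert not out.loc["locus", "switching"]


def test_single_confident_reversal_flags_switch():
    cm = _cm([50] * 5 + [12], [20] * 5 + [40])
    assert arm_switch_screen(cm).loc["locus", "switching"]


def test_low_coverage_reversal_not_flagged():
    cm = _cm([50] * 5 + [3], [20] * 5 + [9])  # reversal below 10 reads
    assert not arm_switch_screen(cm).loc["locus", "switching"]


def test_simulated_constant_arm_ratio_never_switches():
    # constant, strongly biased arm usage: dominance never flips beyond
    # what sampling noise at a 4:1 ratio could occasionally fake
    from sealmir.synthetic_data import (SimConfig, build_toy_genome,
                                        simulate_libraries)
    cfg = SimConfig(seed=31, n_hairpins=12, n_genes=14, genome_length=60_000,
                    mean_depth=6000, arm_ratio=8.0)
    sim = simulate_libraries(build_toy_genome(cfg))
    out = arm_switch_screen(sim.true_counts)
    assert not out["switching"].any()
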
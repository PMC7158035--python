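"""Trimming, exact alignment, rescue and counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sealmir._seq import find_all, random_seq, revcomp
from sealmir.preprocess import (align_exact, count_matrix, rescue_unmapped,
                                trim_adapter)

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


def test_adapter_trim_keeps_17nt_insert():
    insert = "ACGTACGTACGTACGTA"
    collapsed, stats = trim_adapter([("r1", insert + ADAPTER)], ADAPTER)
    assert collapsed == {insert: 1}
    assert stats.with_adapter == 1 and stats.kept == 1


def test_boundary_16nt_rule():
    short = "ACGTACGTACGTACG"  # 15 nt
    exact = "ACGTACGTACGTACGT"  # 16 nt
    collapsed, stats = trim_adapter(
        [("r1", short + ADAPTER), ("r2", exact + ADAPTER)], ADAPTER)
    assert collapsed == {exact: 1}
    assert stats.too_short == 1


def test_empty_fastq_is_not_an_error():
    collapsed, stats = trim_adapter([], ADAPTER)
    assert collapsed == {} and stats.total_reads == 0


def test_partial_adapter_suffix_trimmed():
    insert = "ACGTACGTACGTACGTAC"
    read = insert + ADAPTER[:7]  # partial adapter at the 3' end
    collapsed, _ = trim_adapter([("r", read)], ADAPTER)
    assert collapsed == {insert: 1}


def test_suffix_below_min_overlap_kept():
    insert = "ACGTACGTACGTACGTAC"
    read = insert + ADAPTER[:3]  # 3 < min_overlap 5: not recognized
    collapsed, _ = trim_adapter([("r", read)], ADAPTER)
    assert collapsed == {read: 1}


@settings(max_examples=60, deadline=None)
@given(st.text(alphabet="ACGT", min_size=16, max_size=40))
def test_trimming_is_idempotent(insert):
    once, _ = trim_adapter([("r", insert + ADAPTER)], ADAPTER)
    for seq in once:
        twice, _ = trim_adapter([("r", seq)], ADAPTER)
        for seq2 in twice:
            thrice, _ = trim_adapter([("r", seq2)], ADAPTER)
            assert thrice == twice or seq2 in thrice


def test_trimmed_counts_match_generator_bookkeeping(libsim, aligned, toy):
    for lib, stats in aligned["trim_stats"].items():
        n_short = int(libsim.stats.loc[lib, "n_short"])
        assert stats.total_reads == len(libsim.reads[lib])
        assert stats.too_short == n_short
        assert stats.kept == stats.total_reads - n_short


def test_minus_strand_hit():
    genome = {"c": "TTTT" + "ACGTACGTACGTACGTACGT" + "TTTT"}
    read = revcomp("ACGTACGTACGTACGTACGT")
    hits, unmapped = align_exact({read: 1}, genome)
    minus = [h for h in hits if h.strand == "-"]
    assert any(h.start == 4 and h.end == 24 for h in minus)


def test_repeated_occurrence_reported_twice():
    seg = "ACCGGTTACCGGTTAAGGTT"  # not a palindrome
    genome = {"c": seg + "AAAA" + seg}
    hits, _ = align_exact({seg: 2}, genome)
    plus = [h for h in hits if h.strand == "+"]
    assert len(plus) == 2
    assert all(h.count == 2 for h in plus)


def test_n_bases_never_match():
    genome = {"c": "ACGTNACGTACGTACGTACGTA"}
    hits, unmapped = align_exact({"ACGTNACGTACGTACGT": 1}, genome)
    assert hits == [] and "ACGTNACGTACGTACGT" in unmapped


def test_align_agrees_with_naive_scan():
    rng = np.random.default_rng(11)
    genome = {"c": random_seq(rng, 600)}
    reads = {}
    for _ in range(10):
        i = int(rng.integers(0, 580))
        reads[genome["c"][i:i + 18]] = 1
    reads[random_seq(rng, 18)] = 1
    hits, unmapped = align_exact(reads, genome)
    for seq in reads:
        expected = [(p, "+") for p in find_all(seq, genome["c"])]
        expected += [(p, "-") for p in find_all(revcomp(seq), genome["c"])]
        got = [(h.start, h.strand) for h in hits if h.seq == seq]
        assert sorted(got) == sorted(expected)
        assert (seq in unmapped) == (not expected)


def test_rescue_finds_mir143_like_read():
    # the classic plasma read perfectly inside its reference hairpin
    read = "TGAGATGAAGCACTGTAGCT"
    hairpin = ("GGTGCAGTGCTGCATCTCTGGTCAGTTGGGAGTCTGAGATGAAGCACTGTAGCTC"
               "AGGAAGAGAGAAGTTGTTCTGCAGC")
    matches, per_hairpin = rescue_unmapped({read: 5}, {"mir-143": hairpin})
    assert matches == [(read, 5, "mir-143")]
    assert per_hairpin == {"mir-143": 5}


def test_rescue_misses_absent_read():
    _, per_hairpin = rescue_unmapped({"A" * 20: 1}, {"h": "CGCG" * 20})
    assert per_hairpin == {}


def test_offgenome_reads_fully_rescued(aligned, toy):
    db = toy.truth.hairpin_db
    for lib, unmapped in aligned["unmapped"].items():
        long_enough = {s: c for s, c in unmapped.items() if len(s) >= 16}
        # unmapped reads are off-genome matures (plus junk shorter than 16
        # already dropped); every off-genome mature is in the reference DB
        offgenome_seqs = {s for s in long_enough
                          if any(s in hp for hp in db.values())}
        matches, _ = rescue_unmapped(long_enough, db)
        rescued = {m[0] for m in matches}
        assert offgenome_seqs <= rescued


def test_count_matrix_empty_hits_keeps_skeleton(toy):
    import pandas as pd
    samples = pd.DataFrame({"sample_type": ["brain"], "age": ["pup"],
                            "replicate": [1]}, index=["s1"])
    cm = count_matrix({"s1": []}, toy.truth.loci, samples)
    assert (cm.counts.values == 0).all()
    assert len(cm.counts) == 2 * len(toy.truth.loci)


def test_multi_locus_read_counted_everywhere(toy):
    import copy
    import pandas as pd
    from sealmir.preprocess import ExactHit
    lc1 = copy.deepcopy(toy.truth.loci[0])
    lc2 = copy.deepcopy(toy.truth.loci[0])
    lc2.id = "dup"
    samples = pd.DataFrame({"sample_type": ["brain"], "age": ["pup"],
                            "replicate": [1]}, index=["s1"])
    a5 = lc1.arm5p
    hit = ExactHit(seq="x" * (a5[1] - a5[0]), count=3, chrom=lc1.chrom,
                   start=a5[0], end=a5[1], strand=lc1.strand)
    cm = count_matrix({"s1": [hit]}, [lc1, lc2], samples)
    assert cm.counts.loc[f"{lc1.id}-5p", "s1"] == 3
    assert cm.counts.loc["dup-5p", "s1"] == 3


def test_missing_sample_metadata_is_named(toy):
    import pandas as pd
    samples = pd.DataFrame({"sample_type": ["brain"], "age": ["pup"],
                            "replicate": [1]}, index=["s1"])
    with pytest.raises(ValueError, match="mystery"):
        count_matrix({"mystery": []}, toy.truth.loci, samples)


def test_pipeline_counts_equal_true_matrix(toy, libsim, aligned):
    # with zero jitter and zero errors the recomputed matrix is the truth
    cm = count_matrix(aligned["hits"], toy.truth.loci,
                      libsim.true_counts.samples)
    truth = libsim.true_counts.counts
    assert cm.counts.loc[truth.index, truth.columns].equals(truth)
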
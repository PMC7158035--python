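"""Orthogroup construction and gain/loss evolution on a dated tree.

Hairpin sequences from all taxa are clustered greedily at 80% global
identity (longest sequence founds each cluster), presence is rescued
across assemblies by an ungapped seed-and-extend homolog search with
Karlin-Altschul E-values (e <= 1e-6, alignment >= 40 nt) backed by synteny
support from flanking protein-coding genes, and per-orthogroup gain/loss
histories are reconstructed by Dollo parsimony: each family is gained
exactly once, on the branch above the most recent common ancestor of the
taxa that carry it, and lost on every branch leading to a carrier-free
subtree.  Branch rates are (gains - losses) / branch length in My.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from scipy.optimize import brentq

from ._seq import revcomp
from ._tree import branch_key, branch_table, parse_tree
from .containers import Gene

# ---------------------------------------------------------------------------
# greedy identity clustering


@dataclass
class Orthogroup:
    id: str
    representative: str  # sequence
    members: list[tuple[str, str, str]] = field(default_factory=list)  # (taxon, locus, seq)
    presence: dict[str, bool] = field(default_factory=dict)
    annotation_class: str = "novel"  # miRBase if any member annotated


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -2
    al.extend_gap_score = -2
    return al


def global_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """matches / alignment columns of the best global alignment
    (match +1, mismatch -1, gap -2)."""
    aligner = aligner or _aligner()
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def cluster_hairpins(
    seqs: list[tuple[str, str, str]],
    min_identity: float = 0.80,
    annotated: set[str] | None = None,
) -> list[Orthogroup]:
    """Greedy incremental clustering of (taxon, locus id, sequence) records.

    Sequences are visited longest-first (ties lexicographic by sequence);
    each joins the first existing representative with global identity >=
    `min_identity`, else founds a new cluster.  An orthogroup is classed
    miRBase when any member locus id is in `annotated` (mixed composition
    counts as miRBase).
    """
    aligner = _aligner()
    order = sorted(seqs, key=lambda r: (-len(r[2]), r[2], r[0], r[1]))
    groups: list[Orthogroup] = []
    for taxon, locus, seq in order:
        placed = False
        for og in groups:
            short, long_ = sorted((len(seq), len(og.representative)))
            if short / long_ < min_identity:
                continue
            if global_identity(og.representative, seq, aligner) >= min_identity:
                og.members.append((taxon, locus, seq))
                placed = True
                break
        if not placed:
            og = Orthogroup(id=f"OG{len(groups):04d}", representative=seq)
            og.members.append((taxon, locus, seq))
            groups.append(og)
    for og in groups:
        taxa = {m[0] for m in og.members}
        og.presence = {t: True for t in taxa}
        if annotated and any(m[1] in annotated for m in og.members):
            og.annotation_class = "miRBase"
    return groups


# ---------------------------------------------------------------------------
# Karlin-Altschul ungapped statistics


def karlin_altschul_params(
    match: int, mismatch: int, composition: dict[str, float]
) -> tuple[float, float, float]:
    """(lambda, K, H) for an ungapped match/mismatch score scheme under the
    given base composition (assumed for both sequences).

    lambda solves sum p_i p_j exp(lambda s_ij) = 1; K comes from the
    Karlin-Altschul series K = exp(-2*S) * lambda*d / (H * (1 - e^{-lambda d}))
    with S = sum_k k^{-1} [P(S_k >= 0) + E(e^{lambda S_k}; S_k < 0)] and d
    the lattice span of the score support.
    """
    p = np.array([composition.get(b, 0.0) for b in "ACGT"])
    p = p / p.sum()
    p_match = float((p * p).sum())
    probs = {match: p_match, mismatch: 1.0 - p_match}
    if sum(s * q for s, q in probs.items()) >= 0:
        raise ValueError("expected score must be negative")

    def f(lam):
        return sum(q * math.exp(lam * s) for s, q in probs.items()) - 1.0

    lam = brentq(f, 1e-9, 20.0)
    A = sum(s * q * math.exp(lam * s) for s, q in probs.items())
    H = lam * A
    d = math.gcd(*[abs(s) for s in probs])

    cur = {0: 1.0}
    total = 0.0
    for k in range(1, 400):
        nxt: dict[int, float] = defaultdict(float)
        for s1, q1 in cur.items():
            for s2, q2 in probs.items():
                nxt[s1 + s2] += q1 * q2
        cur = dict(nxt)
        term = sum(q for s, q in cur.items() if s >= 0) + \
            sum(q * math.exp(lam * s) for s, q in cur.items() if s < 0)
        total += term / k
        if term / k < 1e-12:
            break
    K = math.exp(-2.0 * total) * lam * d / (H * (1.0 - math.exp(-lam * d)))
    return lam, K, H


@dataclass
class HomologHit:
    query: str
    taxon: str
    chrom: str
    start: int
    end: int
    strand: str
    score: int
    length: int
    evalue: float
    q_start: int = 0
    q_end: int = 0
    synteny_supported: bool = False


def _composition(seq: str) -> dict[str, float]:
    n = max(len(seq), 1)
    return {b: seq.count(b) / n for b in "ACGT"}


def homolog_search(
    queries: dict[str, str],
    genome: dict[str, str],
    taxon: str = "",
    word_size: int = 11,
    match: int = 1,
    mismatch: int = -2,
    max_evalue: float = 1e-6,
    min_length: int = 40,
) -> list[HomologHit]:
    """Ungapped seed-and-extend local search of each query against the
    genome (both strands), filtered at e <= max_evalue and length >=
    min_length.  E = K * m * n * exp(-lambda * S)."""
    full = "".join(genome.values())
    lam, K, _H = karlin_altschul_params(match, mismatch, _composition(full))
    n_total = sum(len(s) for s in genome.values())

    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for chrom, seq in genome.items():
        for i in range(len(seq) - word_size + 1):
            index[seq[i:i + word_size]].append((chrom, i))

    hits: list[HomologHit] = []
    for qid, qseq in queries.items():
        m = len(qseq)
        best: dict[tuple, HomologHit] = {}
        for strand in ("+", "-"):
            q = qseq if strand == "+" else revcomp(qseq)
            for qi in range(m - word_size + 1):
                word = q[qi:qi + word_size]
                for chrom, gi in index.get(word, ()):  # seed
                    gseq = genome[chrom]
                    # ungapped extension to maximal-scoring segment
                    s, e = qi, qi + word_size
                    gs = gi
                    score = word_size * match
                    bs, be, bgs, bscore = s, e, gs, score
                    cs, cscore = s, score
                    # left
                    k = 1
                    run = score
                    while qi - k >= 0 and gi - k >= 0:
                        run += match if q[qi - k] == gseq[gi - k] else mismatch
                        if run > bscore:
                            bscore, bs, bgs = run, qi - k, gi - k
                        if run < bscore - 20:
                            break
                        k += 1
                    score = bscore
                    s, gs = bs, bgs
                    # right
                    k = 0
                    run = score
                    bscore2, be2 = score, qi + word_size
                    while qi + word_size + k < m and gi + word_size + k < len(gseq):
                        run += (match if q[qi + word_size + k] ==
                                gseq[gi + word_size + k] else mismatch)
                        if run > bscore2:
                            bscore2, be2 = run, qi + word_size + k + 1
                        if run < bscore2 - 20:
                            break
                        k += 1
                    score, e = bscore2, be2
                    length = e - s
                    g_start = gs
                    g_end = gs + length
                    ev = K * m * n_total * math.exp(-lam * score)
                    if ev > max_evalue or length < min_length:
                        continue
                    if strand == "-":
                        q_s, q_e = m - e, m - s
                    else:
                        q_s, q_e = s, e
                    key = (chrom, strand, g_start - q_s if strand == "+" else
                           g_start + q_e)
                    prev = best.get(key)
                    if prev is None or score > prev.score:
                        best[key] = HomologHit(
                            query=qid, taxon=taxon, chrom=chrom,
                            start=g_start, end=g_end, strand=strand,
                            score=score, length=length, evalue=ev,
                            q_start=q_s, q_end=q_e,
                        )
        hits.extend(best.values())
    hits.sort(key=lambda h: (h.query, h.chrom, h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# synteny support


def _flanking(genes: list[Gene], chrom: str, start: int, end: int):
    """(upstream, downstream, containing) genes for an interval; upstream is
    the nearest gene ending at or before start."""
    up = down = cont = None
    for g in genes:
        if g.chrom != chrom:
            continue
        if g.end <= start:
            if up is None or g.end > up.end:
                up = g
        elif g.start >= end:
            if down is None or g.start < down.start:
                down = g
        elif g.start <= start and g.end >= end:
            cont = g
    return up, down, cont


def synteny_support(
    hit: HomologHit,
    query_locus,
    query_genes: list[Gene],
    target_genes: list[Gene],
    orthology: dict[str, str],
) -> bool:
    """True iff at least one flanking (or containing) gene pair is
    homologous with matching relative strand.

    Relative strand means same-vs-opposite orientation of the gene with
    respect to the miRNA locus (query side) or BLAST hit (target side).
    Query flanks are compared against both target flanks, since assembly
    orientation is arbitrary; a missing flank on one side is skipped, not
    failed.
    """
    q_up, q_down, q_cont = _flanking(query_genes, query_locus.chrom,
                                     query_locus.start, query_locus.end)
    t_up, t_down, t_cont = _flanking(target_genes, hit.chrom, hit.start, hit.end)

    def rel(gene: Gene, strand: str) -> str:
        return "same" if gene.strand == strand else "opposite"

    q_pairs = [(g, rel(g, query_locus.strand)) for g in (q_up, q_down)
               if g is not None]
    t_pairs = [(g, rel(g, hit.strand)) for g in (t_up, t_down) if g is not None]
    for qg, qrel in q_pairs:
        hom = orthology.get(qg.id)
        for tg, trel in t_pairs:
            if hom == tg.id and qrel == trel:
                return True
    if q_cont is not None and t_cont is not None:
        if orthology.get(q_cont.id) == t_cont.id and \
                rel(q_cont, query_locus.strand) == rel(t_cont, hit.strand):
            return True
    return False


# ---------------------------------------------------------------------------
# presence matrix and Dollo reconstruction


def build_presence_matrix(
    orthogroups: list[Orthogroup],
    taxa: list[str],
    supported_hits: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Binary taxa x orthogroups matrix from annotated members plus
    synteny-supported rescue hits (orthogroup id -> set of taxa)."""
    supported_hits = supported_hits or {}
    for og_id, extra in supported_hits.items():
        for t in extra:
            if t not in taxa:
                raise ValueError(f"hit taxon {t!r} not in taxa set")
    mat = pd.DataFrame(0, index=sorted(taxa), columns=[og.id for og in orthogroups])
    for og in orthogroups:
        for t in og.presence:
            mat.loc[t, og.id] = 1
        for t in supported_hits.get(og.id, ()):
            mat.loc[t, og.id] = 1
    return mat


def dollo_reconstruct(matrix: pd.DataFrame, tree_newick: str):
    """Single-gain (Dollo) parsimony reconstruction per orthogroup.

    Gain is placed on the branch above the LCA of the presence leaves
    (orthogroups present in every leaf gain on the root branch); a loss is
    counted on each branch from a present ancestor into a subtree with no
    presence leaves.  Returns (per-branch table, per-orthogroup placements).
    """
    tree = parse_tree(tree_newick)
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    for taxon in matrix.index:
        if taxon not in leaves:
            raise ValueError(f"matrix taxon {taxon!r} is not a tree leaf")
    lengths = branch_table(tree)
    gains = {k: 0 for k in lengths}
    losses = {k: 0 for k in lengths}
    leafsets = {id(nd): set(lf.taxon.label for lf in nd.leaf_iter())
                for nd in tree.preorder_node_iter()}
    placements = []
    for og in matrix.columns:
        present = set(matrix.index[matrix[og] == 1])
        if not present:
            raise ValueError(f"orthogroup {og} absent from every taxon")
        mrca = tree.mrca(taxa=[leaves[t].taxon for t in present]) \
            if len(present) > 1 else leaves[next(iter(present))]
        gkey = branch_key(mrca)
        gains[gkey] += 1
        og_losses = []
        stack = [mrca]
        while stack:
            node = stack.pop()
            for child in node.child_nodes():
                if leafsets[id(child)] & present:
                    stack.append(child)
                else:
                    key = branch_key(child)
                    losses[key] += 1
                    og_losses.append(key)
        placements.append({"orthogroup": og, "gain_branch": gkey,
                           "loss_branches": ",".join(sorted(og_losses))})
    table = pd.DataFrame({
        "branch": list(lengths),
        "length_my": [lengths[k] for k in lengths],
        "gains": [gains[k] for k in lengths],
        "losses": [losses[k] for k in lengths],
    })
    table = net_gain_rates(table)
    return table.set_index("branch"), pd.DataFrame(placements)


def net_gain_rates(table: pd.DataFrame) -> pd.DataFrame:
    """rate = (gains - losses) / branch length (My); zero-length branches
    with events are flagged undefined (NaN rate)."""
    table = table.copy()
    net = table["gains"] - table["losses"]
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(table["length_my"] > 0, net / table["length_my"], np.nan)
    table["net_gain"] = net
    table["net_gain_rate"] = np.round(rate, 2)
    table["rate_undefined"] = (table["length_my"] == 0) & (net != 0)
    return table
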
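"""Three-way consensus miRNA target prediction on 3'UTRs.

Three independent scorers share one site vocabulary (7mer-A1, 7mer-m8,
8mer; perfect seed matches only):

* a seed matcher with a context-style score (site type, AU flank content,
  position; more negative is better; threshold <= -0.1);
* a weighted local duplex aligner over the site's +-20 nt window
  (miRanda-style; threshold > 140);
* an accessibility scorer combining a pairing-energy proxy with the cost
  of opening local secondary structure around the site (PITA-style;
  threshold <= -10).

Only interactions predicted by all three are retained as consensus,
keyed by (transcript, site end, site type).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import revcomp
from .fold import max_pairs_constrained, max_pairs_table

CONTEXT_MAX = -0.1
DUPLEX_MIN = 140.0
ACCESS_MAX = -10.0

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")


@dataclass
class TargetInteraction:
    mirna: str
    transcript: str
    start: int  # 0-based half-open on the UTR
    end: int
    site_type: str
    context_score: float = np.nan
    duplex_score: float = np.nan
    accessibility_score: float = np.nan
    consensus: bool = False

    @property
    def key(self):
        return (self.transcript, self.end, self.site_type)


# ---------------------------------------------------------------------------
# seed matcher


def _au_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("A") + seq.count("T") + seq.count("U")) / len(seq)


_TYPE_WEIGHT = {"8mer": 3.0, "7mer-m8": 2.0, "7mer-A1": 2.0}


def context_score(utr: str, start: int, end: int, site_type: str,
                  flank: int = 30) -> float:
    """Stand-in context score: -(0.05*type_weight + 0.02*AU_flank +
    positional closeness to the UTR ends), clipped to <= 0."""
    au = _au_fraction(utr[max(0, start - flank):start] + utr[end:end + flank])
    rel = min(start, len(utr) - end) / max(len(utr), 1)
    positional = 0.02 * (1.0 - min(rel * 4, 1.0))
    return min(0.0, -(0.05 * _TYPE_WEIGHT[site_type] + 0.02 * au + positional))


def seed_sites(mirna_id: str, mirna_seq: str, transcript: str,
               utr: str) -> list[TargetInteraction]:
    """Scan a UTR for perfect 7mer/8mer seed matches.

    Site sequences (5'->3' on the UTR): 7mer-m8 = revcomp(m2..m8);
    7mer-A1 = revcomp(m2..m7) + A; 8mer = revcomp(m2..m8) + A.  A position
    reports its best (longest) type only.  6mers are not sites.
    """
    m = mirna_seq.upper().replace("U", "T")
    if len(m) < 19:
        raise ValueError(f"mature miRNA {mirna_id} shorter than 19 nt")
    utr = utr.upper().replace("U", "T")
    m8 = revcomp(m[1:8])   # 7 nt
    m7 = revcomp(m[1:7])   # 6 nt
    sites: dict[tuple[int, int], str] = {}
    n8, n7m8, n7a1 = m8 + "A", m8, m7 + "A"
    for i in range(len(utr) - len(n8) + 1):
        if utr[i:i + 8] == n8:
            sites[(i, i + 8)] = "8mer"
    for i in range(len(utr) - 7 + 1):
        if utr[i:i + 7] == n7m8 and (i, i + 8) not in sites:
            sites[(i, i + 7)] = "7mer-m8"
    for i in range(len(utr) - 7 + 1):
        if utr[i:i + 7] == n7a1:
            # the trailing 7 nt of an 8mer also spell a 7mer-A1: report the
            # stronger type only, and never shadow a 7mer-m8 call
            if (i - 1, i + 7) in sites or (i, i + 7) in sites:
                continue
            sites[(i, i + 7)] = "7mer-A1"
    out = []
    for (s, e), st in sorted(sites.items()):
        out.append(TargetInteraction(
            mirna=mirna_id, transcript=transcript, start=s, end=e,
            site_type=st, context_score=context_score(utr, s, e, st)))
    return out


# ---------------------------------------------------------------------------
# duplex aligner


_GU = {("G", "T"), ("T", "G")}
_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def duplex_score(
    mirna_seq: str,
    utr: str,
    site_start: int,
    site_end: int,
    window: int = 20,
    match: float = 5.0,
    gu: float = 1.0,
    mismatch: float = -3.0,
    gap_open: float = -8.0,
    gap_extend: float = -2.0,
    seed_weight: float = 2.0,
) -> float:
    """Smith-Waterman complementarity score of the miRNA against the site
    +-window region, with seed positions (miRNA 2-8) doubly weighted.
    Scores count Watson-Crick (+5) and G:U (+1) pairs; empty windows score 0.
    """
    m = mirna_seq.upper().replace("U", "T")
    lo, hi = max(0, site_start - window), min(len(utr), site_end + window)
    w = utr[lo:hi].upper().replace("U", "T")
    if not w or not m:
        return 0.0
    # align miRNA 5'->3' against the reversed window so complementary
    # stretches appear as aligned "matches"
    wr = w[::-1]
    n1, n2 = len(m), len(wr)
    H = np.zeros((n1 + 1, n2 + 1))
    E = np.full((n1 + 1, n2 + 1), -np.inf)
    F = np.full((n1 + 1, n2 + 1), -np.inf)
    best = 0.0
    for i in range(1, n1 + 1):
        weight = seed_weight if 2 <= i <= 8 else 1.0
        for j in range(1, n2 + 1):
            pair = (m[i - 1], wr[j - 1])
            if pair in _WC:
                sub = match * weight
            elif pair in _GU:
                sub = gu * weight
            else:
                sub = mismatch * weight
            E[i, j] = max(E[i, j - 1] + gap_extend, H[i, j - 1] + gap_open)
            F[i, j] = max(F[i - 1, j] + gap_extend, H[i - 1, j] + gap_open)
            H[i, j] = max(0.0, H[i - 1, j - 1] + sub, E[i, j], F[i, j])
            if H[i, j] > best:
                best = H[i, j]
    return float(best)


# ---------------------------------------------------------------------------
# accessibility scorer


def accessibility_score(
    mirna_seq: str,
    utr: str,
    site_start: int,
    site_end: int,
    context: int = 15,
) -> float:
    """PITA-style ddG proxy: -(pairing energy of the seed-extended duplex)
    plus the cost of opening local structure at the site.

    Pairing energy counts -1 per Watson-Crick and -0.5 per G:U pair between
    the miRNA and the UTR region opposite it (the seed site extended
    5'-ward to the miRNA length - the full hybridization footprint);
    opening cost is the drop in maximum base-pair count of the footprint
    +-context window when the whole footprint is forced unpaired.  Lower is
    more favourable.
    """
    m = mirna_seq.upper().replace("U", "T")
    utr = utr.upper().replace("U", "T")
    ext_start = max(0, site_end - len(m))
    region = utr[ext_start:site_end]
    # pair miRNA 5'->3' with region 3'->5'
    rr = region[::-1]
    energy = 0.0
    for a, b in zip(m, rr):
        if (a, b) in _WC:
            energy -= 1.0
        elif (a, b) in _GU:
            energy -= 0.5
    lo, hi = max(0, ext_start - context), min(len(utr), site_end + context)
    wseq = utr[lo:hi]
    if len(wseq) < 2:
        return energy
    M = max_pairs_table(wseq)
    free_pairs = int(M[0, len(wseq) - 1])
    forbidden = set(range(ext_start - lo, site_end - lo))
    open_pairs = max_pairs_constrained(wseq, forbidden)
    opening = free_pairs - open_pairs
    return energy + opening


# ---------------------------------------------------------------------------
# consensus


def consensus_targets(
    interactions: list[TargetInteraction],
    context_max: float = CONTEXT_MAX,
    duplex_min: float = DUPLEX_MIN,
    access_max: float = ACCESS_MAX,
) -> list[TargetInteraction]:
    """Retain interactions passing all three thresholds (the AND rule).

    All three scores must be present on each interaction (the scorers are
    run on identical site coordinates); missing scores raise.
    """
    out = []
    for it in interactions:
        for name, v in (("context", it.context_score),
                        ("duplex", it.duplex_score),
                        ("accessibility", it.accessibility_score)):
            if v is None or (isinstance(v, float) and np.isnan(v)):
                raise ValueError(
                    f"{name} score missing for site {it.key} of {it.mirna}")
        it.consensus = (
            it.context_score <= context_max
            and it.duplex_score > duplex_min
            and it.accessibility_score <= access_max
            and it.site_type in SITE_TYPES
        )
        if it.consensus:
            out.append(it)
    return out


def predict_targets(
    mirnas: dict[str, str],
    utrs: dict[str, str],
    context_max: float = CONTEXT_MAX,
    duplex_min: float = DUPLEX_MIN,
    access_max: float = ACCESS_MAX,
) -> tuple[list[TargetInteraction], list[TargetInteraction]]:
    """Run all three scorers over every (miRNA, UTR) pair.

    Returns (all scored interactions, consensus subset).
    """
    scored: list[TargetInteraction] = []
    for mid, mseq in mirnas.items():
        for tx, utr in utrs.items():
            for it in seed_sites(mid, mseq, tx, utr):
                it.duplex_score = duplex_score(mseq, utr, it.start, it.end)
                it.accessibility_score = accessibility_score(
                    mseq, utr, it.start, it.end)
                scored.append(it)
    cons = consensus_targets(scored, context_max, duplex_min, access_max)
    return scored, cons
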
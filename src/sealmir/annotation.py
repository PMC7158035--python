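"""Hairpin discovery, miR-likeness classification, merging and curation.

Candidate pre-miRNA loci are called from stacks of perfectly aligned reads:
two nearby same-strand stacks (the putative 5p and 3p arms) define a
window that is excised and folded.  Candidates from independent callers
are merged strand-aware, then curated with four filters: expression
evidence on both arms, perfect alignments only, a miR-like fold, and a
minimum of 10 perfectly mapping reads.  Curated loci are labelled miRBase
or novel by mature-sequence match against a reference mature database.
"""

from __future__ import annotations

from collections import Counter, defaultdict

import pandas as pd

from .containers import CountMatrix, HairpinLocus
from .fold import (FoldStructure, MAX_HAIRPIN_LEN, MIN_HAIRPIN_LEN,
                   fold_hairpin, fold_sequence)
from .preprocess import ARM_TOLERANCE, ExactHit, assign_arm
from ._seq import revcomp

__all__ = [
    "candidate_loci", "fold_hairpin", "classify_hairpin", "merge_predictions",
    "curate", "arm_switch_screen", "FoldStructure",
]


# ---------------------------------------------------------------------------
# candidate calling from read stacks


def _stacks(hits: list[ExactHit], min_stack: int):
    """Cluster overlapping same-strand hits; keep stacks with total
    multiplicity >= min_stack.  A stack's interval is its dominant (most
    abundant) read interval."""
    by_key: dict[tuple[str, str], list[ExactHit]] = defaultdict(list)
    for h in hits:
        by_key[(h.chrom, h.strand)].append(h)
    stacks = []
    for (chrom, strand), hs in by_key.items():
        hs.sort(key=lambda h: (h.start, h.end))
        cur: list[ExactHit] = []
        cur_end = -1
        for h in hs + [None]:
            if h is not None and (not cur or h.start < cur_end):
                cur.append(h)
                cur_end = max(cur_end, h.end)
                continue
            if cur:
                total = sum(x.count for x in cur)
                if total >= min_stack:
                    iv = Counter()
                    for x in cur:
                        iv[(x.start, x.end)] += x.count
                    dom = max(sorted(iv), key=lambda k: iv[k])
                    stacks.append({"chrom": chrom, "strand": strand,
                                   "start": min(x.start for x in cur),
                                   "end": cur_end, "dom": dom, "count": total})
            if h is not None:
                cur = [h]
                cur_end = h.end
    stacks.sort(key=lambda s: (s["chrom"], s["strand"], s["start"]))
    return stacks


def candidate_loci(
    hits: list[ExactHit],
    genome: dict[str, str],
    min_stack: int = 5,
    window: int = 120,
    flank: int = 0,
    caller: str = "callerA",
) -> list[HairpinLocus]:
    """Call candidate hairpins from read stacks.

    Adjacent same-strand stacks separated by at most `window` nt are taken
    as the two arms of one hairpin; the spanning window plus `flank` nt on
    each side is excised and folded (two arm stacks already cover the full
    hairpin, so the default adds no flank).  Isolated stacks are emitted
    with a single known arm (they cannot survive curation's both-arms
    filter but are reported for audit).
    """
    stacks = _stacks(hits, min_stack)
    out: list[HairpinLocus] = []
    used = [False] * len(stacks)
    idx = 0
    for i, s in enumerate(stacks):
        if used[i]:
            continue
        partner = None
        if i + 1 < len(stacks):
            t = stacks[i + 1]
            if (t["chrom"], t["strand"]) == (s["chrom"], s["strand"]) and \
                    t["start"] - s["end"] <= window and not used[i + 1]:
                partner = i + 1
        members = [s] if partner is None else [s, stacks[partner]]
        if partner is not None:
            used[partner] = True
        used[i] = True
        chrom, strand = s["chrom"], s["strand"]
        gstart = max(0, min(m["start"] for m in members) - flank)
        gend = min(len(genome[chrom]), max(m["end"] for m in members) + flank)
        if not (MIN_HAIRPIN_LEN <= gend - gstart <= MAX_HAIRPIN_LEN):
            continue
        gseq = genome[chrom][gstart:gend]
        hairpin = gseq if strand == "+" else revcomp(gseq)
        fold = fold_sequence(hairpin)
        # left genomic stack is 5p on +, 3p on -
        doms = sorted((m["dom"] for m in members))
        if len(members) == 2:
            left, right = doms
            arm5p, arm3p = (left, right) if strand == "+" else (right, left)
        else:
            arm5p = doms[0] if strand == "+" else None
            arm3p = None if strand == "+" else doms[0]
        lid = f"cand{idx:04d}"
        idx += 1
        loc = HairpinLocus(
            id=lid, chrom=chrom, start=gstart, end=gend, strand=strand,
            hairpin_seq=hairpin, fold=fold.dotbracket,
            arm5p=arm5p, arm3p=arm3p,
            mature5p=_arm_seq(genome, chrom, strand, arm5p, "5p"),
            mature3p=_arm_seq(genome, chrom, strand, arm3p, "3p"),
            status="candidate", provenance=caller,
        )
        loc.extra["fold_structure"] = fold
        loc.extra["stack_count"] = sum(m["count"] for m in members)
        out.append(loc)
    return out


def _arm_seq(genome, chrom, strand, iv, _arm) -> str:
    if iv is None:
        return ""
    seq = genome[chrom][iv[0]:iv[1]]
    return seq if strand == "+" else revcomp(seq)


# ---------------------------------------------------------------------------
# classification


def classify_hairpin(
    fold: FoldStructure,
    min_duplex_pairs: int = 14,
    loop_range: tuple[int, int] = (3, 30),
    max_unpaired: float = 0.5,
) -> bool:
    """miR-like iff one dominant stem (ignoring stems under 3 pairs), at
    least `min_duplex_pairs` pairs joining the arms, a terminal loop of
    3-30 nt, and at most half the bases unpaired."""
    return (
        fold.n_stems == 1
        and fold.duplex_pairs >= min_duplex_pairs
        and loop_range[0] <= fold.loop_size <= loop_range[1]
        and fold.unpaired_fraction <= max_unpaired
    )


# ---------------------------------------------------------------------------
# merging caller predictions


def _parse_bed6(lines, name):
    out = []
    for ln, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise ValueError(f"{name}: malformed BED line {ln}: {line!r}")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"{name}: malformed BED line {ln}: {line!r}") from exc
        out.append((parts[0], start, end, parts[3], parts[5]))
    return out


def merge_predictions(set_a, set_b, names=("callerA", "callerB")) -> list[HairpinLocus]:
    """Strand-aware union of overlapping intervals from two callers.

    Inputs are HairpinLocus lists or iterables of BED6 lines.  Output
    intervals are non-overlapping per (chrom, strand), with provenance
    callerA/callerB/both.
    """
    def norm(s, name, tag):
        ivs = []
        if s and isinstance(next(iter(s)), HairpinLocus):
            for lc in s:
                ivs.append((lc.chrom, lc.start, lc.end, lc.strand, tag, lc))
        else:
            for chrom, start, end, _nm, strand in _parse_bed6(s, name):
                ivs.append((chrom, start, end, strand, tag, None))
        return ivs

    ivs = norm(list(set_a), names[0], names[0]) + norm(list(set_b), names[1], names[1])
    by_key = defaultdict(list)
    for iv in ivs:
        by_key[(iv[0], iv[3])].append(iv)
    merged: list[HairpinLocus] = []
    idx = 0
    for (chrom, strand) in sorted(by_key):
        group = sorted(by_key[(chrom, strand)], key=lambda iv: (iv[1], iv[2]))
        cur = None
        for iv in group + [None]:
            if iv is not None and cur is not None and iv[1] < cur["end"]:
                cur["end"] = max(cur["end"], iv[2])
                cur["tags"].add(iv[4])
                cur["members"].append(iv[5])
                continue
            if cur is not None:
                prov = "both" if len(cur["tags"]) == 2 else next(iter(cur["tags"]))
                rep = next((m for m in cur["members"] if m is not None), None)
                loc = HairpinLocus(
                    id=f"merged{idx:04d}", chrom=chrom, start=cur["start"],
                    end=cur["end"], strand=strand, provenance=prov,
                )
                if rep is not None and rep.start == cur["start"] and rep.end == cur["end"]:
                    loc.hairpin_seq = rep.hairpin_seq
                    loc.fold = rep.fold
                    loc.arm5p, loc.arm3p = rep.arm5p, rep.arm3p
                    loc.mature5p, loc.mature3p = rep.mature5p, rep.mature3p
                    loc.extra = dict(rep.extra)
                idx += 1
                merged.append(loc)
            if iv is not None:
                cur = {"start": iv[1], "end": iv[2], "tags": {iv[4]},
                       "members": [iv[5]]}
            else:
                cur = None
    return merged


# ---------------------------------------------------------------------------
# curation


def curate(
    candidates: list[HairpinLocus],
    hits: list[ExactHit],
    min_reads: int = 10,
    mature_db: dict[str, str] | None = None,
    tolerance: int = ARM_TOLERANCE,
) -> list[HairpinLocus]:
    """The four-filter high-confidence screen.

    Keeps candidates with (i) at least one perfect read on each arm across
    the pooled libraries, (ii) only perfect alignments counted (guaranteed
    upstream), (iii) a miR-like fold, and (iv) at least `min_reads`
    perfect reads in the locus.  Kept loci are labelled miRBase when either
    mature arm matches the reference mature database by perfect substring
    (either direction), novel otherwise.
    """
    by_chrom: dict[str, list[ExactHit]] = defaultdict(list)
    for h in hits:
        by_chrom[h.chrom].append(h)
    kept = []
    for cand in candidates:
        fold = cand.extra.get("fold_structure")
        if fold is None:
            if not cand.hairpin_seq:
                continue
            fold = fold_hairpin(cand.hairpin_seq)
            cand.extra["fold_structure"] = fold
        inside = [h for h in by_chrom.get(cand.chrom, [])
                  if h.start >= cand.start and h.end <= cand.end
                  and h.strand == cand.strand]
        total = sum(h.count for h in inside)
        arm_reads = {"5p": 0, "3p": 0}
        for h in inside:
            arm = assign_arm(h, cand, tolerance)
            if arm is not None:
                arm_reads[arm] += h.count
        if arm_reads["5p"] < 1 or arm_reads["3p"] < 1:
            continue
        if not classify_hairpin(fold):
            continue
        if total < min_reads:
            continue
        lc = cand
        lc.status = "high_confidence"
        lc.extra["total_reads"] = total
        lc.extra["arm_reads"] = dict(arm_reads)
        if mature_db is not None:
            lc.annotation_class = "novel"
            for arm_seq in (lc.mature5p, lc.mature3p):
                if not arm_seq:
                    continue
                for ref in mature_db.values():
                    if arm_seq in ref or ref in arm_seq:
                        lc.annotation_class = "miRBase"
                        break
                if lc.annotation_class == "miRBase":
                    break
        kept.append(lc)
    return kept


# ---------------------------------------------------------------------------
# arm switching


def arm_switch_screen(counts: CountMatrix, min_reads: int = 10) -> pd.DataFrame:
    """Dominant arm per locus per sample and a switching flag.

    A locus is flagged as switching when two samples, each with >=
    `min_reads` reads on both arms, disagree on the most abundant arm.
    Ties are marked indeterminate and never drive a switch call.
    """
    strands = list(counts.counts.index)
    loci = sorted({s.rsplit("-", 1)[0] for s in strands})
    rows = []
    for locus in loci:
        r5, r3 = f"{locus}-5p", f"{locus}-3p"
        if r5 not in counts.counts.index or r3 not in counts.counts.index:
            continue
        c5, c3 = counts.counts.loc[r5], counts.counts.loc[r3]
        dominant = {}
        confident = []
        for lib in counts.counts.columns:
            a, b = int(c5[lib]), int(c3[lib])
            if a == b:
                dominant[lib] = "tie"
            else:
                dominant[lib] = "5p" if a > b else "3p"
                if a >= min_reads and b >= min_reads:
                    confident.append(dominant[lib])
        switching = len(set(confident)) > 1
        rows.append({"locus": locus, "switching": switching,
                     "n_confident_samples": len(confident),
                     **{f"dom_{lib}": d for lib, d in dominant.items()}})
    return pd.DataFrame(rows).set_index("locus") if rows else pd.DataFrame(
        columns=["switching"])
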
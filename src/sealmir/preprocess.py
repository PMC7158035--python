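"""Adapter trimming, exact genome alignment, hairpin rescue, and counting.

Small-RNA reads carry the 3' sequencing adapter; trimming removes the
longest 3' suffix that matches a prefix of the adapter exactly (minimum
overlap 5 nt) and discards inserts shorter than 16 nt.  Alignment is
perfect-match only — no gaps or mismatches — reporting every occurrence on
both strands.  Reads that miss the genome can be rescued by perfect
substring match against a reference hairpin database, which captures
mature miRNAs whose loci are absent from an incomplete assembly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

from ._seq import find_all, revcomp
from .containers import CountMatrix, HairpinLocus

MIN_READ_LEN = 16


@dataclass
class TrimStats:
    total_reads: int = 0
    with_adapter: int = 0
    too_short: int = 0
    kept: int = 0

    @property
    def kept_unique(self) -> int:  # filled by trim_adapter
        return getattr(self, "_kept_unique", 0)


@dataclass
class ExactHit:
    seq: str
    count: int
    chrom: str
    start: int
    end: int
    strand: str


def _iter_reads(reads):
    """Accept a FASTQ path, an iterable of sequences, or (id, seq) pairs."""
    if isinstance(reads, (str,)) or hasattr(reads, "read"):
        for rec in SeqIO.parse(reads, "fastq"):
            yield str(rec.seq)
    else:
        for r in reads:
            yield r[1] if isinstance(r, tuple) else str(r)


def trim_adapter(reads, adapter: str, min_overlap: int = 5):
    """Trim the 3' adapter, drop short inserts, collapse identical reads.

    Returns (collapsed: dict seq -> multiplicity, stats: TrimStats).
    """
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    stats = TrimStats()
    collapsed: Counter[str] = Counter()
    for seq in _iter_reads(reads):
        seq = seq.upper()
        stats.total_reads += 1
        cut = None
        # longest suffix equal to an adapter prefix, zero mismatches
        lo = max(0, len(seq) - len(adapter))
        for i in range(lo, len(seq) - min_overlap + 1):
            if seq[i:] == adapter[: len(seq) - i]:
                cut = i
                break
        if cut is not None:
            stats.with_adapter += 1
            seq = seq[:cut]
        if len(seq) < MIN_READ_LEN:
            stats.too_short += 1
            continue
        stats.kept += 1
        collapsed[seq] += 1
    stats._kept_unique = len(collapsed)
    return dict(collapsed), stats


def align_exact(collapsed: dict[str, int], genome: dict[str, str]):
    """All perfect occurrences of each read on both strands.

    Returns (hits: list[ExactHit], unmapped: dict seq -> multiplicity).
    Reads containing non-ACGT characters never match.
    """
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("genome is empty")
    hits: list[ExactHit] = []
    unmapped: dict[str, int] = {}
    for seq, count in collapsed.items():
        found = False
        if set(seq) <= set("ACGT"):
            for chrom, gseq in genome.items():
                for pos in find_all(seq, gseq):
                    hits.append(ExactHit(seq, count, chrom, pos, pos + len(seq), "+"))
                    found = True
                rc = revcomp(seq)
                for pos in find_all(rc, gseq):
                    hits.append(ExactHit(seq, count, chrom, pos, pos + len(seq), "-"))
                    found = True
        if not found:
            unmapped[seq] = count
    return hits, unmapped


def rescue_unmapped(unmapped: dict[str, int], hairpin_db: dict[str, str]):
    """Perfect ungapped substring matches of unmapped reads within reference
    hairpins.  Returns (matches: list of (seq, count, hairpin id),
    per_hairpin: dict hairpin id -> total rescued reads)."""
    if not hairpin_db:
        raise ValueError("hairpin database is empty")
    matches = []
    per_hairpin: Counter[str] = Counter()
    for seq, count in unmapped.items():
        for hp_id, hp_seq in hairpin_db.items():
            if seq in hp_seq:
                matches.append((seq, count, hp_id))
                per_hairpin[hp_id] += count
    return matches, dict(per_hairpin)


ARM_TOLERANCE = 3  # nt of 5'-end wobble allowed in arm assignment


def assign_arm(hit: ExactHit, locus: HairpinLocus,
               tolerance: int = ARM_TOLERANCE) -> str | None:
    """Assign a hit to 5p/3p if its 5' end is within +-tolerance of the
    arm's annotated 5' end; otherwise loop/other (None)."""
    if hit.strand != locus.strand:
        return None
    read5 = hit.start if hit.strand == "+" else hit.end
    for arm in ("5p", "3p"):
        a5 = locus.arm_5prime_end(arm)
        if a5 is not None and abs(read5 - a5) <= tolerance:
            return arm
    return None


def count_matrix(
    hits_by_sample: dict[str, list[ExactHit]],
    loci: list[HairpinLocus],
    samples: pd.DataFrame,
    tolerance: int = ARM_TOLERANCE,
) -> CountMatrix:
    """Per mature strand (locus x arm) read counts over samples.

    Multi-locus reads are counted at every matching locus (no
    fractionation).  Rows exist for every locus arm even when all-zero.
    """
    for lib in hits_by_sample:
        if lib not in samples.index:
            raise ValueError(f"sample metadata missing library: {lib}")
    rows = []
    for lc in loci:
        rows += [f"{lc.id}-5p", f"{lc.id}-3p"]
    counts = pd.DataFrame(0, index=rows, columns=list(samples.index))
    by_chrom: dict[str, list[HairpinLocus]] = {}
    for lc in loci:
        by_chrom.setdefault(lc.chrom, []).append(lc)
    for lib, hits in hits_by_sample.items():
        for hit in hits:
            for lc in by_chrom.get(hit.chrom, []):
                if hit.start >= lc.start and hit.end <= lc.end:
                    arm = assign_arm(hit, lc, tolerance)
                    if arm is not None:
                        counts.loc[f"{lc.id}-{arm}", lib] += hit.count
    return CountMatrix(counts, samples)
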
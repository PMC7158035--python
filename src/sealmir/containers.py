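"""Shared in-memory containers for the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

SAMPLE_TYPES = ("brain", "heart", "muscle", "plasma")
AGES = ("pup", "adult")


def default_design(n_replicates: int = 3) -> list[tuple[str, str, int]]:
    """The 4 sample types x 2 ages x n replicates library design."""
    return [
        (st, age, rep)
        for st in SAMPLE_TYPES
        for age in AGES
        for rep in range(1, n_replicates + 1)
    ]


def sample_id(sample_type: str, age: str, replicate: int) -> str:
    return f"{sample_type}_{age}_{replicate}"


@dataclass
class CountMatrix:
    """Per-mature-strand read counts with sample metadata.

    counts: rows are mature strands (named ``<locus>-5p`` / ``<locus>-3p``),
    columns are sample ids.  samples: indexed by sample id, with columns
    sample_type, age, replicate.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in self.counts.columns if c not in self.samples.index]
        if missing:
            raise ValueError(f"sample metadata missing libraries: {missing}")
        self.samples = self.samples.loc[list(self.counts.columns)]

    def triplet_max_total(self, strand: str) -> int:
        """Largest raw-count total over any (sample_type, age) replicate
        triplet, the unit of the >=30-read expression filter."""
        row = self.counts.loc[strand]
        totals = row.groupby(
            [self.samples["sample_type"], self.samples["age"]]
        ).sum()
        return int(totals.max())

    def subset_samples(self, mask: pd.Series) -> "CountMatrix":
        keep = self.samples.index[mask]
        return CountMatrix(self.counts[keep].copy(), self.samples.loc[keep].copy())


@dataclass
class Gene:
    id: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class HairpinLocus:
    """A pre-miRNA locus: genomic interval, folded hairpin, and the two
    mature arms.  Coordinates are 0-based half-open; arm intervals are
    genomic.  The hairpin sequence is in transcript (sense) orientation."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    hairpin_seq: str = ""
    fold: str = ""
    arm5p: tuple[int, int] | None = None
    arm3p: tuple[int, int] | None = None
    mature5p: str = ""
    mature3p: str = ""
    status: str = "candidate"  # candidate | high_confidence
    provenance: str = ""  # callerA | callerB | both
    annotation_class: str = ""  # miRBase | novel
    extra: dict = field(default_factory=dict)

    def arm_5prime_end(self, arm: str) -> int | None:
        """Genomic coordinate of the arm's 5' end (strand-aware)."""
        iv = self.arm5p if arm == "5p" else self.arm3p
        if iv is None:
            return None
        return iv[0] if self.strand == "+" else iv[1]
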
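"""Readers/writers for the standard formats the pipeline speaks.

FASTA via Biopython; BED6 (0-based half-open), GFF3 and TSV as plain text.
All outputs are deterministic in input order.
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import Gene, HairpinLocus


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(loci: list[HairpinLocus], path) -> None:
    with open(path, "w") as fh:
        for lc in loci:
            fh.write(f"{lc.chrom}\t{lc.start}\t{lc.end}\t{lc.id}\t0\t{lc.strand}\n")


def read_bed(path) -> list[HairpinLocus]:
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise ValueError(f"{path}: malformed BED line {ln}")
        out.append(HairpinLocus(id=parts[3], chrom=parts[0], start=int(parts[1]),
                                end=int(parts[2]), strand=parts[5]))
    return out


def write_gff3(genes: list[Gene], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\tsealmir\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.id}\n")


def read_gff3(path) -> list[Gene]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
        out.append(Gene(id=attrs.get("ID", ""), chrom=f[0],
                        start=int(f[3]) - 1, end=int(f[4]), strand=f[6]))
    return out
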
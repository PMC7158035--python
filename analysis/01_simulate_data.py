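#!/usr/bin/env python
"""Generate the full synthetic study inputs with planted ground truth.

Writes the toy genome, gene models, planted hairpin loci, the 8 derived
species genomes with their per-branch event truth, the 24 small-RNA
libraries (FASTQ), the true count matrix, UTRs and the term table.
"""

import argparse
from pathlib import Path

from sealmir import io
from sealmir.synthetic_data import (SimConfig, build_toy_genome,
                                    derive_species_genomes,
                                    simulate_libraries,
                                    simulate_utrs_and_terms, write_fastq)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/simulated"))
    args = ap.parse_args()
    out = args.out
    (out / "reads").mkdir(parents=True, exist_ok=True)
    (out / "species").mkdir(exist_ok=True)

    cfg = SimConfig(seed=args.seed)
    toy = build_toy_genome(cfg)
    io.write_fasta(toy.genome, out / "genome.fa")
    io.write_gff3(toy.genes, out / "genes.gff3")
    io.write_bed(toy.truth.loci, out / "planted_loci.bed")
    io.write_fasta(toy.truth.hairpin_db, out / "reference_hairpins.fa")
    io.write_fasta(toy.truth.mature_db, out / "reference_matures.fa")
    print(f"genome: {len(toy.genome['chr1'])} bp, "
          f"{len(toy.truth.loci)} planted hairpins, {len(toy.genes)} genes")

    sp = derive_species_genomes(toy)
    for taxon, genome in sp.genomes.items():
        io.write_fasta(genome, out / "species" / f"{taxon}.fa")
        io.write_gff3(sp.genes[taxon], out / "species" / f"{taxon}.gff3")
        io.write_bed(sp.loci[taxon], out / "species" / f"{taxon}_loci.bed")
    sp.presence.to_csv(out / "species" / "presence_truth.tsv", sep="\t")
    sp.events.to_csv(out / "species" / "events_truth.tsv", sep="\t",
                     index=False)
    print(f"species: {len(sp.genomes)} genomes, "
          f"{sp.presence.shape[1]} hairpin families, "
          f"{int(sp.events['gains'].sum())} gains / "
          f"{int(sp.events['losses'].sum())} losses on the tree")

    sim = simulate_libraries(toy)
    for lib, reads in sim.reads.items():
        write_fastq(reads, out / "reads" / f"{lib}.fastq")
    sim.true_counts.counts.to_csv(out / "true_counts.tsv", sep="\t")
    sim.true_counts.samples.to_csv(out / "samples.tsv", sep="\t")
    sim.stats.to_csv(out / "library_stats.tsv", sep="\t")
    print(f"libraries: {len(sim.reads)} FASTQ files, "
          f"{int(sim.stats['n_reads'].sum())} reads total")

    u = simulate_utrs_and_terms(toy)
    io.write_fasta(u.utrs, out / "utrs.fa")
    u.term_table.to_csv(out / "term_table.tsv", sep="\t", index=False)
    u.true_sites.to_csv(out / "true_target_sites.tsv", sep="\t", index=False)
    print(f"UTRs: {len(u.utrs)} transcripts, "
          f"{len(u.true_sites)} planted sites "
          f"({int(u.true_sites['accessible'].sum())} accessible), "
          f"enriched term {u.enriched_term}")


if __name__ == "__main__":
    main()
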
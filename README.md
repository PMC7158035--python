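# sealmir

A tested reimplementation of the computational core of a small-RNA
profiling study in a non-model marine mammal: annotation of miRNA loci
from small-RNA reads, conservative consensus differential expression
across tissues and ages, orthogroup gain/loss evolution on a dated
phylogeny, three-way consensus target prediction, and
enrichment/tissue-specificity statistics. Because the original sequencing
data and eight genome assemblies are far beyond desk scale, the package
ships a first-class synthetic-data module that generates every input with
planted ground truth, so each stage can be validated end-to-end against
known answers.

It is intended for bioinformaticians who want an auditable, dependency-light
version of this kind of pipeline: every bespoke step is implemented
directly and cross-checked against an independent brute-force oracle or
the generator's truth tables.

## What the pipeline computes

- **Annotation.** Adapter-trimmed reads (inserts ≥ 16 nt) are aligned to
  the genome with no gaps or mismatches; reads that miss the assembly are
  rescued by perfect substring match against a reference hairpin database.
  Candidate pre-miRNAs called from paired read stacks are folded by a
  Nussinov-style base-pair-maximization DP (Watson–Crick + G:U, minimum
  loop 3) and curated with four filters: expression on both arms, perfect
  alignments only, a miR-like fold, and ≥ 10 perfect reads. Curated loci
  are labelled miRBase/novel by mature-sequence match.
- **Differential expression.** Median-of-ratios size factors s_j, a
  method-of-moments NB dispersion α_i shrunk 50/50 (log scale) toward a
  mean–dispersion trend, then per strand a NB log-linear model
  log μ_ij = x_jᵀβ_i + log s_j with a Wald test on the contrast and BH
  correction (q ≤ 0.05). A strand is tissue-specific only if concordantly
  significant in **all three** pairwise comparisons against the other
  sample types, and any call needs one replicate triplet totalling ≥ 30
  raw reads. Age contrasts are reported adult-relative-to-pup.
- **Evolution.** Hairpins from all taxa are clustered greedily at 80%
  global identity; assemblies missing a family are rescued by an ungapped
  seed-and-extend search (Karlin–Altschul E ≤ 10⁻⁶, alignment ≥ 40 nt)
  with synteny support from flanking protein-coding genes; Dollo parsimony
  places one gain per orthogroup above the LCA of its carriers and counts
  losses on carrier-free subtrees; branch rates are (gains − losses)/My.
- **Targets.** Three independent scorers over 3′UTR seed sites (8mer,
  7mer-m8, 7mer-A1): a context-style score (≤ −0.1), a weighted
  Smith–Waterman duplex score (> 140), and an accessibility score
  combining duplex energy with the structure-opening cost of the site
  footprint (≤ −10). Only sites passing all three count, feeding
  hypergeometric term enrichment against the full prediction background
  and a pooled two-proportion z-test of tissue specificity.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (any `--seed`; tables land under `results/`):

```
$ python analysis/02_annotate_mirnas.py --seed 1
curated 50 loci (30 miRBase / 20 novel); recall 100%, precision 100%
mapped read fraction: tissues 70.1%, plasma 55.1%
arm-switching loci flagged: 3

$ python analysis/04_gain_loss_evolution.py --seed 1
Dollo vs brute force on all 255 presence patterns: 100% agreement
114 orthogroups; clusters pure: True
hidden annotations rescued by synteny: 46/46
per-branch gains/losses match truth on 100% of branches; net gain rates exact: True

$ python analysis/05_targets_enrichment.py --seed 1
consensus interactions: 10; planted accessible sites recovered 100%, stem-buried decoys rejected 100%
planted term is the top enrichment hit (q = 4.67e-07)
tissue-specific share in brain-expressed families: novel 88% vs annotated 0% (z = 5.68, p = 1.3e-08)
```

The annotation run recovers every planted hairpin with no false loci; the
mapped-read fractions (~70% in tissues, ~55% in plasma) reflect the
simulated assembly incompleteness, with plasma-heavy off-genome reads
rescued from the reference hairpin database. The evolution run hides 10%
of the species annotations and recovers all of them through the
synteny-supported homolog search before reconstructing the exact
per-branch event history.

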
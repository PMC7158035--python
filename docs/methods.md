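# Methods

## Scope and overall design

The package rebuilds, as a library plus thin analysis drivers, the
bespoke computation of a small-RNA miRNAome study: locus curation from
reads, conservative consensus differential expression, gene-family
gain/loss evolution, consensus target prediction and enrichment
statistics. External heavyweight tools that the original workflow wrapped
(miRNA predictors, thermodynamic folders, BLAST, DESeq2, dollop) are
replaced by defined, auditable procedures with the same acceptance
regions, each validated against an independent oracle or planted truth.
The synthetic-data module is first-class: it defines the study conditions
under which every claim in the test suite is measured.

## Synthetic data: what it emulates, and what it does not

`synthetic_data.SimConfig` fixes the whole experiment from one seed; all
generators are pure functions of the config, so outputs are
byte-identical across runs.

- **Toy genome.** One ~200 kb chromosome with 50 planted pre-miRNA
  stem-loops interleaved with ~60 protein-coding genes (every hairpin has
  flanking genes, which the synteny rescue needs). Hairpins are built as
  arm (20–23 nt) + loop (8–20 nt) + near-reverse-complement arm with 1–2
  mismatches. Draws are rejected until the construct folds miR-like under
  the package's own classifier ("perfect by construction"): planted truth
  is then a guarantee, not a probability. At least one mismatch is always
  planted because a perfectly palindromic stem would let mature reads
  align to both genomic strands, which real pre-miRNAs do not do.
- **Species genomes.** The layout evolves along an 8-taxon, ~620 My
  phylogeny (branch lengths in My). Per branch, families are gained
  (fresh hairpins, unique identity — gains are never repeated) and lost
  as Poisson events at 0.10 and 0.05 per My, giving on the order of 100
  surviving orthogroups. With `dollo_consistent` (default), a loss is
  vetoed when it would make the true event history unrecoverable from the
  leaf presence pattern (extinction of a family, sibling losses that
  merge, or pruning the gain clade's LCA); realized events are what the
  truth table records. Substitutions run at 5×10⁻⁴/site/My and are capped
  at 10% divergence from the family founder, so any two family members
  stay within the 80% clustering band; a configurable divergence event
  (default off) and relocation probability (default 2%) provide the
  below-band and synteny-broken cases.
- **Libraries.** The 4 sample types × 2 ages × 3 replicates design. Per
  strand and library, counts are NB(μ, α = 0.1) with
  μ = depth · w_family · arm share · 2^(planted log2FC effects), a 4:1
  5p:3p arm ratio, and depth 20 000 reads/library by default. Reads are
  the mature sequence plus the 3′ adapter with constant qualities;
  off-genome hairpin families supply 30% of tissue and 45% of plasma
  reads, reproducing the ~70% / 43–55% genome-mappable fractions the
  study design anticipates. A 2% stream of <16 nt junk inserts exercises
  the trimming bookkeeping. Not emulated: realistic base composition,
  quality-score models, ligation bias, sequencing errors (a config knob,
  default 0 — the curation filters demand perfect matches, so error
  injection is a separate stress test).
- **UTRs and terms.** Planted regulators are canonical matures (≥ 22 nt,
  5′ U) whose full-complement site is verified, with the package's own
  accessibility scorer, to score open in a poly-A context and closed
  inside the decoy construct; matures with strongly self-structured sites
  are not used as regulators. Accessible sites sit in 20 nt poly-A
  flanks; decoys sandwich the same site between two tight stems whose
  partners lie inside the ±15 nt accessibility window. The term table
  annotates most true target genes with one term, plus random terms.

Because planted hairpins and sites are verified by construction, passing
tests demonstrate the pipeline's bookkeeping and rules are exact under
clean conditions; they say nothing about behaviour on degraded real data
(sequencing errors, isomiR clouds, repetitive genomes).

## Folding and miR-likeness

`fold.fold_hairpin` maximizes nested base pairs (Watson–Crick + G:U,
minimum loop 3) by dynamic programming, with a deterministic traceback
that always pairs the smallest available 5′ index with its smallest
admissible partner. `n_pairs` is the true optimum (checked against
exhaustive enumeration for short sequences). Pair maximization decorates
real stems with spurious lone pairs, so the stem-level statistics are
read from a cleaned copy: helices stacked fewer than 3 deep are dropped,
then terminal stems of < 3 pairs are pruned while more than one hairpin
loop remains. A fold is miR-like iff one dominant stem remains, ≥ 14
pairs join the arms, the terminal loop is 3–30 nt and ≤ 50% of bases are
unpaired; all thresholds are keyword-configurable stand-ins for an
otherwise unstated "miR-like" criterion.

## Preprocessing decisions

Arm assignment tolerates ±3 nt at the read 5′ end (5′ ends of miRNAs are
homogeneous; 3′ ends are ragged). Multi-mapping reads are counted at
every matching locus — the simplest auditable rule. Identical reads are
collapsed before alignment and multiplicities propagate. Adapter
trimming removes the longest 3′ suffix matching an adapter prefix
(≥ 5 nt overlap, no mismatches); error-tolerant trimming is out of scope.

## Differential expression

Size factors are median-of-ratios over strands positive in all samples
(geometric-mean fallback with a warning otherwise), normalized to unit
geometric mean. Dispersion is a method-of-moments estimate pooled over
design cells, with the small-sample correction that the squared cell mean
overstates μ² by Var(mean) = v/n; estimates are shrunk 50/50 on the log
scale toward a 10-bin mean–dispersion trend. The per-strand model is a
statsmodels NB GLM with log size-factor offsets and an additive design
(no interactions — the study names factors, not interactions); pairwise
tissue contrasts come from one joint 4-level model with age as a fixed
factor (per-tissue age analyses refit on the subset). Wald p-values are
two-sided normal; BH is a hand-rolled step-up with NaNs excluded from m.
On null 3-vs-3 data the measured type-I error at p < 0.05 is ~0.06 —
mildly anticonservative, as expected for Wald tests at n = 3, and the BH
layer leaves essentially no null discoveries. The ≥ 30-read triplet
filter is applied after testing, exactly as specified, and is exercised
at its 29/30 boundary with synthetic significance so the rule is tested
in isolation from GLM behaviour at degenerate counts.

## Evolution

Clustering identity is matches/columns of a global alignment (+1/−1/−2)
via Biopython's PairwiseAligner; CD-HIT's word heuristics are omitted at
desk scale. The homolog search is ungapped seed-and-extend (word 11,
+1/−2, X-drop 20) with E = K·m·n·e^(−λS); λ solves
Σ pᵢpⱼe^(λsᵢⱼ) = 1 and K comes from the Karlin–Altschul series
K = e^(−2Σₖ k⁻¹[P(Sₖ≥0) + E(e^(λSₖ); Sₖ<0)]) · λδ / (H(1−e^(−λδ))),
validated against the published ungapped constants for +1/−2 at uniform
composition (λ = 1.33, K = 0.621). Synteny support requires ≥ 1
homologous flanking (or containing) gene pair with matching relative
strand; query flanks are compared against both target flanks because
assembly orientation is arbitrary (a both-flank mode is a flag away).
Gene homology across the toy taxa is an explicit identity table derived
from the generator, standing in for a user-supplied orthology map. Dollo
reconstruction places each gain above the LCA of the carriers and counts
losses on maximal carrier-free subtrees; branches are identified by the
sorted leaf set below them, which is stable between the generator's
truth and independent parses of the tree.

## Targets

The three scorers share one site vocabulary (perfect 8mer / 7mer-m8 /
7mer-A1 matches only; a position reports its strongest type). The
context score −(0.06·type + 0.04·AU + positional) is a defined stand-in
with config-exposed weights such that every planted canonical site clears
−0.1. The duplex aligner is local DP with +5/+1(G:U)/−3, gaps −8/−2 and
seed positions 2–8 doubly weighted: a perfect 23-nt complement scores
150. Accessibility is −(WC + 0.5·GU pairs of the footprint duplex) plus
the opening cost — the drop in maximum pair count of the footprint ±15 nt
window when the whole miRNA footprint is forced unpaired. Sites are keyed
by (transcript, site end, type) for the three-way AND.

## Enrichment and specificity

Upper-tail hypergeometric per term with ≥ 1 target gene (k = 0 terms are
untested and excluded from BH's m), fold enrichment (k/n)/(K/N),
enrichment on genes via the transcript→gene map. "Expressed" for the
breadth classification means ≥ 10 raw reads per sample type (mirroring
the annotation read filter; config-exposed); breadth 1–4 maps to
tissue-specific/+1/+2/all, mixed orthogroups count as annotated. The
z-test is the pooled two-proportion statistic with a two-sided normal p.

## Problem sizes and numerical choices

Validation runs use 50 hairpins / 24 libraries at 5 000 reads per library
(every locus comfortably exceeds the 10-read filter), 2 000 strands for
calibration, 200 sequences ≤ 25 nt for the folding oracle, all 255
presence patterns for the Dollo oracle, and a ~110-orthogroup history for
the end-to-end evolution check — sizes chosen so each study answers its
question in seconds while leaving no sampling ambiguity in the exact
checks. Ties in folding tracebacks, stack pairing and greedy clustering
are broken deterministically (smallest index / longest-then-lexicographic
order), so every result is reproducible bit-for-bit under a fixed seed.

## Known limitations

Base-pair maximization is not thermodynamics: structures are plausible
but not MFE, and the classification thresholds are calibrated to the
synthetic regime, not to real pre-miRNA surveys. The NB Wald test at
n = 3 is mildly anticonservative; the conservative consensus rule and the
read filter (not the raw test) carry the error control, as in the
original design. The homolog search is ungapped, so indel-rich orthologs
would be missed. The target scorers share thresholds and site vocabulary
with their published counterparts but not their trained numerics;
absolute scores are only meaningful relative to the planted constructs.
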
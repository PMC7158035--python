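"""Planted-truth simulator for the whole pipeline.

Generates, under one seed:

* a toy single-chromosome genome carrying two-armed stem-loop (pre-miRNA)
  loci interleaved with protein-coding genes;
* eight related genomes derived along a dated tree, with hairpin families
  gained and lost per branch (optionally constrained so the true events are
  exactly recoverable by Dollo parsimony), point substitutions, and
  occasional relocations that break synteny;
* 24 small-RNA libraries (4 sample types x 2 ages x 3 replicates) of
  adapter-carrying reads with negative-binomial counts, arm-biased
  expression, planted tissue/age log2 fold-changes, and a per-sample-type
  fraction of reads drawn from hairpins absent from the focal genome
  (plasma-like behaviour);
* 3'UTRs with planted accessible target sites and stem-buried decoys, plus
  a term-annotation table with one term enriched among the true targets.

Everything is a pure function of the config, so a fixed seed yields
byte-identical outputs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import random_seq, revcomp
from ._tree import branch_key, branch_table, parse_tree
from .containers import CountMatrix, Gene, HairpinLocus, default_design, sample_id

CHROM = "chr1"

# 8 mammals with split times in My, mirroring a boreoeutherian phylogeny
DEFAULT_TREE = (
    "(((seal:45,dog:45):33,((cow:62,pig:62):14,horse:76):2):16,"
    "((mouse:82,rabbit:82):8,human:90):4);"
)

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"  # Illumina TruSeq small-RNA 3'


@dataclass
class SimConfig:
    seed: int = 0
    genome_length: int = 200_000
    n_hairpins: int = 50
    n_genes: int = 60
    tree: str = DEFAULT_TREE
    gain_rate: float = 0.10  # families / My / branch (~100 orthogroups on
    loss_rate: float = 0.05  # the default tree with 50 root families)
    subst_rate: float = 0.0005  # per site per My on retained hairpins
    # (miRNA hairpins are strongly conserved; leaf-to-leaf divergence on the
    # default tree stays comfortably inside the 80% clustering band)
    divergence_prob: float = 0.0  # chance per branch a hairpin drifts <80%
    relocate_prob: float = 0.02  # chance per branch a hairpin breaks synteny
    dollo_consistent: bool = True
    library_design: list[tuple[str, str, int]] = field(default_factory=default_design)
    mean_depth: int = 20_000  # reads per library
    nb_dispersion: float = 0.1
    arm_ratio: float = 4.0  # 5p:3p expression
    effect_table: dict[tuple[str, str, str], float] = field(default_factory=dict)
    adapter: str = DEFAULT_ADAPTER
    offgenome_fraction: dict[str, float] = field(
        default_factory=lambda: {"brain": 0.30, "heart": 0.30, "muscle": 0.30,
                                 "plasma": 0.45}
    )
    n_offgenome_hairpins: int = 10
    mirbase_fraction: float = 0.6  # planted families present in the mature DB
    jitter_prob: float = 0.0  # chance of a 1-nt 3' trim per read
    read_error_rate: float = 0.0
    short_read_fraction: float = 0.02  # junk inserts <16 nt
    n_utrs: int = 40
    n_target_mirnas: int = 4

    def validate(self) -> None:
        for st, f in self.offgenome_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"offgenome_fraction[{st}]={f} outside [0,1]")
        for frac in (self.mirbase_fraction, self.jitter_prob,
                     self.read_error_rate, self.short_read_fraction,
                     self.relocate_prob, self.divergence_prob):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0,1]")
        if self.arm_ratio <= 0 or self.nb_dispersion <= 0:
            raise ValueError("arm_ratio and nb_dispersion must be positive")


# ---------------------------------------------------------------------------
# hairpin construction


def _make_hairpin(rng: np.random.Generator, family: str) -> dict:
    """A stem-loop in sense orientation: mature5p + loop + ~revcomp(mature5p).

    Arms are 20-23 nt, the loop 8-20 nt, and at most 2 planted mismatches
    distinguish the 3p arm from the perfect reverse complement of the 5p
    arm.  Draws are rejected until the construct actually folds miR-like
    (perfect-by-construction stem-loops), so planted loci are guaranteed to
    satisfy the downstream structural screen.
    """
    from .annotation import classify_hairpin
    from .fold import fold_sequence

    for _attempt in range(50):
        arm_len = int(rng.integers(20, 24))
        loop_len = int(rng.integers(8, 21))
        # 1-2 mismatches: a perfectly palindromic stem would let mature
        # reads align to both strands, which no real pre-miRNA does
        n_mm = int(rng.integers(1, 3))
        mature5p = random_seq(rng, arm_len, gc=0.5)
        arm3 = list(revcomp(mature5p))
        for pos in rng.choice(arm_len, size=n_mm, replace=False):
            old = arm3[pos]
            arm3[pos] = str(rng.choice([b for b in "ACGT" if b != old]))
        mature3p = "".join(arm3)
        loop = random_seq(rng, loop_len, gc=0.2)
        seq = mature5p + loop + mature3p
        if classify_hairpin(fold_sequence(seq)):
            return {"family": family, "seq": seq,
                    "len5p": arm_len, "len3p": arm_len}
    raise RuntimeError(f"could not construct a miR-like hairpin for {family}")


def _locus_from_element(family: str, strand: str, hp: dict, start: int) -> HairpinLocus:
    seq = hp["seq"]
    end = start + len(seq)
    l5, l3 = hp["len5p"], hp["len3p"]
    if strand == "+":
        arm5p = (start, start + l5)
        arm3p = (end - l3, end)
    else:
        arm5p = (end - l5, end)
        arm3p = (start, start + l3)
    return HairpinLocus(
        id=family, chrom=CHROM, start=start, end=end, strand=strand,
        hairpin_seq=seq, arm5p=arm5p, arm3p=arm3p,
        mature5p=seq[:l5], mature3p=seq[-l3:],
    )


# ---------------------------------------------------------------------------
# toy genome


@dataclass
class GroundTruth:
    loci: list[HairpinLocus]
    genes: list[Gene]
    elements: list  # layout: ("spacer",seq) | ("gene",gid,strand,seq) | ("hairpin",fam,strand,hp)
    mature_db: dict[str, str]  # miRBase-like mature reference
    hairpin_db: dict[str, str]  # miRBase-like hairpin reference
    annotated_families: set[str]
    offgenome: list[dict]  # hairpin dicts for families absent from the genome


@dataclass
class ToyGenome:
    genome: dict[str, str]
    genes: list[Gene]
    truth: GroundTruth
    config: SimConfig


def _render(elements: list) -> tuple[str, list[Gene], list[HairpinLocus]]:
    pos = 0
    parts: list[str] = []
    genes: list[Gene] = []
    loci: list[HairpinLocus] = []
    for el in elements:
        kind = el[0]
        if kind == "spacer":
            seq = el[1]
        elif kind == "gene":
            _, gid, strand, seq = el
            genes.append(Gene(gid, CHROM, pos, pos + len(seq), strand))
        else:
            _, fam, strand, hp = el
            seq = hp["seq"] if strand == "+" else revcomp(hp["seq"])
            loci.append(_locus_from_element(fam, strand, hp, pos))
        parts.append(seq)
        pos += len(seq)
    return "".join(parts), genes, loci


def build_toy_genome(config: SimConfig) -> ToyGenome:
    """Plant `n_hairpins` stem-loops between protein-coding genes."""
    config.validate()
    rng = np.random.default_rng([config.seed, 11])

    hairpins = [_make_hairpin(rng, f"mir{i:03d}") for i in range(config.n_hairpins)]
    gene_seqs = [
        (f"gene{i:03d}", "+" if rng.random() < 0.5 else "-",
         random_seq(rng, int(rng.integers(300, 801))))
        for i in range(config.n_genes)
    ]
    strands = ["+" if rng.random() < 0.5 else "-" for _ in hairpins]

    # interleave: gene, hairpin, gene, hairpin, ..., then leftover genes
    features: list = []
    gi = hi = 0
    while gi < len(gene_seqs) or hi < len(hairpins):
        if gi < len(gene_seqs):
            gid, gstrand, gseq = gene_seqs[gi]
            features.append(("gene", gid, gstrand, gseq))
            gi += 1
        if hi < len(hairpins):
            features.append(("hairpin", hairpins[hi]["family"], strands[hi],
                             hairpins[hi]))
            hi += 1

    min_spacer = 50
    lengths = [len(f[3]["seq"]) if f[0] == "hairpin" else len(f[3]) for f in features]
    needed = sum(lengths) + min_spacer * (len(features) + 1)
    if needed > config.genome_length:
        # name the first feature that no longer fits
        acc = min_spacer
        for f, ln in zip(features, lengths):
            acc += ln + min_spacer
            if acc > config.genome_length:
                raise ValueError(
                    f"genome_length={config.genome_length} too small: feature "
                    f"{f[1]} does not fit (needs >= {needed} bp in total)"
                )
    slack = config.genome_length - needed
    extra = rng.multinomial(slack, np.ones(len(features) + 1) / (len(features) + 1))
    elements: list = []
    for k, f in enumerate(features):
        elements.append(("spacer", random_seq(rng, min_spacer + int(extra[k]))))
        elements.append(f)
    elements.append(("spacer", random_seq(rng, min_spacer + int(extra[-1]))))

    genome_seq, genes, loci = _render(elements)

    offgenome = [_make_hairpin(rng, f"off{i:02d}")
                 for i in range(config.n_offgenome_hairpins)]

    n_annot = int(round(config.mirbase_fraction * len(hairpins)))
    annotated = {hp["family"] for hp in hairpins[:n_annot]}
    mature_db: dict[str, str] = {}
    hairpin_db: dict[str, str] = {}
    for hp in hairpins:
        if hp["family"] in annotated:
            mature_db[f"{hp['family']}-5p"] = hp["seq"][: hp["len5p"]]
            mature_db[f"{hp['family']}-3p"] = hp["seq"][-hp["len3p"]:]
            hairpin_db[hp["family"]] = hp["seq"]
    for hp in offgenome:
        mature_db[f"{hp['family']}-5p"] = hp["seq"][: hp["len5p"]]
        mature_db[f"{hp['family']}-3p"] = hp["seq"][-hp["len3p"]:]
        hairpin_db[hp["family"]] = hp["seq"]

    truth = GroundTruth(
        loci=loci, genes=genes, elements=elements, mature_db=mature_db,
        hairpin_db=hairpin_db, annotated_families=annotated, offgenome=offgenome,
    )
    return ToyGenome(genome={CHROM: genome_seq}, genes=genes, truth=truth,
                     config=config)


# ---------------------------------------------------------------------------
# species genomes along the tree


@dataclass
class SpeciesSet:
    genomes: dict[str, dict[str, str]]  # taxon -> chrom -> seq
    genes: dict[str, list[Gene]]
    loci: dict[str, list[HairpinLocus]]
    presence: pd.DataFrame  # taxa x families, 0/1
    events: pd.DataFrame  # branch, gains, losses, length_my, gained/lost ids
    relocated: dict[str, set[str]]  # taxon -> families moved (synteny broken)
    tree: str


def _mutate(rng: np.random.Generator, seq: str, rate: float,
            founder: str | None = None, max_div: float = 0.10) -> str:
    """Point substitutions at `rate` per site.  When a founder sequence is
    given, substitutions that would push the copy beyond `max_div` hamming
    divergence from the founder are withheld, so any two family members
    stay within the 80% clustering band."""
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    if founder is not None and len(founder) == len(arr):
        budget = int(max_div * len(arr))
        for i in hits:
            diverged = sum(1 for a, f in zip(arr, founder) if a != f)
            if diverged >= budget:
                break
            arr[i] = str(rng.choice([b for b in "ACGT" if b != arr[i]]))
    else:
        for i in hits:
            arr[i] = str(rng.choice([b for b in "ACGT" if b != arr[i]]))
    return "".join(arr)


def derive_species_genomes(toy: ToyGenome, config: SimConfig | None = None) -> SpeciesSet:
    """Evolve the root layout along the tree with per-branch gains/losses.

    With ``dollo_consistent`` set, a loss is only applied when the family's
    post-loss presence pattern still reconstructs, under single-gain (Dollo)
    parsimony, to exactly the events simulated so far; this keeps the true
    per-branch event lists recoverable from the leaf presence matrix alone.
    """
    config = config or toy.config
    rng = np.random.default_rng([config.seed, 23])
    tree = parse_tree(config.tree)
    leaves_total = [lf.taxon.label for lf in tree.leaf_node_iter()]

    # family bookkeeping for the Dollo-consistency rule
    gain_node: dict[str, object] = {}
    live_leaves: dict[str, set[str]] = {}
    node_leafsets = {id(nd): set(lf.taxon.label for lf in nd.leaf_iter())
                     for nd in tree.preorder_node_iter()}

    def loss_allowed(fam: str, node) -> bool:
        if not config.dollo_consistent:
            return True
        sub = node_leafsets[id(node)]
        after = live_leaves[fam] - sub
        if not after:
            return False
        parent = node.parent_node
        if parent is not None and not (node_leafsets[id(parent)] & after):
            return False  # would merge with a sibling loss one level up
        g = gain_node[fam]
        g_children = g.child_nodes()
        if len(g_children) >= 2:
            live_kids = sum(1 for c in g_children if node_leafsets[id(c)] & after)
            if live_kids < 2:
                return False  # gain branch would no longer be the LCA
        return True

    root = tree.seed_node
    root_state = copy.deepcopy(toy.truth.elements)
    root_fams = [el[1] for el in root_state if el[0] == "hairpin"]
    founders = {el[1]: el[3]["seq"] for el in root_state if el[0] == "hairpin"}
    for fam in root_fams:
        gain_node[fam] = root
        live_leaves[fam] = set(leaves_total)

    states: dict[int, list] = {id(root): root_state}
    gain_counter = 0
    rows = []
    relocated: dict[str, set[str]] = {lf: set() for lf in leaves_total}
    reloc_by_node: dict[int, set[str]] = {id(root): set()}

    for node in tree.preorder_node_iter():
        if node is root:
            rows.append({"branch": branch_key(root), "length_my": 0.0,
                         "gains": len(root_fams), "losses": 0,
                         "gained_ids": ",".join(root_fams), "lost_ids": ""})
            continue
        L = float(node.edge.length or 0.0)
        state = copy.deepcopy(states[id(node.parent_node)])
        node_reloc = set(reloc_by_node[id(node.parent_node)])
        present = [k for k, el in enumerate(state) if el[0] == "hairpin"]
        gained_ids, lost_ids = [], []

        n_loss = rng.poisson(config.loss_rate * L) if L > 0 else 0
        for _ in range(min(n_loss, len(present))):
            hp_idx = [k for k, el in enumerate(state) if el[0] == "hairpin"]
            if not hp_idx:
                break
            k = int(rng.choice(hp_idx))
            fam = state[k][1]
            if not loss_allowed(fam, node):
                continue
            live_leaves[fam] -= node_leafsets[id(node)]
            state.pop(k)
            lost_ids.append(fam)

        n_gain = rng.poisson(config.gain_rate * L) if L > 0 else 0
        for _ in range(n_gain):
            fam = f"gx{gain_counter:03d}"
            gain_counter += 1
            hp = _make_hairpin(rng, fam)
            strand = "+" if rng.random() < 0.5 else "-"
            state.insert(int(rng.integers(0, len(state) + 1)),
                         ("hairpin", fam, strand, hp))
            founders[fam] = hp["seq"]
            gain_node[fam] = node
            live_leaves[fam] = set(node_leafsets[id(node)])
            gained_ids.append(fam)

        # substitutions on retained hairpins (genes held fixed: orthology is by id)
        if config.subst_rate > 0 and L > 0:
            for k, el in enumerate(state):
                if el[0] != "hairpin" or el[1] in gained_ids:
                    continue
                hp = dict(el[3])
                if config.divergence_prob > 0 and rng.random() < config.divergence_prob:
                    # divergence event: drift below the 80% band
                    hp["seq"] = _mutate(rng, hp["seq"], 0.30)
                else:
                    hp["seq"] = _mutate(rng, hp["seq"], config.subst_rate * L,
                                        founder=founders.get(el[1]))
                state[k] = ("hairpin", el[1], el[2], hp)

        # relocations: move a retained hairpin next to a different gene pair
        if config.relocate_prob > 0 and L > 0:
            hp_idx = [k for k, el in enumerate(state) if el[0] == "hairpin"]
            for k in hp_idx:
                if state[k][1] in gained_ids:
                    continue
                if rng.random() < config.relocate_prob:
                    el = state.pop(k)
                    state.insert(int(rng.integers(0, len(state) + 1)), el)
                    node_reloc.add(el[1])

        states[id(node)] = state
        reloc_by_node[id(node)] = node_reloc
        rows.append({"branch": branch_key(node), "length_my": L,
                     "gains": len(gained_ids), "losses": len(lost_ids),
                     "gained_ids": ",".join(gained_ids),
                     "lost_ids": ",".join(lost_ids)})

    genomes, genes_by_taxon, loci_by_taxon = {}, {}, {}
    presence_rows = {}
    all_fams = sorted(gain_node)
    for leaf in tree.leaf_node_iter():
        taxon = leaf.taxon.label
        seq, genes, loci = _render(states[id(leaf)])
        genomes[taxon] = {CHROM: seq}
        genes_by_taxon[taxon] = genes
        loci_by_taxon[taxon] = loci
        fams = {lc.id for lc in loci}
        presence_rows[taxon] = [1 if f in fams else 0 for f in all_fams]
        relocated[taxon] = reloc_by_node[id(leaf)] & fams

    presence = pd.DataFrame.from_dict(presence_rows, orient="index",
                                      columns=all_fams).sort_index()
    events = pd.DataFrame(rows)
    return SpeciesSet(genomes=genomes, genes=genes_by_taxon, loci=loci_by_taxon,
                      presence=presence, events=events, relocated=relocated,
                      tree=config.tree)


# ---------------------------------------------------------------------------
# small-RNA libraries


@dataclass
class LibrarySim:
    reads: dict[str, list[tuple[str, str]]]  # sample id -> [(read id, seq)]
    true_counts: CountMatrix  # focal strands only
    offgenome_counts: pd.DataFrame
    stats: pd.DataFrame  # per library: n_reads, n_short, n_offgenome
    config: SimConfig


def _strand_ids(loci: list[HairpinLocus]) -> list[str]:
    out = []
    for lc in loci:
        out += [f"{lc.id}-5p", f"{lc.id}-3p"]
    return out


def _effect_multiplier(effects, strand, sample_type, age) -> float:
    lfc = 0.0
    for (sid, factor, level), value in effects.items():
        if sid != strand:
            continue
        if factor == "sample_type" and level == sample_type:
            lfc += value
        elif factor == "age" and level == age:
            lfc += value
        elif factor.startswith("age@"):
            if factor.split("@", 1)[1] == sample_type and level == age:
                lfc += value
    return 2.0 ** lfc


def simulate_libraries(toy: ToyGenome, config: SimConfig | None = None) -> LibrarySim:
    """Draw NB read counts per mature strand per library and emit reads.

    Reads are the mature sequence (optionally 3'-jittered) with the 3'
    adapter appended; quality lines are constant.  A per-sample-type
    fraction of reads comes from hairpin families absent from the focal
    genome, emulating an incomplete assembly.
    """
    config = config or toy.config
    if not config.library_design:
        raise ValueError("library design is empty")
    rng = np.random.default_rng([config.seed, 37])
    loci = toy.truth.loci
    strands = _strand_ids(loci)
    mature = {}
    for lc in loci:
        mature[f"{lc.id}-5p"] = lc.mature5p
        mature[f"{lc.id}-3p"] = lc.mature3p
    known = set(strands)
    for (sid, _f, _l) in config.effect_table:
        if sid not in known:
            raise ValueError(f"effect_table references unknown miRNA strand {sid}")

    off_strands, off_mature = [], {}
    for hp in toy.truth.offgenome:
        for arm, seq in (("5p", hp["seq"][: hp["len5p"]]),
                         ("3p", hp["seq"][-hp["len3p"]:])):
            sid = f"{hp['family']}-{arm}"
            off_strands.append(sid)
            off_mature[sid] = seq

    r = config.arm_ratio
    fam_w = rng.lognormal(0.0, 1.0, size=len(loci))
    base = {}
    for w, lc in zip(fam_w, loci):
        base[f"{lc.id}-5p"] = w * r / (1 + r)
        base[f"{lc.id}-3p"] = w * 1 / (1 + r)
    z = sum(base.values())
    base = {k: v / z for k, v in base.items()}
    if off_strands:
        off_w = rng.lognormal(0.0, 1.0, size=len(off_strands))
        off_w /= off_w.sum()
        off_base = dict(zip(off_strands, off_w))
    else:
        off_base = {}

    reads: dict[str, list[tuple[str, str]]] = {}
    counts = pd.DataFrame(0, index=strands,
                          columns=[sample_id(*d) for d in config.library_design])
    off_counts = pd.DataFrame(0, index=off_strands, columns=counts.columns)
    stats_rows = []
    alpha = config.nb_dispersion

    def nb_draw(mu: float) -> int:
        if mu <= 0:
            return 0
        n = 1.0 / alpha
        return int(rng.negative_binomial(n, n / (n + mu)))

    def make_reads(lib, sid, seq, c, out):
        for i in range(c):
            s = seq
            if config.jitter_prob > 0 and rng.random() < config.jitter_prob:
                s = s[:-1]
            if config.read_error_rate > 0:
                s = _mutate(rng, s, config.read_error_rate)
            out.append((f"{lib}:{sid}:{i}", s + config.adapter))

    for design in config.library_design:
        lib = sample_id(*design)
        st, age, _rep = design
        f_off = config.offgenome_fraction.get(st, 0.0)
        lib_reads: list[tuple[str, str]] = []
        for sid in strands:
            mult = _effect_multiplier(config.effect_table, sid, st, age)
            mu = (1 - f_off) * config.mean_depth * base[sid] * mult
            c = nb_draw(mu)
            counts.loc[sid, lib] = c
            make_reads(lib, sid, mature[sid], c, lib_reads)
        for sid in off_strands:
            mu = f_off * config.mean_depth * off_base[sid]
            c = nb_draw(mu)
            off_counts.loc[sid, lib] = c
            make_reads(lib, sid, off_mature[sid], c, lib_reads)
        n_short = int(rng.poisson(config.short_read_fraction * config.mean_depth))
        for i in range(n_short):
            junk = random_seq(rng, int(rng.integers(10, 16)))
            lib_reads.append((f"{lib}:short:{i}", junk + config.adapter))
        reads[lib] = lib_reads
        stats_rows.append({"sample": lib, "n_reads": len(lib_reads),
                           "n_short": n_short,
                           "n_offgenome": int(off_counts[lib].sum())})

    samples = pd.DataFrame(
        [{"sample": sample_id(*d), "sample_type": d[0], "age": d[1],
          "replicate": d[2]} for d in config.library_design]
    ).set_index("sample")
    cm = CountMatrix(counts, samples)
    stats = pd.DataFrame(stats_rows).set_index("sample")
    return LibrarySim(reads=reads, true_counts=cm, offgenome_counts=off_counts,
                      stats=stats, config=config)


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# direct count-table simulation (for DE calibration studies)


def simulate_count_table(
    n_strands: int,
    design: list[tuple[str, str, int]],
    effects: dict[tuple[str, str, str], float] | None = None,
    mean_depth: float = 1e4,
    dispersion: float = 0.1,
    seed: int = 0,
    baseline_sigma: float = 1.0,
) -> CountMatrix:
    """NB counts straight into a matrix (no reads), for calibration studies.

    Strand names are s0000..; effects use the same keys as SimConfig's
    effect_table.
    """
    rng = np.random.default_rng([seed, 53])
    effects = effects or {}
    strands = [f"s{i:04d}" for i in range(n_strands)]
    w = rng.lognormal(0.0, baseline_sigma, size=n_strands)
    w /= w.sum()
    cols = [sample_id(*d) for d in design]
    mat = np.zeros((n_strands, len(cols)), dtype=int)
    n = 1.0 / dispersion
    for j, d in enumerate(design):
        st, age, _rep = d
        mult = np.array([_effect_multiplier(effects, s, st, age) for s in strands])
        mu = mean_depth * w * mult
        mat[:, j] = rng.negative_binomial(n, n / (n + np.maximum(mu, 1e-12)))
    counts = pd.DataFrame(mat, index=strands, columns=cols)
    samples = pd.DataFrame(
        [{"sample": sample_id(*d), "sample_type": d[0], "age": d[1],
          "replicate": d[2]} for d in design]
    ).set_index("sample")
    return CountMatrix(counts, samples)


# ---------------------------------------------------------------------------
# UTRs, target sites, and term table


@dataclass
class UTRSim:
    utrs: dict[str, str]  # transcript -> sequence
    tx2gene: dict[str, str]
    true_sites: pd.DataFrame  # mirna, transcript, start, end, accessible
    term_table: pd.DataFrame  # term, gene
    enriched_term: str
    target_mirnas: list[str]
    mirna_seqs: dict[str, str]
    config: SimConfig


def _site_for(mirna_seq: str) -> str:
    """Strongest canonical site: full complement of positions 2..end, plus
    the A opposite position 1 (8mer-compatible)."""
    return revcomp(mirna_seq[1:]) + "A"


def _decoy_hairpin(site: str) -> tuple[str, int]:
    """The site sandwiched between two tight stems (partners inside the
    +-15 nt accessibility window); returns (construct, site offset)."""
    half = len(site) // 2
    construct = (revcomp(site[:half]) + "AAA" + site + "AAA"
                 + revcomp(site[half:]))
    return construct, half + 3


def _verified_regulator(mirna_seq: str) -> bool:
    """True iff the planted site scores accessible in an open (poly-A)
    context and inaccessible inside the decoy stems, under the pipeline's
    own accessibility scorer.  Matures failing this (e.g. strongly
    self-structured sites) are not used as planted regulators."""
    from .targets import accessibility_score

    site = _site_for(mirna_seq)
    open_ctx = "A" * 20 + site + "A" * 20
    acc = accessibility_score(mirna_seq, open_ctx, 20, 20 + len(site))
    hair, off = _decoy_hairpin(site)
    decoy_ctx = "A" * 20 + hair + "A" * 20
    s0 = 20 + off
    dec = accessibility_score(mirna_seq, decoy_ctx, s0, s0 + len(site))
    return acc <= -11.0 and dec >= -9.0


def simulate_utrs_and_terms(toy: ToyGenome, config: SimConfig | None = None) -> UTRSim:
    """UTRs over a pairing-free A/C background with planted accessible sites
    and stem-buried decoys; a term table with one term enriched among the
    true target genes."""
    config = config or toy.config
    rng = np.random.default_rng([config.seed, 71])
    loci = toy.truth.loci
    # canonical regulators: >=22 nt matures starting with U, so planted
    # full-complement sites clear the fixed duplex threshold by construction
    eligible = [(f"{lc.id}-{arm}", seq)
                for lc in loci
                for arm, seq in (("5p", lc.mature5p), ("3p", lc.mature3p))
                if len(seq) >= 22 and seq.startswith("T")
                and _verified_regulator(seq)]
    if not eligible:
        raise ValueError("no planted mature qualifies as a regulator "
                         "(>=22 nt, 5' U, verifiably accessible site); "
                         "increase n_hairpins")
    picks = rng.choice(len(eligible),
                       size=min(config.n_target_mirnas, len(eligible)),
                       replace=False)
    mirnas = {eligible[i][0]: eligible[i][1] for i in sorted(picks)}

    def background(n: int) -> str:
        return "".join(rng.choice(list("AC"), size=n, p=[0.7, 0.3]))

    utrs, tx2gene = {}, {}
    site_rows = []
    mirna_ids = sorted(mirnas)
    n_true = max(4, config.n_utrs // 4)
    n_decoy = max(2, config.n_utrs // 8)
    for t in range(config.n_utrs):
        tx = f"tx{t:03d}"
        gene = f"g{t:03d}"
        tx2gene[tx] = gene
        seq = background(int(rng.integers(180, 260)))
        if t < n_true:
            mid = mirna_ids[t % len(mirna_ids)]
            site = _site_for(mirnas[mid])
            # 20 nt poly-A on each side reproduces the open context the
            # regulator was verified in
            block = "A" * 20 + site + "A" * 20
            pos = int(rng.integers(20, len(seq) - len(block) - 20))
            seq = seq[:pos] + block + seq[pos + len(block):]
            s0 = pos + 20
            site_rows.append({"mirna": mid, "transcript": tx, "start": s0,
                              "end": s0 + len(site), "accessible": True})
        elif t < n_true + n_decoy:
            mid = mirna_ids[t % len(mirna_ids)]
            site = _site_for(mirnas[mid])
            hair, off = _decoy_hairpin(site)
            block = "A" * 20 + hair + "A" * 20
            pos = int(rng.integers(20, len(seq) - len(block) - 20))
            seq = seq[:pos] + block + seq[pos + len(block):]
            s0 = pos + 20 + off
            site_rows.append({"mirna": mid, "transcript": tx, "start": s0,
                              "end": s0 + len(site), "accessible": False})
        utrs[tx] = seq

    true_sites = pd.DataFrame(site_rows)
    true_genes = sorted({tx2gene[r["transcript"]] for r in site_rows
                         if r["accessible"]})
    all_genes = sorted(tx2gene.values())
    terms = []
    enriched = "TERM_ENR"
    for g in true_genes:
        terms.append({"term": enriched, "gene": g})
    extra = [g for g in all_genes if g not in true_genes]
    for g in extra[:2]:
        terms.append({"term": enriched, "gene": g})
    for k in range(6):
        size = int(rng.integers(5, 12))
        for g in rng.choice(all_genes, size=size, replace=False):
            terms.append({"term": f"TERM_{k}", "gene": str(g)})
    term_table = pd.DataFrame(terms).drop_duplicates()
    return UTRSim(utrs=utrs, tx2gene=tx2gene, true_sites=true_sites,
                  term_table=term_table, enriched_term=enriched,
                  target_mirnas=mirna_ids, mirna_seqs=mirnas, config=config)
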
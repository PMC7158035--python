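"""End-to-end study drivers over the library modules.

Each function runs one self-contained experiment on freshly simulated data
and returns plain dictionaries of summary numbers.  The analysis scripts,
the validation suite and the reproduction script all call these, so every
reported figure comes from the same code path.
"""

from __future__ import annotations

import copy
import itertools

import numpy as np
import pandas as pd

from . import annotation, diffexpr, enrichment, evolution, preprocess, targets
from ._seq import random_seq
from ._tree import parse_tree
from .containers import default_design
from .fold import fold_sequence
from .oracles import dollo_min_losses, enumerate_max_pairs
from .synthetic_data import (SimConfig, build_toy_genome,
                             derive_species_genomes, simulate_count_table,
                             simulate_libraries, simulate_utrs_and_terms)


def _pool(hits_by_sample):
    pooled = {}
    for hits in hits_by_sample.values():
        for h in hits:
            key = (h.seq, h.chrom, h.start, h.end, h.strand)
            if key in pooled:
                pooled[key].count += h.count
            else:
                pooled[key] = copy.copy(h)
    return list(pooled.values())


# ---------------------------------------------------------------------------
# annotation recovery


def annotation_study(seed: int, n_hairpins: int = 50,
                     mean_depth: int = 5000) -> dict:
    """Simulate 24 libraries over a 50-hairpin genome, run trim -> align ->
    candidates -> curation, and score recovery against the planted truth."""
    cfg = SimConfig(seed=seed, n_hairpins=n_hairpins, n_genes=n_hairpins + 2,
                    genome_length=4000 * n_hairpins, mean_depth=mean_depth)
    toy = build_toy_genome(cfg)
    sim = simulate_libraries(toy)
    hits_by_sample = {}
    mapped = {}
    for lib, reads in sim.reads.items():
        collapsed, _stats = preprocess.trim_adapter(reads, cfg.adapter)
        hits, unmapped = preprocess.align_exact(collapsed, toy.genome)
        hits_by_sample[lib] = hits
        n_mapped = sum(h.count for h in
                       {(x.seq): x for x in hits}.values())
        mapped[lib] = (n_mapped, sum(collapsed.values()))
    pooled = _pool(hits_by_sample)
    cands = annotation.candidate_loci(pooled, toy.genome)
    kept = annotation.curate(cands, pooled, mature_db=toy.truth.mature_db)
    planted = {(l.chrom, l.strand, l.start, l.end) for l in toy.truth.loci}
    found = {(l.chrom, l.strand, l.start, l.end) for l in kept}
    tp = len(planted & found)
    stypes = sim.true_counts.samples["sample_type"]
    frac = {}
    for st in ("plasma", "brain"):
        libs = [l for l in mapped if stypes[l] == st]
        frac[st] = (sum(mapped[l][0] for l in libs)
                    / max(sum(mapped[l][1] for l in libs), 1))
    n_mirbase = sum(1 for l in kept if l.annotation_class == "miRBase")
    switches = annotation.arm_switch_screen(sim.true_counts)
    return {
        "recall": tp / len(planted),
        "precision": tp / len(kept) if kept else 0.0,
        "n_curated": len(kept),
        "n_mirbase": n_mirbase,
        "n_novel": len(kept) - n_mirbase,
        "plasma_mapped_fraction": frac["plasma"],
        "tissue_mapped_fraction": frac["brain"],
        "n_arm_switches": int(switches["switching"].sum()),
        "toy": toy, "sim": sim, "curated": kept,
    }


# ---------------------------------------------------------------------------
# folding and Dollo oracles


def fold_oracle_study(seed: int, n_seqs: int = 200, max_len: int = 25) -> dict:
    rng = np.random.default_rng([seed, 2])
    agree = 0
    for _ in range(n_seqs):
        seq = random_seq(rng, int(rng.integers(5, max_len + 1)))
        agree += fold_sequence(seq).n_pairs == enumerate_max_pairs(seq)
    return {"agreement": agree / n_seqs, "n": n_seqs}


def dollo_oracle_study(tree_newick: str | None = None) -> dict:
    tree_newick = tree_newick or SimConfig().tree
    tree = parse_tree(tree_newick)
    taxa = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    cols = {f"p{bits}": [1 if bits >> i & 1 else 0 for i in range(len(taxa))]
            for bits in range(1, 2 ** len(taxa))}
    mat = pd.DataFrame(cols, index=taxa)
    table, placements = evolution.dollo_reconstruct(mat, tree_newick)
    per_og = placements.set_index("orthogroup")
    agree = 0
    for bits in range(1, 2 ** len(taxa)):
        present = {taxa[i] for i in range(len(taxa)) if bits >> i & 1}
        losses = [x for x in per_og.loc[f"p{bits}", "loss_branches"].split(",")
                  if x]
        agree += len(losses) == dollo_min_losses(tree, present)
    n = 2 ** len(taxa) - 1
    return {"agreement": agree / n, "n": n,
            "gains_sum_ok": int(table["gains"].sum()) == n}


# ---------------------------------------------------------------------------
# evolution end-to-end


def evolution_study(seed: int, hide_fraction: float = 0.10) -> dict:
    """Dollo-consistent 8-taxon history with synteny intact: cluster all
    annotated hairpins, hide a fraction of annotations from multi-taxon
    families, rescue them by homolog search + synteny support, and compare
    the reconstructed per-branch events with the generator's truth."""
    cfg = SimConfig(seed=seed, n_hairpins=50, n_genes=52,
                    genome_length=200_000, relocate_prob=0.0,
                    divergence_prob=0.0)
    toy = build_toy_genome(cfg)
    sp = derive_species_genomes(toy)
    rng = np.random.default_rng([seed, 3])

    fam_taxa: dict[str, list[str]] = {}
    for taxon, loci in sp.loci.items():
        for lc in loci:
            fam_taxa.setdefault(lc.id, []).append(taxon)
    hidden: set[tuple[str, str]] = set()
    for taxon in sorted(sp.loci):
        for lc in sp.loci[taxon]:
            if len(fam_taxa[lc.id]) >= 2 and rng.random() < hide_fraction:
                key = (taxon, lc.id)
                # keep at least one visible copy per family
                vis = sum(1 for t in fam_taxa[lc.id]
                          if (t, lc.id) not in hidden)
                if vis >= 2:
                    hidden.add(key)

    visible = [(t, lc.id, lc.hairpin_seq)
               for t in sorted(sp.loci) for lc in sp.loci[t]
               if (t, lc.id) not in hidden]
    annotated = {lc.id for t in sp.loci for lc in sp.loci[t]
                 if lc.id in toy.truth.annotated_families}
    ogs = evolution.cluster_hairpins(visible, annotated=annotated)

    # rescue hidden loci: search a visible family member against the taxon
    orthology = {g.id: g.id for t in sp.genes for g in sp.genes[t]}
    rep_of = {}
    for t in sorted(sp.loci):
        for lc in sp.loci[t]:
            if (t, lc.id) not in hidden:
                rep_of.setdefault(lc.id, (t, lc))
    og_of_fam = {}
    for og in ogs:
        fams = {m[1] for m in og.members}
        for f in fams:
            og_of_fam[f] = og.id
    supported: dict[str, set[str]] = {}
    n_rescued = 0
    for (taxon, fam) in sorted(hidden):
        qt, qlc = rep_of[fam]
        hits = evolution.homolog_search({fam: qlc.hairpin_seq},
                                        sp.genomes[taxon], taxon=taxon)
        for h in hits:
            if evolution.synteny_support(h, qlc, sp.genes[qt],
                                         sp.genes[taxon], orthology):
                supported.setdefault(og_of_fam[fam], set()).add(taxon)
                n_rescued += 1
                break

    taxa = sorted(sp.presence.index)
    matrix = evolution.build_presence_matrix(ogs, taxa, supported)
    # map orthogroup columns back to family names for the truth comparison
    matrix.columns = [next(iter({m[1] for m in og.members})) for og in ogs]
    truth_presence = sp.presence.loc[taxa, sorted(matrix.columns)]
    matrix = matrix[sorted(matrix.columns)]
    presence_exact = matrix.equals(truth_presence)

    table, _placements = evolution.dollo_reconstruct(matrix, cfg.tree)
    truth_events = {}
    for _, row in sp.events.iterrows():
        g = [f for f in row["gained_ids"].split(",") if f]
        l = [f for f in row["lost_ids"].split(",") if f]
        truth_events[row["branch"]] = (len(g), len(l))
    branches = list(table.index)
    n_match = sum(
        (int(table.loc[b, "gains"]), int(table.loc[b, "losses"]))
        == truth_events.get(b, (0, 0))
        for b in branches)
    rates_ok = True
    for b in branches:
        L = table.loc[b, "length_my"]
        if L > 0:
            tg, tl = truth_events.get(b, (0, 0))
            if table.loc[b, "net_gain_rate"] != round((tg - tl) / L, 2):
                rates_ok = False
    return {
        "n_orthogroups": len(ogs),
        "n_hidden": len(hidden),
        "n_rescued": n_rescued,
        "presence_exact": presence_exact,
        "branch_agreement": n_match / len(branches),
        "rates_exact": rates_ok,
        "clusters_pure": all(len({m[1] for m in og.members}) == 1
                             for og in ogs),
        "gainloss_table": table,
    }


# ---------------------------------------------------------------------------
# differential expression studies


TWO_GROUP = [("brain", a, r) for a in ("pup", "adult") for r in (1, 2, 3)]


def de_calibration_study(seed: int, n_strands: int = 2000) -> dict:
    """Null 3-vs-3 NB data: empirical type-I error of the Wald test and the
    BH false-discovery behaviour."""
    cm = simulate_count_table(n_strands, TWO_GROUP, None, 2e4, 0.1,
                              seed=seed)
    res = diffexpr.nb_test(cm, ("age",), ("age", "pup", "adult"))
    p = res["p"].dropna()
    q = res["q"].dropna()
    return {"type1_error": float((p < 0.05).mean()),
            "fdr_calls": float((q <= 0.05).mean()),
            "n": int(len(p))}


def de_recovery_study(seed: int, n_strands: int = 2000,
                      n_effect: int = 100) -> dict:
    """Balanced planted +-2 log2FC strands: median estimate per direction."""
    effects = {}
    for i in range(n_effect):
        effects[(f"s{i:04d}", "age", "adult")] = 2.0
    for i in range(n_effect, 2 * n_effect):
        effects[(f"s{i:04d}", "age", "adult")] = -2.0
    cm = simulate_count_table(n_strands, TWO_GROUP, effects, 2e4, 0.1,
                              seed=seed)
    res = diffexpr.nb_test(cm, ("age",), ("age", "pup", "adult"))
    up = res["log2FC"].iloc[:n_effect].median()
    down = res["log2FC"].iloc[n_effect:2 * n_effect].median()
    return {"median_lfc_up": float(up), "median_lfc_down": float(down),
            "n_effect": n_effect}


def consensus_study(seed: int, n_strands: int = 300,
                    n_single: int = 20, n_double: int = 20) -> dict:
    """Planted brain-only vs brain+heart strands through the all-pairwise
    consensus rule: single-tissue must be called, two-tissue must not."""
    effects = {}
    for i in range(n_single):
        effects[(f"s{i:04d}", "sample_type", "brain")] = 2.0
    for i in range(n_single, n_single + n_double):
        effects[(f"s{i:04d}", "sample_type", "brain")] = 2.0
        effects[(f"s{i:04d}", "sample_type", "heart")] = 2.0
    cm = simulate_count_table(n_strands, default_design(), effects, 2e4, 0.1,
                              seed=seed)
    pw = diffexpr.pairwise_tissue_de(cm)
    calls = diffexpr.tissue_consensus(pw, cm)
    up_brain = set(calls[(calls["sample_type"] == "brain")
                         & (calls["direction"] == "up")]["strand"])
    singles = {f"s{i:04d}" for i in range(n_single)}
    doubles = {f"s{i:04d}" for i in range(n_single, n_single + n_double)}
    correct = (len(up_brain & singles)
               + (n_double - len(up_brain & doubles)))
    null_false = len(up_brain - singles - doubles)
    return {"accuracy": correct / (n_single + n_double),
            "n_false_null_calls": null_false,
            "n_called_single": len(up_brain & singles),
            "n_called_double": len(up_brain & doubles)}


def boundary_count_matrix():
    """Two brain-specific strands whose best replicate triplet totals
    exactly 29 (g29) and 30 (g30) raw reads."""
    design = default_design()
    cols = [f"{d[0]}_{d[1]}_{d[2]}" for d in design]
    counts = pd.DataFrame(0, index=["g29", "g30"], columns=cols)
    samples = pd.DataFrame(
        [{"sample": c, "sample_type": d[0], "age": d[1], "replicate": d[2]}
         for c, d in zip(cols, design)]).set_index("sample")
    brain_pup = [c for c, d in zip(cols, design)
                 if d[0] == "brain" and d[1] == "pup"]
    counts.loc["g29", brain_pup] = [10, 10, 9]
    counts.loc["g30", brain_pup] = [10, 10, 10]
    from .containers import CountMatrix
    return CountMatrix(counts, samples)


def significant_brain_up_pairwise(strands):
    """Synthetic pairwise DE results marking every strand unambiguously
    up-in-brain (used to exercise the read filter in isolation)."""
    tissues = ["brain", "heart", "muscle", "plasma"]
    pw = {}
    for t1, t2 in itertools.combinations(tissues, 2):
        lfc = -3.0 if t1 == "brain" else (3.0 if t2 == "brain" else 0.0)
        q = 1e-9 if "brain" in (t1, t2) else 1.0
        pw[(t1, t2)] = pd.DataFrame(
            {"log2FC": lfc, "p": q, "q": q}, index=list(strands))
    return pw


def consensus_boundary_study(seed: int = 0) -> dict:
    """The >=30-read triplet rule at its boundary: an otherwise clearly
    significant brain-specific strand is dropped at a best-triplet total of
    29 and retained at 30."""
    cm = boundary_count_matrix()
    pw = significant_brain_up_pairwise(cm.counts.index)
    calls = diffexpr.tissue_consensus(pw, cm)
    called = set(calls["strand"])
    return {"boundary_29_filtered": "g29" not in called,
            "boundary_30_retained": "g30" in called,
            "n_filtered": int(calls.attrs["n_filtered"])}


# ---------------------------------------------------------------------------
# targets and enrichment


def target_study(seed: int) -> dict:
    cfg = SimConfig(seed=seed)
    toy = build_toy_genome(cfg)
    u = simulate_utrs_and_terms(toy)
    scored, cons = targets.predict_targets(u.mirna_seqs, u.utrs)
    acc = u.true_sites[u.true_sites["accessible"]]
    dec = u.true_sites[~u.true_sites["accessible"]]
    ck = {(c.mirna, c.transcript) for c in cons}
    recall = (sum((r.mirna, r.transcript) in ck for r in acc.itertuples())
              / max(len(acc), 1))
    rejection = (sum((r.mirna, r.transcript) not in ck
                     for r in dec.itertuples()) / max(len(dec), 1))
    subset_ok = {c.key for c in cons} <= {s.key for s in scored}
    tg = {u.tx2gene[c.transcript] for c in cons}
    res = enrichment.hypergeom_enrich(tg, u.term_table,
                                      set(u.tx2gene.values()))
    top_is_planted = bool(len(res)) and res.iloc[0]["term"] == u.enriched_term
    return {"site_recall": recall, "decoy_rejection": rejection,
            "consensus_subset_ok": subset_ok,
            "top_term_is_planted": top_is_planted,
            "top_term_q": float(res.iloc[0]["q"]) if len(res) else float("nan"),
            "n_consensus": len(cons), "utr_sim": u, "enrichment": res}


def enrichment_closed_form_study() -> dict:
    """Agreement of the enrichment machinery with hand-computable values."""
    import math
    from scipy import stats as st
    background = {f"g{i}" for i in range(100)}
    tgt = {f"g{i}" for i in range(5)}
    table = pd.DataFrame([("T", f"g{i}") for i in range(5)],
                         columns=["term", "gene"])
    res = enrichment.hypergeom_enrich(tgt, table, background)
    p_err = abs(res.loc[0, "p"] - 1.0 / math.comb(100, 5))
    q = diffexpr.bh_adjust([0.01, 0.02, 0.03])
    bh_err = float(np.max(np.abs(q - 0.03)))
    z, p = enrichment.proportion_ztest(30, 40, 10, 40)
    z_hand = (0.75 - 0.25) / np.sqrt(0.5 * 0.5 * (1 / 40 + 1 / 40))
    return {"hypergeom_abs_err": float(p_err), "bh_abs_err": bh_err,
            "ztest_abs_err": abs(z - z_hand), "ztest_z": float(z)}


# ---------------------------------------------------------------------------
# tissue-specificity of novel vs annotated families


def specificity_study(seed: int) -> dict:
    """Plant novel families tissue-restricted and annotated families broad;
    the novel set must show a higher tissue-specific share (z-test)."""
    cfg = SimConfig(seed=seed, n_hairpins=40, n_genes=42,
                    genome_length=170_000, mean_depth=20_000)
    toy = build_toy_genome(cfg)
    annotated = toy.truth.annotated_families
    effects = {}
    novel = [lc.id for lc in toy.truth.loci if lc.id not in annotated]
    for fam in novel:
        # strong brain restriction: depressed everywhere else
        for st in ("heart", "muscle", "plasma"):
            effects[(f"{fam}-5p", "sample_type", st)] = -9.0
            effects[(f"{fam}-3p", "sample_type", st)] = -9.0
    cfg.effect_table = effects
    sim = simulate_libraries(toy, cfg)
    members = {f"OG_{lc.id}": [f"{lc.id}-5p", f"{lc.id}-3p"]
               for lc in toy.truth.loci}
    classes = {f"OG_{lc.id}": ("miRBase" if lc.id in annotated else "novel")
               for lc in toy.truth.loci}
    res = enrichment.specificity_classes(sim.true_counts, members, classes)
    cls = res.classes
    in_brain = cls[cls["expressed_in"].str.split(",")
                   .apply(lambda s: "brain" in s)]
    nov = in_brain[in_brain["source"] == "novel"]
    mb = in_brain[in_brain["source"] == "miRBase"]
    k1 = int((nov["breadth_class"] == "tissue-specific").sum())
    k2 = int((mb["breadth_class"] == "tissue-specific").sum())
    z, p = enrichment.proportion_ztest(k1, len(nov), k2, len(mb))
    return {"novel_specific_share": k1 / max(len(nov), 1),
            "mirbase_specific_share": k2 / max(len(mb), 1),
            "z": float(z), "p": float(p)}
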
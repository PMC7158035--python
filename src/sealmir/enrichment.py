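"""Term enrichment, tissue-specificity classes, and the two-proportion test.

Enrichment is an upper-tail hypergeometric test of each term's overlap
with a target gene set against a custom background (the non-redundant gene
universe used for target prediction), BH-corrected over the tested terms.
Tissue-specificity classifies each orthogroup by expression breadth
(tissue-specific, +1, +2, or all four sample types) at a fixed raw-read
threshold, and novel-vs-annotated proportions are compared with a pooled
two-proportion z-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix
from .diffexpr import bh_adjust

BREADTH_LABELS = {1: "tissue-specific", 2: "+1", 3: "+2", 4: "all"}


def hypergeom_enrich(
    target_genes: set[str],
    term_table: pd.DataFrame,
    background: set[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each term among the targets.

    term_table has columns (term, gene).  Targets must be a subset of the
    background; terms with zero annotated targets are untested (excluded
    from the BH correction).
    """
    offenders = sorted(target_genes - background)
    if offenders:
        raise ValueError(f"target genes absent from background: {offenders}")
    N = len(background)
    n = len(target_genes)
    rows = []
    tt = term_table[term_table["gene"].isin(background)]
    for term, genes in tt.groupby("term")["gene"]:
        annotated = set(genes)
        K = len(annotated)
        k = len(annotated & target_genes)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n and K else np.nan
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N,
                     "fold_enrichment": fold, "p": p})
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N",
                                      "fold_enrichment", "p"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values(["q", "p", "term"]).reset_index(drop=True)
    else:
        out["q"] = []
    return out


@dataclass
class SpecificityResult:
    classes: pd.DataFrame  # orthogroup, class source, breadth, expressed-in sets
    proportions: pd.DataFrame  # per (tissue, source): share of each breadth


def specificity_classes(
    counts: CountMatrix,
    orthogroup_members: dict[str, list[str]],
    orthogroup_class: dict[str, str],
    expressed_min: int = 10,
) -> SpecificityResult:
    """Expression-breadth classes per orthogroup.

    An orthogroup is expressed in a sample type iff any member strand
    totals >= expressed_min raw reads across that type's samples.  Breadth
    1..4 maps to tissue-specific, +1, +2, all.  Orthogroups expressed
    nowhere are dropped.  Proportions are reported per sample type over
    the orthogroups expressed in that type, split by class source
    (miRBase vs novel; mixed composition counts as miRBase upstream).
    """
    st = counts.samples["sample_type"]
    type_totals = counts.counts.T.groupby(st).sum().T  # strands x sample types
    rows = []
    for og, members in orthogroup_members.items():
        members = [m for m in members if m in type_totals.index]
        if not members:
            continue
        expressed = type_totals.loc[members].sum(axis=0) >= expressed_min
        breadth = int(expressed.sum())
        if breadth == 0:
            continue
        rows.append({"orthogroup": og,
                     "source": orthogroup_class.get(og, "novel"),
                     "breadth": breadth,
                     "breadth_class": BREADTH_LABELS[breadth],
                     "expressed_in": ",".join(sorted(expressed.index[expressed]))})
    classes = pd.DataFrame(rows, columns=["orthogroup", "source", "breadth",
                                          "breadth_class", "expressed_in"])
    prop_rows = []
    if len(classes):
        for tissue in sorted(st.unique()):
            in_t = classes[classes["expressed_in"].str.split(",")
                           .apply(lambda s: tissue in s)]
            for source, grp in in_t.groupby("source"):
                total = len(grp)
                for b, lab in BREADTH_LABELS.items():
                    k = int((grp["breadth"] == b).sum())
                    prop_rows.append({"sample_type": tissue, "source": source,
                                      "breadth_class": lab, "k": k, "n": total,
                                      "proportion": k / total if total else np.nan})
    proportions = pd.DataFrame(prop_rows)
    return SpecificityResult(classes=classes, proportions=proportions)


def proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z statistic and two-sided normal p-value."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if k1 > n1 or k2 > n2:
        raise ValueError("successes exceed group size")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    return float(z), float(2 * stats.norm.sf(abs(z)))
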
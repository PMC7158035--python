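#!/usr/bin/env python
"""Three-way consensus target prediction, enrichment, tissue specificity.

Runs the seed/duplex/accessibility scorers over the simulated UTRs,
intersects them, tests term enrichment of the consensus targets against
the full gene background, and compares tissue-specificity of novel vs
annotated miRNA families with the pooled two-proportion z-test.
"""

import argparse
from pathlib import Path

import pandas as pd

from sealmir import pipeline


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/targets"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    r = pipeline.target_study(args.seed)
    r["enrichment"].to_csv(args.out / "enrichment.tsv", sep="\t", index=False)
    print(f"consensus interactions: {r['n_consensus']}; planted accessible "
          f"sites recovered {r['site_recall']:.0%}, stem-buried decoys "
          f"rejected {r['decoy_rejection']:.0%}")
    if r["top_term_is_planted"]:
        print(f"planted term is the top enrichment hit "
              f"(q = {r['top_term_q']:.3g})")

    spec = pipeline.specificity_study(args.seed)
    pd.Series(spec).to_csv(args.out / "specificity.tsv", sep="\t",
                           header=False)
    print(f"tissue-specific share in brain-expressed families: novel "
          f"{spec['novel_specific_share']:.0%} vs annotated "
          f"{spec['mirbase_specific_share']:.0%} "
          f"(z = {spec['z']:.2f}, p = {spec['p']:.2g})")


if __name__ == "__main__":
    main()
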
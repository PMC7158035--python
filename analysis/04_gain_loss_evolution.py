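#!/usr/bin/env python
"""Orthogroup gain/loss evolution across the 8 simulated genomes.

Clusters hairpins at 80% identity, hides a tenth of the annotations,
rescues them by homolog search with synteny support, reconstructs
per-branch gains and losses by Dollo parsimony, and checks both oracles:
the exhaustive single-gain enumeration and the generator's event truth.
"""

import argparse
from pathlib import Path

from sealmir import pipeline


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/evolution"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    oracle = pipeline.dollo_oracle_study()
    print(f"Dollo vs brute force on all {oracle['n']} presence patterns: "
          f"{oracle['agreement']:.0%} agreement")

    r = pipeline.evolution_study(args.seed)
    r["gainloss_table"].to_csv(args.out / "gain_loss_table.tsv", sep="\t")
    print(f"{r['n_orthogroups']} orthogroups; clusters pure: "
          f"{r['clusters_pure']}")
    print(f"hidden annotations rescued by synteny: "
          f"{r['n_rescued']}/{r['n_hidden']}")
    print(f"per-branch gains/losses match truth on "
          f"{r['branch_agreement']:.0%} of branches; "
          f"net gain rates exact: {r['rates_exact']}")
    tbl = r["gainloss_table"]
    top = tbl[tbl["length_my"] > 0].nlargest(3, "net_gain_rate")
    for br, row in top.iterrows():
        label = br if "|" not in br else f"ancestor({br.split('|')[0]}...)"
        print(f"  highest net gain: {label}: +{int(row['gains'])}/"
              f"-{int(row['losses'])} over {row['length_my']:.0f} My "
              f"= {row['net_gain_rate']:.2f}/My")


if __name__ == "__main__":
    main()
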
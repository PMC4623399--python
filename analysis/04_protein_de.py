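"""Protein identification filtering and tiered differential abundance.

Applies the unused-ProtScore/peptide filter, then the one-tailed
one-sample t-tests against the 1.2x / 1.33x / 1.5x fold-change nulls.
"""

import argparse
from pathlib import Path

import pandas as pd

from energyomics.pipeline import protein_summary_counts, write_tsv
from energyomics.protstat import call_protein_de, filter_identifications


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--out", type=Path, default=Path("results/proteins"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    records = pd.read_csv(args.sim / "proteins.tsv", sep="\t")
    kept = filter_identifications(records)
    results = call_protein_de(kept, alpha=args.alpha)
    write_tsv(results, args.out / "de_proteins.tsv")

    tiers = protein_summary_counts(results)
    print(f"{len(kept)}/{len(records)} proteins pass identification")
    for tier, c in tiers.items():
        print(f"  {tier}: {c['n_up']} up, {c['n_down']} down (P<{args.alpha})")


if __name__ == "__main__":
    main()
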
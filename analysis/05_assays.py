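"""Metabolite, energy-panel and qPCR analyses.

Normalizes GC-MS peaks by ribitol and fresh weight, scales to the WT
0 h reference, tests genotype contrasts per metabolite and time point,
derives the energy pools/ratios, and computes ddCt fold changes.
"""

import argparse
from pathlib import Path

import pandas as pd

from energyomics import assays
from energyomics.pipeline import write_tsv


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results/assays"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    gcms = pd.read_csv(args.sim / "gcms.tsv", sep="\t")
    norm = assays.relative_to_reference_group(assays.normalize_gcms(gcms))
    write_tsv(norm, args.out / "gcms_normalized.tsv")

    rows = []
    for (met, tp), sub in norm.groupby(["metabolite", "timepoint"]):
        wt = sub[sub["genotype"] == "WT"]["relative"]
        oe = sub[sub["genotype"] == "OE"]["relative"]
        t, p, stars = assays.two_sample_t(wt, oe)
        rows.append({"metabolite": met, "timepoint": tp, "t": t, "p": p, "stars": stars})
    tests = pd.DataFrame(rows)
    write_tsv(tests, args.out / "gcms_tests.tsv")
    n_sig = (tests["stars"] != "").sum()
    print(f"GC-MS: {n_sig}/{len(tests)} metabolite/timepoint contrasts at P<0.05")

    energy = pd.read_csv(args.sim / "energy.tsv", sep="\t")
    ratios = assays.derive_energy_ratios(energy)
    summary = ratios.attrs["summary"]
    write_tsv(summary, args.out / "energy_summary.tsv")
    atp_nadph = summary[summary["quantity"] == "ATP/NADPH"]
    for _, r in atp_nadph.iterrows():
        print(
            f"ATP/NADPH {r['genotype']} {r['timepoint']}: "
            f"{r['mean']:.2f} +/- {r['sd']:.2f} (n={int(r['n'])})"
        )

    qpcr = pd.read_csv(args.sim / "qpcr.tsv", sep="\t")
    ddct = assays.ddct_relative_expression(qpcr)
    write_tsv(ddct, args.out / "qpcr_ddct.tsv")
    folds = ", ".join(
        f"{r['target']}: {r['fold_change']:.2f}" for _, r in ddct.iterrows()
    )
    print(f"qPCR ddCt fold changes -> {folds}")


if __name__ == "__main__":
    main()
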
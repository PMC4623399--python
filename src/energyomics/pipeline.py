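"""End-to-end orchestration of the synthetic tri-omic comparison.

``run_pipeline`` drives every stage from one config: simulate the
experiment, quantify RPKM and expressed genes, run the exact
transcript test at the study thresholds (FDR <= 0.001, 2-fold
genome-wide plus a 1.5-fold organellar pass), run the tiered protein
t-tests, the assay normalizations, and bin enrichment; it writes
machine-readable TSVs plus a summary.json, and — since the simulation
truth is known — a confusion matrix per omic layer.  All outputs are
byte-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import assays, detest, enrich, protstat, quantify
from .synthetic import (
    SimConfig,
    gen_category_map,
    gen_counts,
    gen_energy_panel,
    gen_itraq,
    gen_metabolites,
    gen_qpcr,
)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "de_summary_counts",
    "transcript_protein_correlation",
    "confusion_matrix",
    "write_tsv",
]

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Thresholds and simulation settings for one pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    alpha: float = 0.001
    fc_thresholds: tuple[float, ...] = (2.0, 1.5)
    protein_alpha: float = 0.05
    enrich_p_cutoff: float = 0.01
    n_bins: int = 20

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.protein_alpha <= 0:
            raise ValueError("alpha thresholds must be positive")
        if any(t <= 0 for t in self.fc_thresholds):
            raise ValueError("fold-change thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        cfg = cls(sim=sim, **{k: v for k, v in raw.items()})
        return cfg


def write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    """TSV writer with a fixed float format so reruns are byte-identical."""
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def de_summary_counts(de: pd.DataFrame) -> dict[str, int]:
    """Up/down tallies of a DE call table (transcripts or one protein tier)."""
    if "call" in de.columns:
        calls = de["call"]
        return {
            "n_up": int((calls == "up").sum()),
            "n_down": int((calls == "down").sum()),
            "n_tested": int(len(calls)),
        }
    raise ValueError("expected a 'call' column")


def protein_summary_counts(results: pd.DataFrame, tiers=protstat.TIERS) -> dict:
    """Per-tier up/down counts from the tiered protein test output."""
    out = {}
    for mu0 in tiers:
        calls = results[f"call_{mu0:g}"]
        out[f"{mu0:g}x"] = {
            "n_up": int((calls == "up").sum()),
            "n_down": int((calls == "down").sum()),
        }
    return out


def transcript_protein_correlation(
    transcript_log2fc: pd.Series,
    protein_log2fc: pd.Series,
    method: str = "spearman",
) -> dict:
    """Cross-omic fold-change correlation on matched feature ids."""
    common = transcript_log2fc.index.intersection(protein_log2fc.index)
    t = transcript_log2fc.reindex(common).to_numpy(dtype=float)
    p = protein_log2fc.reindex(common).to_numpy(dtype=float)
    ok = np.isfinite(t) & np.isfinite(p)
    t, p = t[ok], p[ok]
    if t.size < 3:
        return {"rho": float("nan"), "p": float("nan"), "n": int(t.size)}
    if method == "spearman":
        res = stats.spearmanr(t, p)
    elif method == "pearson":
        res = stats.pearsonr(t, p)
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    return {"rho": float(res.statistic), "p": float(res.pvalue), "n": int(t.size)}


def confusion_matrix(calls: pd.Series, truth: pd.Series) -> dict[str, int]:
    """Binary confusion of called-vs-true changed features on shared ids."""
    common = calls.index.intersection(truth.index)
    called = calls.reindex(common) != "ns"
    is_changed = truth.reindex(common) == "changed"
    return {
        "tp": int((called & is_changed).sum()),
        "fp": int((called & ~is_changed).sum()),
        "fn": int((~called & is_changed).sum()),
        "tn": int((~called & ~is_changed).sum()),
    }


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run simulate -> quantify -> test -> enrich -> report; return summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.sim.seed, "thresholds": {
        "alpha": config.alpha,
        "fc": list(config.fc_thresholds),
        "protein_alpha": config.protein_alpha,
        "enrich_p": config.enrich_p_cutoff,
    }}

    # --- simulate ---
    counts, annot, truth_rna = gen_counts(config.sim)
    proteins, truth_prot = gen_itraq(config.sim)
    gcms = gen_metabolites(config.sim)
    energy = gen_energy_panel(config.sim)
    qpcr = gen_qpcr(config.sim)
    bins = gen_category_map(config.sim, annot["gene_id"], n_bins=config.n_bins)

    write_tsv(counts.counts.reset_index(), out / "counts.tsv")
    write_tsv(annot, out / "annotation.tsv")
    write_tsv(truth_rna, out / "truth_transcripts.tsv")
    write_tsv(proteins, out / "proteins.tsv")
    write_tsv(truth_prot, out / "truth_proteins.tsv")
    write_tsv(bins, out / "bins.tsv")

    # --- quantify ---
    rpkm = quantify.compute_rpkm(counts, annot)
    expressed = quantify.detect_expressed(counts)
    gt_summary = quantify.summarize_gene_types(
        annot, counts.counts.index[expressed]
    )
    write_tsv(rpkm.reset_index(), out / "rpkm.tsv")
    write_tsv(gt_summary, out / "gene_type_summary.tsv", index=True)
    summary["total_expressed_genes"] = quantify.total_expressed(gt_summary)

    # --- transcript DE (one pass per fold-change tier) ---
    n1 = counts.library_sizes["lib1"]
    n2 = counts.library_sizes["lib2"]
    de_inputs = pd.DataFrame(
        {
            "gene_id": counts.counts.index,
            "x": counts.counts["lib1"].to_numpy(),
            "y": counts.counts["lib2"].to_numpy(),
        }
    )
    de_tables: dict[float, pd.DataFrame] = {}
    summary["transcripts"] = {}
    for fc in config.fc_thresholds:
        de = detest.call_de_table(
            de_inputs, n1, n2, alpha=config.alpha, fc_threshold=fc
        )
        de_tables[fc] = de
        write_tsv(de, out / f"de_transcripts_fc{fc:g}.tsv")
        summary["transcripts"][f"fc{fc:g}"] = de_summary_counts(de)
    de_main = de_tables[config.fc_thresholds[0]]
    truth_idx = truth_rna.set_index("feature_id")["true_status"]
    summary["transcripts"]["confusion"] = confusion_matrix(
        de_main.set_index("gene_id")["call"], truth_idx
    )

    # --- proteins ---
    identified = protstat.filter_identifications(proteins)
    prot_results = protstat.call_protein_de(
        identified, alpha=config.protein_alpha
    )
    write_tsv(prot_results, out / "de_proteins.tsv")
    summary["proteins"] = protein_summary_counts(prot_results)
    summary["proteins"]["n_identified"] = int(len(identified))
    summary["proteins"]["confusion_1.2x"] = confusion_matrix(
        prot_results.set_index("protein_id")["call_1.2"],
        truth_prot.set_index("feature_id")["true_status"],
    )

    # --- assays ---
    gcms_norm = assays.relative_to_reference_group(assays.normalize_gcms(gcms))
    write_tsv(gcms_norm, out / "gcms_normalized.tsv")
    met_tests = []
    for (met, tp), sub in gcms_norm.groupby(["metabolite", "timepoint"]):
        wt = sub[sub["genotype"] == "WT"]["relative"]
        oe = sub[sub["genotype"] == "OE"]["relative"]
        t, p, stars = assays.two_sample_t(wt, oe)
        met_tests.append(
            {"metabolite": met, "timepoint": tp, "t": t, "p": p, "stars": stars}
        )
    write_tsv(pd.DataFrame(met_tests), out / "gcms_tests.tsv")

    energy_ratios = assays.derive_energy_ratios(energy)
    write_tsv(energy_ratios, out / "energy_ratios.tsv")
    write_tsv(energy_ratios.attrs["summary"], out / "energy_summary.tsv")
    ddct = assays.ddct_relative_expression(qpcr)
    write_tsv(ddct, out / "qpcr_ddct.tsv")
    summary["qpcr_folds"] = {
        r["target"]: r["fold_change"] for _, r in ddct.iterrows()
    }

    # --- enrichment ---
    enr = enrich.enrichment_table(
        de_main, bins, timepoint="0h", p_cutoff=config.enrich_p_cutoff
    )
    write_tsv(enr, out / "enrichment.tsv")
    summary["enrichment"] = {
        "n_categories": int(len(enr)),
        "n_significant": int(enr["significant"].sum()) if not enr.empty else 0,
    }

    # --- cross-omic report ---
    corr = transcript_protein_correlation(
        de_main.set_index("gene_id")["log2fc"],
        np.log2(prot_results.set_index("protein_id")["mean_ratio"]),
    )
    summary["transcript_protein_correlation"] = corr

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary
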
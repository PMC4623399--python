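"""Synthetic tri-omic experiments with known ground truth.

Emulates the study design the statistics modules expect: two genotypes
(WT, OE) at three time points after the onset of illumination, with

* two unreplicated RNA-seq libraries per contrast — per-gene Poisson
  counts across the nuclear / mitochondrial / chloroplast gene sets,
  with spike-in fold changes on a known subset;
* iTRAQ protein quantification — four replicate OE/WT ratios per
  protein (2 biological x 2 technical, treated as 4 independent
  ratios), log-normally noised around a true ratio, plus identification
  scores so the ProtScore/peptide filter is exercised;
* GC-MS metabolite panels — raw peak heights with ribitol
  internal-standard and fresh-weight fields, 3 replicates per group;
* an enzymatic energy panel (ATP/ADP/NADP+/NADPH, nmol per g FW);
* qPCR Ct tables with a reference gene playing the Actin-2 role.

Each generator draws from its own RNG stream seeded from the config
seed plus a fixed offset, so adding one generator never perturbs the
draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quantify import CountMatrix, COMPARTMENTS

__all__ = [
    "SimConfig",
    "gen_counts",
    "gen_itraq",
    "gen_metabolites",
    "gen_energy_panel",
    "gen_qpcr",
    "gen_category_map",
]

# RNG stream offsets, one per generator
_STREAM_COUNTS = 1
_STREAM_ITRAQ = 2
_STREAM_METABOLITES = 3
_STREAM_QPCR = 4
_STREAM_ENERGY = 5
_STREAM_BINS = 6

# expressed-gene type composition per compartment (from the TAIR10-style
# annotation summary the generator mirrors)
_GENE_TYPE_WEIGHTS = {
    "nuclear": {
        "protein_coding": 21497,
        "rRNA": 2,
        "snRNA": 13,
        "snoRNA": 18,
        "miRNA": 66,
        "other_RNA": 339,
        "pseudogene": 368,
        "TE": 947,
    },
    "mitochondrial": {"protein_coding": 121, "pre_tRNA": 2, "rRNA": 3},
    "chloroplast": {"protein_coding": 87, "pre_tRNA": 1, "rRNA": 8},
}


def _default_metabolite_means() -> dict:
    """Group means for a small GC-MS panel (relative response units).

    OE effects echo the study's qualitative picture: higher sugars under
    light, higher sucrose in the dark, lower succinate at t=0 h.
    """
    base = {
        "sucrose": 10.0,
        "glucose": 5.0,
        "fructose": 4.0,
        "succinate": 2.0,
        "fumarate": 3.0,
        "asparagine": 1.0,
    }
    oe_fold = {
        "sucrose": {"0h": 1.5, "1h": 1.2, "8h": 1.6},
        "glucose": {"0h": 1.0, "1h": 1.5, "8h": 1.5},
        "fructose": {"0h": 0.7, "1h": 1.5, "8h": 1.5},
        "succinate": {"0h": 0.6, "1h": 1.0, "8h": 1.0},
        "fumarate": {"0h": 1.0, "1h": 1.0, "8h": 1.4},
        "asparagine": {"0h": 1.8, "1h": 1.8, "8h": 1.8},
    }
    means: dict = {}
    for met, b in base.items():
        means[met] = {
            "WT": {"0h": b, "1h": b, "8h": b},
            "OE": {tp: b * oe_fold[met][tp] for tp in ("0h", "1h", "8h")},
        }
    return means


def _default_energy_means() -> dict:
    """Energy-panel group means in nmol per g fresh weight.

    Magnitudes are typical leaf adenylate/pyridine-nucleotide pools;
    the OE line carries ~40-50% more ATP at every time point and less
    NADPH in the light, so ATP/NADPH separates the genotypes.
    """
    return {
        "ATP": {
            "WT": {"0h": 30.0, "1h": 40.0, "8h": 45.0},
            "OE": {"0h": 45.0, "1h": 58.0, "8h": 65.0},
        },
        "ADP": {
            "WT": {"0h": 20.0, "1h": 22.0, "8h": 24.0},
            "OE": {"0h": 30.0, "1h": 32.0, "8h": 35.0},
        },
        "NADP+": {
            "WT": {"0h": 12.0, "1h": 10.0, "8h": 10.0},
            "OE": {"0h": 9.0, "1h": 10.0, "8h": 10.0},
        },
        "NADPH": {
            "WT": {"0h": 8.0, "1h": 10.0, "8h": 11.0},
            "OE": {"0h": 8.0, "1h": 9.5, "8h": 8.0},
        },
    }


@dataclass
class SimConfig:
    """Knobs of the synthetic tri-omic experiment.

    Defaults mirror the study conditions: gene-set sizes per genome
    (23,250 nuclear / 126 mitochondrial / 96 chloroplast), ten million
    mappable reads per library, 10% of genes carrying a 4-fold spike-in
    (half up, half down), four replicate protein ratios with 0.1
    natural-log noise, and triplicate assay panels.
    """

    seed: int = 0
    # --- RNA-seq ---
    n_genes_by_compartment: Mapping[str, int] = field(
        default_factory=lambda: {
            "nuclear": 23250,
            "mitochondrial": 126,
            "chloroplast": 96,
        }
    )
    library_sizes: tuple[int, int] = (10_000_000, 10_000_000)
    gene_length_range: tuple[int, int] = (300, 3000)
    rpkm_log_mean: float = 1.0
    rpkm_log_sd: float = 1.5
    frac_de: float = 0.10
    log2_effects: Sequence[float] = (2.0, -2.0)
    overdispersion: float = 0.0  # Gamma-mixed Poisson; 0 = pure Poisson
    # --- iTRAQ proteins ---
    n_proteins: int = 2000
    protein_ratio_noise_sd: float = 0.1
    frac_protein_changed: float = 0.10
    protein_true_ratios: Sequence[float] = (2.0, 0.5)
    frac_protein_fail_id: float = 0.10
    # --- GC-MS metabolites ---
    metabolite_group_means: Mapping = field(
        default_factory=_default_metabolite_means
    )
    metabolite_cv: float = 0.10
    n_reps: int = 3
    mean_fresh_weight_g: float = 0.05
    ribitol_height: float = 500.0
    # --- energy panel ---
    energy_group_means: Mapping = field(default_factory=_default_energy_means)
    energy_cv: float = 0.10
    # --- qPCR ---
    qpcr_designed_log2fc: Sequence[float] = (2.0, 1.0, 0.0, -1.0)
    qpcr_ct_noise_sd: float = 0.1
    qpcr_n_reps: int = 3
    qpcr_base_ct_target: float = 24.0
    qpcr_base_ct_reference: float = 18.0

    def __post_init__(self) -> None:
        for comp, n in self.n_genes_by_compartment.items():
            if comp not in COMPARTMENTS:
                raise ValueError(f"unknown compartment {comp!r}")
            if n <= 0:
                raise ValueError("gene counts per compartment must be > 0")
        n1, n2 = self.library_sizes
        if n1 <= 0 or n2 <= 0:
            raise ValueError("library sizes must be positive")
        lo, hi = self.gene_length_range
        if lo < 1 or hi < lo:
            raise ValueError("gene lengths must be >= 1 bp with lo <= hi")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must be in [0, 1]")
        if not 0.0 <= self.frac_protein_changed <= 1.0:
            raise ValueError("frac_protein_changed must be in [0, 1]")
        if self.protein_ratio_noise_sd < 0:
            raise ValueError("protein_ratio_noise_sd must be >= 0")
        if self.metabolite_cv < 0 or self.energy_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")

    def rng(self, offset: int) -> np.random.Generator:
        """Independent RNG stream for one generator."""
        return np.random.default_rng([self.seed, offset])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_genes_by_compartment"] = dict(self.n_genes_by_compartment)
        return d


def _pick_changed(n: int, frac: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask with floor(frac*n) True entries at shuffled positions."""
    n_changed = int(np.floor(frac * n))
    order = rng.permutation(n)
    mask = np.zeros(n, dtype=bool)
    mask[order[:n_changed]] = True
    return mask


def gen_counts(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate the two-library RNA-seq experiment.

    Counts follow the model the exact test assumes: x_g1 ~ Poisson(l_g1)
    and x_g2 ~ Poisson(l_g2 * 2**delta_g) with l_gl = N_l * L_g *
    RPKM_g / 1e9 and delta_g the true log2 effect (0 for null genes).
    Returns (CountMatrix, annotation, truth).
    """
    rng = config.rng(_STREAM_COUNTS)
    comps, gene_types = [], []
    for comp in COMPARTMENTS:
        n = int(config.n_genes_by_compartment.get(comp, 0))
        if n == 0:
            continue
        weights = _GENE_TYPE_WEIGHTS[comp]
        types = list(weights)
        probs = np.array([weights[t] for t in types], dtype=float)
        probs /= probs.sum()
        comps.extend([comp] * n)
        gene_types.extend(rng.choice(types, size=n, p=probs))
    n_genes = len(comps)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]

    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n_genes)
    rpkm = np.exp(rng.normal(config.rpkm_log_mean, config.rpkm_log_sd, n_genes))

    changed = _pick_changed(n_genes, config.frac_de, rng)
    effects = np.zeros(n_genes)
    if changed.any():
        cycle = np.resize(np.asarray(config.log2_effects, float), changed.sum())
        effects[changed] = cycle

    n1, n2 = config.library_sizes
    lam1 = n1 * lengths * rpkm / 1e9
    lam2 = n2 * lengths * rpkm / 1e9 * np.exp2(effects)
    if config.overdispersion > 0:
        shape = 1.0 / config.overdispersion
        lam1 = lam1 * rng.gamma(shape, 1.0 / shape, n_genes)
        lam2 = lam2 * rng.gamma(shape, 1.0 / shape, n_genes)
    x1 = rng.poisson(lam1)
    x2 = rng.poisson(lam2)

    counts = CountMatrix(
        counts=pd.DataFrame({"lib1": x1, "lib2": x2}, index=pd.Index(gene_ids, name="gene_id")),
        library_sizes={"lib1": n1, "lib2": n2},
    )
    annot = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "compartment": comps,
            "gene_type": gene_types,
            "length_bp": lengths,
        }
    )
    truth = pd.DataFrame(
        {
            "feature_id": gene_ids,
            "compartment": comps,
            "true_status": np.where(changed, "changed", "null"),
            "true_log2fc": effects,
        }
    )
    return counts, annot, truth


def gen_itraq(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate iTRAQ protein quantification records.

    Each protein carries four replicate OE/WT ratios r * exp(eps) with
    eps ~ Normal(0, protein_ratio_noise_sd^2); a configurable fraction
    fails the identification filter (unused ProtScore < 1.3 or fewer
    than two confident peptides).  Protein ids reuse the simulated gene
    ids so transcript-protein matching works downstream.
    """
    rng = config.rng(_STREAM_ITRAQ)
    n = config.n_proteins
    ids = [f"G{i:05d}" for i in range(n)]

    changed = _pick_changed(n, config.frac_protein_changed, rng)
    true_ratio = np.ones(n)
    if changed.any():
        true_ratio[changed] = np.resize(
            np.asarray(config.protein_true_ratios, float), changed.sum()
        )

    eps = rng.normal(0.0, config.protein_ratio_noise_sd, size=(n, 4))
    ratios = true_ratio[:, None] * np.exp(eps)

    fails = _pick_changed(n, config.frac_protein_fail_id, rng)
    unused = np.where(
        fails & (rng.random(n) < 0.5),
        rng.uniform(0.1, 1.29, n),
        rng.uniform(1.3, 9.0, n),
    )
    peptides = np.where(
        fails & (unused >= 1.3), 1, 2 + rng.poisson(3.0, n)
    )

    table = pd.DataFrame(
        {
            "protein_id": ids,
            "unused_score": np.round(unused, 3),
            "n_peptides_95": peptides,
            "ratio_r1": ratios[:, 0],
            "ratio_r2": ratios[:, 1],
            "ratio_r3": ratios[:, 2],
            "ratio_r4": ratios[:, 3],
        }
    )
    truth = pd.DataFrame(
        {
            "feature_id": ids,
            "true_status": np.where(changed, "changed", "null"),
            "true_ratio": true_ratio,
            "passes_id_filter": ~fails,
        }
    )
    return table, truth


def gen_metabolites(config: SimConfig) -> pd.DataFrame:
    """Simulate GC-MS records with raw normalization fields.

    Replicate relative responses are group_mean * (1 + Normal(0, cv)).
    Peak heights are back-composed as response * ribitol_height *
    fresh_weight so the ribitol/fresh-weight normalization recovers the
    designed response exactly end to end.
    """
    rng = config.rng(_STREAM_METABOLITES)
    rows = []
    for met, per_gt in config.metabolite_group_means.items():
        for gt, per_tp in per_gt.items():
            for tp, mean in per_tp.items():
                for rep in range(1, config.n_reps + 1):
                    value = mean * (1.0 + rng.normal(0.0, config.metabolite_cv))
                    fw = max(
                        config.mean_fresh_weight_g
                        * (1.0 + rng.normal(0.0, 0.05)),
                        1e-4,
                    )
                    rib = config.ribitol_height * (
                        1.0 + rng.normal(0.0, 0.02)
                    )
                    rows.append(
                        {
                            "assay_type": "gcms",
                            "metabolite": met,
                            "genotype": gt,
                            "timepoint": tp,
                            "replicate": rep,
                            "peak_height": value * rib * fw,
                            "ribitol_height": rib,
                            "fresh_weight": fw,
                            "true_response": mean,
                        }
                    )
    return pd.DataFrame(rows)


def gen_energy_panel(config: SimConfig) -> pd.DataFrame:
    """Simulate the ATP/ADP/NADP+/NADPH panel (nmol per g fresh weight)."""
    rng = config.rng(_STREAM_ENERGY)
    rows = []
    for analyte, per_gt in config.energy_group_means.items():
        for gt, per_tp in per_gt.items():
            for tp, mean in per_tp.items():
                for rep in range(1, config.n_reps + 1):
                    value = mean * (1.0 + rng.normal(0.0, config.energy_cv))
                    rows.append(
                        {
                            "assay_type": "energy",
                            "analyte": analyte,
                            "genotype": gt,
                            "timepoint": tp,
                            "replicate": rep,
                            "value_nmol_per_gfw": max(value, 0.0),
                        }
                    )
    return pd.DataFrame(rows)


def gen_qpcr(config: SimConfig) -> pd.DataFrame:
    """Simulate qPCR Ct tables for target genes plus a reference gene.

    Each target has a designed log2 fold change d between treatment and
    control; Ct values get additive Normal noise.  With zero noise the
    downstream 2^-ddCt estimate recovers 2**d exactly.
    """
    rng = config.rng(_STREAM_QPCR)
    d_ct0 = config.qpcr_base_ct_target - config.qpcr_base_ct_reference
    rows = []
    for t_idx, d in enumerate(config.qpcr_designed_log2fc):
        for group in ("control", "treatment"):
            shift = -d if group == "treatment" else 0.0
            for rep in range(1, config.qpcr_n_reps + 1):
                ct_ref = config.qpcr_base_ct_reference + rng.normal(
                    0.0, config.qpcr_ct_noise_sd
                )
                ct_tgt = (
                    config.qpcr_base_ct_reference
                    + d_ct0
                    + shift
                    + rng.normal(0.0, config.qpcr_ct_noise_sd)
                )
                rows.append(
                    {
                        "assay_type": "qpcr",
                        "target": f"T{t_idx + 1}",
                        "sample_id": f"T{t_idx + 1}_{group}_{rep}",
                        "group": group,
                        "replicate": rep,
                        "ct_target": ct_tgt,
                        "ct_reference": ct_ref,
                        "true_log2fc": d,
                    }
                )
    return pd.DataFrame(rows)


def gen_category_map(
    config: SimConfig,
    feature_ids: Sequence[str],
    n_bins: int = 20,
    mean_bins_per_feature: float = 1.3,
) -> pd.DataFrame:
    """Assign features to synthetic hierarchical functional bins.

    A stand-in ontology for enrichment tests (two-column layout:
    feature_id, bin path); real bin content is user-supplied data.
    """
    rng = config.rng(_STREAM_BINS)
    paths = [
        f"proc{1 + i // 5}.sub{1 + i % 5}" for i in range(n_bins)
    ]
    rows = []
    for fid in feature_ids:
        k = max(1, rng.poisson(mean_bins_per_feature))
        k = min(k, n_bins)
        for b in rng.choice(n_bins, size=k, replace=False):
            rows.append({"feature_id": fid, "bin": paths[b]})
    return pd.DataFrame(rows)
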
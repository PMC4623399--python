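"""Metabolite, energy-panel and qPCR assay math.

GC-MS responses are normalized per record by the ribitol internal
standard and the sample fresh weight, then rescaled to the mean of a
reference group (WT at t = 0 h by convention).  The energy panel
(ATP/ADP/NADP+/NADPH in nmol per g FW) yields the derived pools and
ratios ATP/ADP, ATP+ADP, NADPH/NADP+, NADP+ + NADPH and ATP/NADPH,
computed per replicate and then summarized.  Group contrasts use
two-sample t-tests (Welch by default; a pooled-variance variant is one
flag away, as software defaults differ and n = 3 per group makes the
choice visible).  qPCR relative expression uses the comparative
threshold (ddCt) method against a reference gene, with a paired
two-tailed t-test on per-replicate dCt values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "normalize_gcms",
    "relative_to_reference_group",
    "derive_energy_ratios",
    "two_sample_t",
    "significance_stars",
    "ddct_relative_expression",
]


def normalize_gcms(records: pd.DataFrame) -> pd.DataFrame:
    """Per-g-FW relative response: peak_height / ribitol_height / fresh_weight."""
    required = {"peak_height", "ribitol_height", "fresh_weight"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records are missing columns: {sorted(missing)}")
    bad = records[
        (records["ribitol_height"] <= 0) | (records["fresh_weight"] <= 0)
    ]
    if not bad.empty:
        ids = bad.index.tolist()[:10]
        raise ValueError(
            f"non-positive ribitol height or fresh weight in records {ids}"
        )
    out = records.copy()
    out["normalized"] = (
        out["peak_height"] / out["ribitol_height"] / out["fresh_weight"]
    )
    return out


def relative_to_reference_group(
    table: pd.DataFrame,
    value_col: str = "normalized",
    by: str = "metabolite",
    ref_genotype: str = "WT",
    ref_timepoint: str = "0h",
) -> pd.DataFrame:
    """Scale each analyte so the reference group's mean maps to 1.

    Division is by the mean of (ref_genotype, ref_timepoint) within each
    ``by`` group; analytes whose reference mean is zero are flagged and
    their values set to missing.
    """
    out = table.copy()
    out["relative"] = np.nan
    out["reference_flag"] = "ok"
    for key, sub in table.groupby(by):
        ref = sub[
            (sub["genotype"] == ref_genotype)
            & (sub["timepoint"] == ref_timepoint)
        ][value_col]
        if ref.empty:
            raise ValueError(f"no reference group for {by}={key!r}")
        ref_mean = ref.mean()
        idx = sub.index
        if ref_mean == 0:
            out.loc[idx, "reference_flag"] = "zero_reference_mean"
        else:
            out.loc[idx, "relative"] = table.loc[idx, value_col] / ref_mean
    return out


#: derived quantity -> (numerator, denominator or None for sums)
ENERGY_DERIVED = {
    "ATP/ADP": ("ATP", "ADP"),
    "ATP+ADP": ("ATP", "ADP", "sum"),
    "NADPH/NADP+": ("NADPH", "NADP+"),
    "NADP++NADPH": ("NADP+", "NADPH", "sum"),
    "ATP/NADPH": ("ATP", "NADPH"),
}


def derive_energy_ratios(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate derived energy pools and ratios, plus group summaries.

    ``panel`` is long-format with columns analyte, genotype, timepoint,
    replicate, value_nmol_per_gfw.  Ratios are computed within each
    (genotype, timepoint, replicate) triple and then summarized as mean
    and SD across replicates; a zero denominator leaves that replicate's
    ratio missing.
    """
    wide = panel.pivot_table(
        index=["genotype", "timepoint", "replicate"],
        columns="analyte",
        values="value_nmol_per_gfw",
    )
    rows = []
    for name, spec in ENERGY_DERIVED.items():
        if len(spec) == 3:  # sum
            a, b, _ = spec
            vals = wide[a] + wide[b]
        else:
            a, b = spec
            denom = wide[b].replace(0.0, np.nan)
            vals = wide[a] / denom
        for (gt, tp, rep), v in vals.items():
            rows.append(
                {
                    "quantity": name,
                    "genotype": gt,
                    "timepoint": tp,
                    "replicate": rep,
                    "value": v,
                }
            )
    per_rep = pd.DataFrame(rows)
    summary = (
        per_rep.groupby(["quantity", "genotype", "timepoint"])["value"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    per_rep.attrs["summary"] = summary
    return per_rep


def two_sample_t(
    group_a,
    group_b,
    equal_var: bool = False,
    two_tailed: bool = True,
) -> tuple[float, float, str]:
    """Two-sample t-test between replicate groups: (t, p, stars).

    Welch (unequal variances) by default; set ``equal_var=True`` for the
    pooled-variance test.  Stars: '*' for p < 0.05, '**' for p < 0.01.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two replicates per group")
    if np.array_equal(a, b) and a.std() == 0 and b.std() == 0:
        return 0.0, 1.0, ""
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    t = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(p):  # both groups constant and equal
        t, p = 0.0, 1.0
    if not two_tailed:
        p = p / 2.0 if t > 0 else 1.0 - p / 2.0
    return t, p, significance_stars(p)


def significance_stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def ddct_relative_expression(
    records: pd.DataFrame,
    treatment: str = "treatment",
    control: str = "control",
) -> pd.DataFrame:
    """Comparative-threshold (ddCt) relative expression per target.

    For each target: dCt = ct_target - ct_reference per sample;
    ddCt = mean dCt(treatment) - mean dCt(control); fold = 2**(-ddCt).
    Per-group relative abundances 2**(-dCt) are rescaled so the maximum
    across the compared groups is 1.  Significance is a two-tailed
    paired t-test on replicate-matched dCt values, so replicate counts
    must agree between groups.
    """
    required = {"target", "group", "replicate", "ct_target", "ct_reference"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records are missing columns: {sorted(missing)}")
    out = []
    for target, sub in records.groupby("target"):
        sub = sub.copy()
        sub["dct"] = sub["ct_target"] - sub["ct_reference"]
        trt = sub[sub["group"] == treatment].sort_values("replicate")
        ctl = sub[sub["group"] == control].sort_values("replicate")
        if len(trt) != len(ctl):
            raise ValueError(
                f"{target}: paired test needs equal replicate counts "
                f"({len(trt)} vs {len(ctl)})"
            )
        ddct = trt["dct"].mean() - ctl["dct"].mean()
        fold = 2.0 ** (-ddct)
        rel = 2.0 ** (-sub.groupby("group")["dct"].mean())
        rel = rel / rel.max()
        diff = trt["dct"].to_numpy() - ctl["dct"].to_numpy()
        if np.allclose(diff.std(ddof=1) if len(diff) > 1 else 0.0, 0.0):
            p = 1.0 if np.allclose(diff, 0.0) else float("nan")
        else:
            p = float(stats.ttest_rel(trt["dct"], ctl["dct"]).pvalue)
        out.append(
            {
                "target": target,
                "ddct": ddct,
                "fold_change": fold,
                "relative_treatment": rel.get(treatment, np.nan),
                "relative_control": rel.get(control, np.nan),
                "p_paired": p,
                "n_pairs": len(diff),
            }
        )
    return pd.DataFrame(out)
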
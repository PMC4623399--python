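"""Functional-category enrichment over DE calls and log2 ratios.

Two complementary category tests, in the style of bin-based pathway
displays for plant expression data:

* Fisher's exact overrepresentation — one-sided hypergeometric
  upper-tail p for the count of DE features inside a category versus
  the background 2x2 table;
* Wilcoxon rank-sum shift — two-sided test of the category members'
  log2 ratios against the complement (exact enumeration for small
  categories, normal approximation with tie correction otherwise).

Categories are hierarchical bin paths supplied as a two-column table
(feature_id, bin); a feature may sit in several bins and is counted
once per bin.  Raw p-values at P < 0.01 are the default significance
rule (no cross-category correction); a BH option is provided.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .detest import bh_fdr

__all__ = [
    "category_map_from_table",
    "fisher_overrep",
    "wilcoxon_shift",
    "enrichment_table",
    "enrichment_matrix",
]

EXACT_MAX_N = 10


def category_map_from_table(bins: pd.DataFrame) -> dict[str, set[str]]:
    """Invert a (feature_id, bin) table into bin -> set of features."""
    missing = {"feature_id", "bin"} - set(bins.columns)
    if missing:
        raise ValueError(f"bin table is missing columns: {sorted(missing)}")
    if (bins["bin"].astype(str).str.len() == 0).any():
        raise ValueError("empty bin labels")
    out: dict[str, set[str]] = {}
    for b, sub in bins.groupby("bin"):
        out[str(b)] = set(sub["feature_id"])
    return out


def _members(category_map: Mapping[str, set], category: str) -> set:
    if category not in category_map:
        raise KeyError(f"unknown category {category!r}")
    members = category_map[category]
    if not members:
        raise ValueError(f"category {category!r} is empty")
    return members


def fisher_overrep(
    de_flags: pd.Series, category_map: Mapping[str, set], category: str
) -> float:
    """One-sided overrepresentation p for DE features in a category.

    ``de_flags`` is a boolean Series over the tested universe; mapped
    features outside the universe are ignored.  Returns the
    hypergeometric upper-tail probability of observing at least the
    seen number of DE features in the category.
    """
    members = _members(category_map, category)
    in_cat = de_flags.index.isin(members)
    if not in_cat.any():
        raise ValueError(f"category {category!r} has no features in universe")
    m_total = len(de_flags)
    n_de = int(de_flags.sum())
    k_cat = int(in_cat.sum())
    k_de_in = int(de_flags[in_cat].sum())
    return float(stats.hypergeom.sf(k_de_in - 1, m_total, n_de, k_cat))


def wilcoxon_shift(
    log2fc: pd.Series,
    category_map: Mapping[str, set],
    category: str,
    exact_max_n: int = EXACT_MAX_N,
) -> tuple[float, float, str]:
    """Two-sided rank-sum test of category log2 ratios vs the complement.

    Returns (U statistic, p, direction) with direction the sign of the
    median difference ('up', 'down' or 'none').  Exact null enumeration
    is used when the category has at most ``exact_max_n`` members;
    larger categories use the normal approximation with tie correction.
    """
    members = _members(category_map, category)
    in_cat = log2fc.index.isin(members)
    a = log2fc[in_cat].to_numpy(dtype=float)
    b = log2fc[~in_cat].to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError(
            f"category {category!r} must split the universe non-trivially"
        )
    method = "exact" if a.size <= exact_max_n else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    med_diff = float(np.median(a) - np.median(b))
    if med_diff > 0:
        direction = "up"
    elif med_diff < 0:
        direction = "down"
    else:
        direction = "none"
    return float(res.statistic), float(res.pvalue), direction


def enrichment_table(
    de_table: pd.DataFrame,
    bins: pd.DataFrame,
    timepoint: str = "",
    p_cutoff: float = 0.01,
    correct: bool = False,
) -> pd.DataFrame:
    """Per-category Fisher + Wilcoxon tests for one contrast.

    ``de_table`` needs ``gene_id``, ``call`` and ``log2fc`` (finite
    values only enter the rank test).  Mapped features absent from the
    universe are dropped; their count is recorded in
    ``result.attrs['n_dropped_features']``.
    """
    cmap = category_map_from_table(bins)
    universe = pd.Index(de_table["gene_id"])
    mapped = set(bins["feature_id"])
    n_dropped = len(mapped - set(universe))

    de_flags = pd.Series(
        (de_table["call"] != "ns").to_numpy(), index=universe
    )
    lfc = pd.Series(de_table["log2fc"].to_numpy(), index=universe)
    finite = np.isfinite(lfc.to_numpy())
    lfc_fin = lfc[finite]

    rows = []
    for cat, members in sorted(cmap.items()):
        members_in = universe.isin(members)
        n_in = int(members_in.sum())
        if n_in == 0:
            continue
        fisher_p = fisher_overrep(de_flags, cmap, cat)
        _, wilcox_p, direction = wilcoxon_shift(lfc_fin, cmap, cat)
        med = float(np.median(lfc_fin[lfc_fin.index.isin(members)]))
        rows.append(
            {
                "category": cat,
                "timepoint": timepoint,
                "n_in": n_in,
                "n_out": len(universe) - n_in,
                "fisher_p": fisher_p,
                "wilcoxon_p": wilcox_p,
                "median_log2fc": med,
                "direction": direction,
            }
        )
    result = pd.DataFrame(rows)
    if not result.empty:
        fisher = result["fisher_p"]
        wilcox = result["wilcoxon_p"]
        if correct:
            fisher = pd.Series(bh_fdr(fisher), index=result.index)
            wilcox = pd.Series(bh_fdr(wilcox), index=result.index)
        result["significant"] = (fisher < p_cutoff) | (wilcox < p_cutoff)
    result.attrs["n_dropped_features"] = n_dropped
    return result


def enrichment_matrix(per_timepoint: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Condense per-timepoint results into a categories x timepoints table.

    Cells hold the category's median log2 fold change, with a parallel
    ``<tp>_sig`` flag column per time point.
    """
    pieces = []
    for tp, table in per_timepoint.items():
        sub = table.set_index("category")[["median_log2fc", "significant"]]
        sub.columns = [tp, f"{tp}_sig"]
        pieces.append(sub)
    if not pieces:
        return pd.DataFrame()
    out = pd.concat(pieces, axis=1)
    out.index.name = "category"
    return out
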
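"""iTRAQ protein identification filtering and tiered ratio t-tests.

Proteins pass identification with an unused ProtScore of at least 1.3
and at least two peptides at >= 95% confidence.  Differential abundance
is then assessed per protein by one-tailed one-sample t-tests of the
four replicate OE/WT ratios against assumed fold-change nulls
mu0 in {1.2, 1.33, 1.5}:

    t = (xbar - mu0) / (s / sqrt(n)),   df = n - 1 = 3

with xbar the arithmetic mean ratio and s the sample SD.  A protein is
called up at a tier when its mean exceeds mu0 and the upper-tail p is
below alpha (default 0.05); down-calls test against the reciprocal null
1/mu0 with the lower tail (symmetric on the log scale), with a
lower-tail-at-mu0 alternative available.  No multiple-testing
correction is applied across proteins — calls are per-protein at raw
P < 0.05, mirroring the study's procedure; combine with ``detest.bh_fdr``
if FDR control is wanted.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TIERS",
    "filter_identifications",
    "one_sample_t",
    "call_protein_de",
]

TIERS = (1.2, 1.33, 1.5)

MIN_UNUSED_SCORE = 1.3
MIN_PEPTIDES = 2

RATIO_COLUMNS = ["ratio_r1", "ratio_r2", "ratio_r3", "ratio_r4"]


def filter_identifications(records: pd.DataFrame) -> pd.DataFrame:
    """Keep proteins with unused_score >= 1.3 and >= 2 confident peptides."""
    required = {"unused_score", "n_peptides_95"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records are missing columns: {sorted(missing)}")
    keep = (records["unused_score"] >= MIN_UNUSED_SCORE) & (
        records["n_peptides_95"] >= MIN_PEPTIDES
    )
    return records.loc[keep].reset_index(drop=True)


def one_sample_t(ratios, mu0: float, tail: str = "greater") -> tuple[float, float]:
    """One-tailed one-sample t-test of replicate ratios against mu0.

    Returns (t, p) with t = (xbar - mu0)/(s/sqrt(n)) and p the
    requested Student-t tail probability at df = n - 1.  A zero sample
    SD is degenerate: t is +-inf or 0 and p is returned as NaN (never
    significant downstream).
    """
    if tail not in ("greater", "less"):
        raise ValueError("tail must be 'greater' or 'less'")
    r = np.asarray(ratios, dtype=float)
    if r.ndim != 1 or r.size < 2:
        raise ValueError("need at least two replicate ratios")
    if np.any(r <= 0):
        raise ValueError("ratios must be positive")
    n = r.size
    xbar = r.mean()
    s = r.std(ddof=1)
    if s == 0.0:
        t = math.inf if xbar > mu0 else (-math.inf if xbar < mu0 else 0.0)
        return t, float("nan")
    t = (xbar - mu0) / (s / math.sqrt(n))
    if tail == "greater":
        p = float(stats.t.sf(t, df=n - 1))
    else:
        p = float(stats.t.cdf(t, df=n - 1))
    return float(t), p


def _tier_call(
    ratios: np.ndarray, mu0: float, alpha: float, down_mode: str
) -> tuple[str, float, float]:
    """Call one protein at one tier; returns (call, t_up, p_used)."""
    xbar = ratios.mean()
    t_up, p_up = one_sample_t(ratios, mu0, tail="greater")
    if xbar > mu0 and not math.isnan(p_up) and p_up < alpha:
        return "up", t_up, p_up
    if down_mode == "reciprocal":
        mu_down = 1.0 / mu0
    elif down_mode == "lower_tail":
        mu_down = mu0
    else:
        raise ValueError("down_mode must be 'reciprocal' or 'lower_tail'")
    t_dn, p_dn = one_sample_t(ratios, mu_down, tail="less")
    if xbar < mu_down and not math.isnan(p_dn) and p_dn < alpha:
        return "down", t_up, p_dn
    return "ns", t_up, p_up


def call_protein_de(
    records: pd.DataFrame,
    alpha: float = 0.05,
    tiers=TIERS,
    down_mode: str = "reciprocal",
) -> pd.DataFrame:
    """Tiered differential-abundance calls for filtered protein records.

    ``records`` needs ``protein_id`` and the four ratio columns.  For
    each tier mu0 the output carries the upper-tail t statistic, the
    p-value backing the call, and the call itself; ``df`` is n-1 = 3
    throughout.
    """
    missing = set(["protein_id", *RATIO_COLUMNS]) - set(records.columns)
    if missing:
        raise ValueError(f"records are missing columns: {sorted(missing)}")
    out_rows = []
    for _, row in records.iterrows():
        ratios = row[RATIO_COLUMNS].to_numpy(dtype=float)
        entry = {
            "protein_id": row["protein_id"],
            "mean_ratio": ratios.mean(),
            "sd": ratios.std(ddof=1),
            "df": len(ratios) - 1,
        }
        for mu0 in tiers:
            call, t, p = _tier_call(ratios, mu0, alpha, down_mode)
            key = f"{mu0:g}"
            entry[f"t_{key}"] = t
            entry[f"p_{key}"] = p
            entry[f"call_{key}"] = call
        out_rows.append(entry)
    return pd.DataFrame(out_rows)
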
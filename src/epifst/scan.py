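"""All-pairs SNP scanning with multiple-testing adjustment."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data import DegenerateInputError, GenotypeDataset, pair_counts
from .power import ALL_METHODS, run_test

CORRECTIONS = ("bonferroni", "bh", "none")
_SM_METHOD = {"bonferroni": "bonferroni", "bh": "fdr_bh"}


def adjust_pvalues(p: np.ndarray, correction: str) -> np.ndarray:
    """Bonferroni or Benjamini-Hochberg adjustment of a p-value vector.

    NaN entries (degenerate pairs) are excluded from the family and stay NaN.
    """
    p = np.asarray(p, dtype=float)
    ok = np.isfinite(p)
    out = np.full_like(p, np.nan)
    if not ok.any():
        return out
    if correction == "none":
        out[ok] = p[ok]
    elif correction in _SM_METHOD:
        out[ok] = multipletests(p[ok], method=_SM_METHOD[correction])[1]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return out


def scan_all_pairs(
    ds: GenotypeDataset,
    methods: tuple[str, ...] = ALL_METHODS,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Apply each interaction test to every unordered SNP pair.

    Adjustment is within method over the non-degenerate pairs; degenerate
    pairs stay in the output with a flag and are excluded from the
    adjustment denominator.  The scan never aborts on a bad pair.
    """
    if ds.n_snps < 2:
        raise ValueError("need at least 2 SNPs to scan")
    if correction not in CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}")
    rows = []
    for i, j in combinations(range(ds.n_snps), 2):
        try:
            pc = pair_counts(ds, i, j)
        except DegenerateInputError as exc:
            for m in methods:
                rows.append({
                    "snp_i": ds.snp_ids[i], "snp_j": ds.snp_ids[j],
                    "method": m, "statistic": np.nan, "df1": np.nan,
                    "df2": np.nan, "p_value": np.nan, "flags": str(exc),
                })
            continue
        for m in methods:
            res = run_test(m, pc)
            df = tuple(res.df) + (np.nan,) * (2 - len(res.df))
            rows.append({
                "snp_i": ds.snp_ids[i], "snp_j": ds.snp_ids[j],
                "method": m, "statistic": res.statistic,
                "df1": df[0], "df2": df[1], "p_value": res.p_value,
                "flags": ";".join(res.flags) if res.flags else "",
            })
    out = pd.DataFrame(rows)
    out["p_adjusted"] = np.nan
    for m in methods:
        sel = out["method"] == m
        out.loc[sel, "p_adjusted"] = adjust_pvalues(
            out.loc[sel, "p_value"].to_numpy(), correction
        )
    out["significant"] = out["p_adjusted"] < alpha
    return out
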
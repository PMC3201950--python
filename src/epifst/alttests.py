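"""Comparison interaction tests: Pearson chi-square, mutual information, LD r².

All three operate on the same 3x3x2 genotype-pair count tensor as the Fst
test.  The mutual-information statistic 2n*MI (natural log) is identical to
the likelihood-ratio G statistic on the 9-genotype-class x status table and
is referred to chi-square with (9-1)(2-1) = 8 degrees of freedom.  The LD
test is the classic case-only statistic: under the null of unlinked,
non-interacting loci the case group shows no linkage disequilibrium, so
N * r-squared (N = subjects in the group — each subject's second gamete is
determined by its first, so gametes do not count double) is chi-square(1).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .data import DegenerateInputError, PairCounts, TestResult
from .em import HaplotypeFreqs, em_haplotype_freqs

MI_DF = 8  # (9 genotype classes - 1) x (2 statuses - 1)


def mutual_information(table: np.ndarray) -> float:
    """Plug-in mutual information (nats) of a 2-D count or probability table.

    Cells with zero joint probability contribute nothing.
    """
    t = np.asarray(table, dtype=float)
    if t.sum() <= 0:
        raise ValueError("empty table")
    p = t / t.sum()
    p1 = p.sum(axis=1, keepdims=True)
    p2 = p.sum(axis=0, keepdims=True)
    mask = p > 0
    mi = float((p[mask] * np.log(p[mask] / (p1 @ p2)[mask])).sum())
    return max(mi, 0.0)


def mi_test(pc: PairCounts, df_mode: str = "fixed") -> TestResult:
    """Mutual-information interaction test: 2n*MI vs chi-square(8).

    ``df_mode="fixed"`` keeps df = 8 regardless of empty genotype classes;
    ``"observed"`` uses (non-empty classes - 1) for sparse-data sensitivity
    analyses.
    """
    table = pc.as_9x2()
    n = pc.n_subjects
    stat = 2 * n * mutual_information(table)
    if df_mode == "fixed":
        df = MI_DF
    elif df_mode == "observed":
        df = max(int((table.sum(axis=1) > 0).sum()) - 1, 1)
    else:
        raise ValueError(f"unknown df_mode {df_mode!r}")
    p = float(stats.chi2.sf(stat, df))
    return TestResult(method="mi", statistic=float(stat), df=(df,), p_value=p)


def pearson_chisq_test(pc: PairCounts) -> TestResult:
    """Pearson chi-square on the 9-genotype-class x status table.

    Genotype classes unobserved in both groups are dropped; df is then
    (non-empty classes - 1) x 1.
    """
    table = pc.as_9x2()
    table = table[table.sum(axis=1) > 0]
    if table.shape[0] < 2:
        return TestResult(
            method="chisq", statistic=np.nan, df=(0,), p_value=np.nan,
            flags=["degenerate: single genotype class"],
        )
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(
        method="chisq", statistic=float(stat), df=(int(df),), p_value=float(p)
    )


def r_squared(h: HaplotypeFreqs) -> float:
    """LD measure r² = D² / (p_A p_a p_B p_b) of a gamete pool."""
    denom = h.p_A * (1 - h.p_A) * h.p_B * (1 - h.p_B)
    if denom <= 0:
        raise DegenerateInputError("r² undefined: monomorphic locus")
    return min(h.D ** 2 / denom, 1.0)


def ld_test(pc: PairCounts, group: str = "case") -> TestResult:
    """Case-only (or control-only / pooled) LD interaction test, N*r² ~ chi²(1).

    N is the number of subjects in the selected group: of a subject's two
    gametes, one determines the other, so the effective sample for r² is the
    subject count, not the gamete count.
    """
    if group == "case":
        table, n = pc.group_table(1), pc.n_cases
    elif group == "control":
        table, n = pc.group_table(0), pc.n_controls
    elif group == "all":
        table, n = pc.pooled_table(), pc.n_subjects
    else:
        raise ValueError(f"unknown group {group!r}")
    h, _, _ = em_haplotype_freqs(table)
    try:
        r2 = r_squared(h)
    except DegenerateInputError as exc:
        return TestResult(
            method="ld", statistic=np.nan, df=(1,), p_value=np.nan,
            flags=[f"degenerate: {exc}"],
        )
    stat = n * r2
    return TestResult(
        method="ld", statistic=float(stat), df=(1,),
        p_value=float(stats.chi2.sf(stat, 1)),
    )
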
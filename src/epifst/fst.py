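"""Two-locus fixation-index (Fst) interaction test.

The test treats cases and controls as two subpopulations diverged from a
common ancestral pool and asks whether their two-locus gamete frequencies
differ — the classical population-differentiation question, posed on the
case/control split.  Writing X = (X_A, X_B) for the pair of allele
indicators of a gamete, the null hypothesis "equal gamete frequencies in
the two groups" is exactly a two-group MANOVA hypothesis on the mean of X,
and the two-locus Fst is the Wilks' lambda ratio

    Lambda = det(SSW) / det(SSW + SSB),

where SSW and SSB are the 2x2 within- and between-group sums of squares and
cross products of X over the pooled gamete sample.  Group moments come from
EM-estimated gamete frequencies (unphased genotypes carry no direct gamete
counts), with gamete sample sizes n_i = 2 x subjects.

For k = 2 indicator variables and m = 2 groups the exact Wilks-to-F
transform is

    F = (1 - sqrt(Lambda)) / sqrt(Lambda) * (n - 3)   ~   F(2, 2(n - 3))

under the null, with n the total number of gametes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import DegenerateInputError, PairCounts, TestResult
from .em import (
    GroupMoments,
    HaplotypeFreqs,
    em_haplotype_freqs,
    moments_from_h,
)

K_VARIABLES = 2   # two allele indicators per gamete
M_GROUPS = 2      # case and control


@dataclass
class ScatterMatrices:
    """Within/between sums of squares and cross products of the indicators."""

    ssw: np.ndarray
    ssb: np.ndarray
    df_w: int   # n0 + n1 - 2 gametes
    df_b: int   # m - 1 = 1

    def __post_init__(self) -> None:
        self.ssw = np.asarray(self.ssw, dtype=float)
        self.ssb = np.asarray(self.ssb, dtype=float)
        for name, m in (("ssw", self.ssw), ("ssb", self.ssb)):
            if m.shape != (2, 2) or not np.allclose(m, m.T, atol=1e-8):
                raise ValueError(f"{name} must be symmetric 2x2")

    @property
    def total(self) -> np.ndarray:
        return self.ssw + self.ssb


@dataclass
class FstResult:
    """Full output of the Fst interaction test on one SNP pair."""

    lambda_: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    h_control: HaplotypeFreqs | None = None
    h_case: HaplotypeFreqs | None = None
    scatter: ScatterMatrices | None = None
    flags: list[str] | None = None

    def as_test_result(self) -> TestResult:
        return TestResult(
            method="fst",
            statistic=self.f_stat,
            df=self.df,
            p_value=self.p_value,
            flags=list(self.flags or []),
        )


def scatter_matrices(m0: GroupMoments, m1: GroupMoments) -> ScatterMatrices:
    """SSW and SSB from the per-group indicator moments.

    SSW = n0 Sigma0 + n1 Sigma1 (group covariance matrices scaled by gamete
    counts); SSB = sum_i n_i (mu_i - mu_t)(mu_i - mu_t)^T about the pooled
    mean.  By construction SSW + SSB equals the total scatter about the
    grand mean, the MANOVA decomposition identity.
    """
    for m in (m0, m1):
        if m.n_gametes < 4:
            raise DegenerateInputError("need at least 4 gametes per group")
    n0, n1 = m0.n_gametes, m1.n_gametes
    ssw = n0 * m0.covariance_matrix() + n1 * m1.covariance_matrix()
    mu_t = (n0 * m0.mu + n1 * m1.mu) / (n0 + n1)
    d0, d1 = m0.mu - mu_t, m1.mu - mu_t
    ssb = n0 * np.outer(d0, d0) + n1 * np.outer(d1, d1)
    total = ssw + ssb
    if np.isclose(total[0, 0], 0.0) or np.isclose(total[1, 1], 0.0):
        raise DegenerateInputError(
            "locus monomorphic in both groups: total scatter is singular"
        )
    return ScatterMatrices(ssw=ssw, ssb=ssb, df_w=n0 + n1 - 2, df_b=1)


def pooled_total_scatter(
    pooled_counts: np.ndarray, n_gametes: int
) -> np.ndarray:
    """Alternative total scatter n * Sigma_t from a pooled EM run.

    Differs from SSW + SSB only in the off-diagonal: the pooled-EM gametic
    disequilibrium is not the mean-decomposed one, so the MANOVA identity
    holds only approximately under this convention.
    """
    h_t, _, _ = em_haplotype_freqs(pooled_counts)
    m_t = moments_from_h(h_t, n_gametes)
    return n_gametes * m_t.covariance_matrix()


def wilks_lambda(s: ScatterMatrices, total: np.ndarray | None = None) -> float:
    """Wilks' lambda det(SSW)/det(SSW + SSB) — the two-locus Fst statistic."""
    tot = s.total if total is None else np.asarray(total, dtype=float)
    det_tot = float(np.linalg.det(tot))
    if det_tot <= 0:
        raise DegenerateInputError("singular total scatter matrix")
    lam = float(np.linalg.det(s.ssw)) / det_tot
    if lam <= 0:
        raise DegenerateInputError("singular within-group scatter matrix")
    return min(lam, 1.0)


def fst_f_transform(lambda_: float, n_gametes: int) -> tuple[float, int, int]:
    """Exact F transform of Wilks' lambda for k = 2 variables, m = 2 groups.

    Returns (F, df1, df2) with F = (1 - sqrt(L))/sqrt(L) * (n - 3) and
    df = (2, 2(n - 3)), n = total gametes.
    """
    if not 0.0 < lambda_ <= 1.0:
        raise ValueError(f"lambda must be in (0, 1], got {lambda_}")
    if n_gametes <= 3:
        raise ValueError("need more than 3 gametes")
    root = np.sqrt(lambda_)
    f_stat = (1.0 - root) / root * (n_gametes - 3)
    return float(f_stat), 2, 2 * (n_gametes - 3)


def fst_test(pc: PairCounts, pooled_em: bool = False) -> FstResult:
    """Run the full Fst interaction test on one genotype-pair table.

    EM is run separately within controls and cases (the statistic compares
    group-specific gamete pools); moments use gamete counts n_i = 2 x group
    subjects.  With ``pooled_em=True`` the total scatter is n * Sigma_t from
    an EM fit to the pooled table instead of SSW + SSB.
    """
    n0, n1 = 2 * pc.n_controls, 2 * pc.n_cases
    n = n0 + n1
    try:
        h0, _, _ = em_haplotype_freqs(pc.group_table(0))
        h1, _, _ = em_haplotype_freqs(pc.group_table(1))
        m0 = moments_from_h(h0, n0)
        m1 = moments_from_h(h1, n1)
        s = scatter_matrices(m0, m1)
        total = pooled_total_scatter(pc.pooled_table(), n) if pooled_em else None
        lam = wilks_lambda(s, total)
        f_stat, df1, df2 = fst_f_transform(lam, n)
    except DegenerateInputError as exc:
        return FstResult(
            lambda_=np.nan, f_stat=np.nan, df=(2, 2 * (n - 3)),
            p_value=np.nan, flags=[f"degenerate: {exc}"],
        )
    p = float(stats.f.sf(f_stat, df1, df2))
    return FstResult(
        lambda_=lam, f_stat=f_stat, df=(df1, df2), p_value=p,
        h_control=h0, h_case=h1, scatter=s, flags=[],
    )
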
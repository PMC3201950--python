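"""Synthetic case-control genotype generators.

Two generators back the calibration and power studies:

* :func:`simulate_null_dataset` — two independent Hardy-Weinberg SNPs with
  minor-allele frequencies drawn uniformly (default U(0.1, 0.4)) and a
  random half of subjects labelled cases.  Status carries no signal, so
  every interaction statistic is exactly null-distributed.
* :func:`simulate_case_control` — retrospective sampling from a two-locus
  penetrance model.  Disease risk is baseline times a relative risk acting
  only through the interaction coding x1(g1) * x2(g2) (dominant, additive
  or recessive at both loci); cases are drawn from P(g | case) and controls
  from P(g | control) by Bayes' rule against the population prevalence.

Replicate seeds derive from a master seed through ``numpy.random
.SeedSequence(master, replicate)``, so replicates are independent and
order-insensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd

from .data import GenotypeDataset

logger = logging.getLogger("epifst")

DEFAULT_MAF_LOW = 0.1
DEFAULT_MAF_HIGH = 0.4
DEFAULT_PREVALENCE = 0.01

_CODINGS = {
    "dominant": lambda d: (d >= 1).astype(float),
    "additive": lambda d: d / 2.0,
    "recessive": lambda d: (d == 2).astype(float),
}


def rng_for(master_seed: int, *stream: int) -> np.random.Generator:
    """Counter-based per-stream generator derived from a master seed."""
    return np.random.default_rng(np.random.SeedSequence((master_seed, *stream)))


def hwe_probs(p: float) -> np.ndarray:
    """Genotype probabilities (q^2, 2pq, p^2) for dosage 0/1/2 of allele p."""
    q = 1.0 - p
    return np.array([q * q, 2 * p * q, p * p])


@dataclass
class SimulationConfig:
    """Shared knobs of the Monte-Carlo studies."""

    n_cases: int = 500
    n_controls: int = 500
    replicates: int = 1000
    alpha: float = 0.05
    master_seed: int = 0
    maf_low: float = DEFAULT_MAF_LOW
    maf_high: float = DEFAULT_MAF_HIGH

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0 or self.replicates <= 0:
            raise ValueError("counts and replicates must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")


@dataclass
class DiseaseModel:
    """Two-locus interaction-only penetrance model.

    Penetrance(g1, g2) = f0 * exp(ln_rr * x1(g1) * x2(g2)) with the coding
    x shared by both loci (dominant: carrier indicator; additive: dosage/2;
    recessive: homozygote indicator).  The baseline f0 is solved so the
    HWE-weighted mean penetrance equals the prevalence.
    """

    model: str
    f_A: float
    f_B: float
    ln_rr: float
    prevalence: float = DEFAULT_PREVALENCE
    f0: float = field(init=False)
    penetrance: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.model not in _CODINGS:
            raise ValueError(f"unknown model {self.model!r}; choose {sorted(_CODINGS)}")
        if not (0.0 < self.f_A < 1.0 and 0.0 < self.f_B < 1.0):
            raise ValueError("disease allele frequencies must be in (0, 1)")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        coding = _CODINGS[self.model]
        dos = np.arange(3, dtype=float)
        x1 = coding(dos)[:, None]
        x2 = coding(dos)[None, :]
        risk = np.exp(self.ln_rr * x1 * x2)
        hwe = self.genotype_probs_hwe()
        self.f0 = self.prevalence / float((hwe * risk).sum())
        self.penetrance = self.f0 * risk
        if self.penetrance.max() > 1.0:
            raise ValueError(
                f"infeasible model: max penetrance {self.penetrance.max():.4g} "
                "> 1 (baseline * exp(ln_rr) exceeds certainty)"
            )

    def genotype_probs_hwe(self) -> np.ndarray:
        """3x3 population genotype-pair probabilities under HWE + independence."""
        return np.outer(hwe_probs(self.f_A), hwe_probs(self.f_B))

    def conditional_probs(self) -> tuple[np.ndarray, np.ndarray]:
        """(P(g | case), P(g | control)) as 3x3 tables (Bayes' rule)."""
        hwe = self.genotype_probs_hwe()
        p_case = hwe * self.penetrance
        p_ctrl = hwe * (1.0 - self.penetrance)
        return p_case / p_case.sum(), p_ctrl / p_ctrl.sum()


def simulate_null_dataset(
    n_subjects: int,
    maf_low: float = DEFAULT_MAF_LOW,
    maf_high: float = DEFAULT_MAF_HIGH,
    seed: int | np.random.Generator = 0,
    n_snps: int = 2,
) -> GenotypeDataset:
    """Status-free null data: independent HWE SNPs, half the subjects cases.

    MAFs are drawn once per SNP from U(maf_low, maf_high); case labels are
    assigned to a random half by permutation (controls get the extra subject
    when ``n_subjects`` is odd).
    """
    if not 0.0 < maf_low <= maf_high <= 0.5:
        raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_subjects % 2:
        logger.info("odd n_subjects=%d: controls get the extra subject", n_subjects)
    mafs = rng.uniform(maf_low, maf_high, size=n_snps)
    geno = np.column_stack([
        rng.choice(3, size=n_subjects, p=hwe_probs(m)) for m in mafs
    ]).astype(float)
    status = np.zeros(n_subjects, dtype=np.int8)
    status[rng.permutation(n_subjects)[: n_subjects // 2]] = 1
    ids = [f"snp{k + 1}" for k in range(n_snps)]
    return GenotypeDataset(ids, geno, status)


def penetrance_table(
    model: str,
    f_A: float,
    f_B: float,
    ln_rr: float,
    prevalence: float = DEFAULT_PREVALENCE,
) -> DiseaseModel:
    """Solve the baseline penetrance and return the full disease model."""
    return DiseaseModel(model=model, f_A=f_A, f_B=f_B, ln_rr=ln_rr,
                        prevalence=prevalence)


def simulate_case_control(
    dm: DiseaseModel,
    n_cases: int = 500,
    n_controls: int = 500,
    seed: int | np.random.Generator = 0,
    n_null_snps: int = 0,
    maf_low: float = DEFAULT_MAF_LOW,
    maf_high: float = DEFAULT_MAF_HIGH,
) -> GenotypeDataset:
    """Retrospective case-control sample from a two-locus penetrance model.

    Genotype pairs are drawn by exact categorical sampling from the
    conditional distributions P(g | case) and P(g | control); optional
    independent HWE null SNPs are appended (emulating marker panels in
    which only the first two loci are functional).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_case, p_ctrl = dm.conditional_probs()
    n = n_cases + n_controls
    cells_case = rng.choice(9, size=n_cases, p=p_case.ravel())
    cells_ctrl = rng.choice(9, size=n_controls, p=p_ctrl.ravel())
    cells = np.concatenate([cells_case, cells_ctrl])
    geno = np.column_stack([cells // 3, cells % 3]).astype(float)
    status = np.concatenate([
        np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)
    ])
    ids = ["g1", "g2"]
    if n_null_snps > 0:
        mafs = rng.uniform(maf_low, maf_high, size=n_null_snps)
        extra = np.column_stack([
            rng.choice(3, size=n, p=hwe_probs(m)) for m in mafs
        ]).astype(float)
        geno = np.hstack([geno, extra])
        ids += [f"null{k + 1}" for k in range(n_null_snps)]
    return GenotypeDataset(ids, geno, status)


def sample_pair_counts_null(
    n_subjects: int, maf_low: float, maf_high: float, rng: np.random.Generator
) -> np.ndarray:
    """Fast path: 3x3x2 null counts without materialising subjects.

    Distributionally identical to tabulating :func:`simulate_null_dataset`
    output: genotype pairs are iid across subjects and independent of the
    randomly permuted status, so each group's 3x3 table is multinomial on
    the HWE cell probabilities.
    """
    pA, pB = rng.uniform(maf_low, maf_high, size=2)
    probs = np.outer(hwe_probs(pA), hwe_probs(pB)).ravel()
    n_cases = n_subjects // 2
    counts = np.empty((3, 3, 2), dtype=np.int64)
    counts[:, :, 0] = rng.multinomial(n_subjects - n_cases, probs).reshape(3, 3)
    counts[:, :, 1] = rng.multinomial(n_cases, probs).reshape(3, 3)
    return counts


def sample_pair_counts_cc(
    dm: DiseaseModel, n_cases: int, n_controls: int, rng: np.random.Generator
) -> np.ndarray:
    """Fast path: 3x3x2 counts for the functional pair under a disease model."""
    p_case, p_ctrl = dm.conditional_probs()
    counts = np.empty((3, 3, 2), dtype=np.int64)
    counts[:, :, 0] = rng.multinomial(n_controls, p_ctrl.ravel()).reshape(3, 3)
    counts[:, :, 1] = rng.multinomial(n_cases, p_case.ravel()).reshape(3, 3)
    return counts


def covariance_asymptotics_check(
    n_grid: list[int] | None = None,
    reps: int = 2000,
    seed: int = 0,
    h: np.ndarray | None = None,
) -> pd.DataFrame:
    """Compare the discrete-sampling covariance of the allele-frequency
    vector with its normal-theory counterpart across gamete sample sizes.

    For each n, draws ``reps`` multinomial gamete samples of size n from
    the gamete distribution ``h``, computes the empirical sampling
    covariance of the estimated mean vector (mu_A, mu_B), and compares it
    elementwise with the normal-theory matrix Sigma / n (Sigma the true
    indicator covariance).  The absolute differences shrink as n grows,
    which is the empirical content of the normal approximation the MANOVA
    formulation relies on.
    """
    if n_grid is None:
        n_grid = [100, 1000, 10000]
    if h is None:
        h = np.array([0.25, 0.25, 0.25, 0.25])
    h = np.asarray(h, dtype=float)
    # mean vector is linear in the gamete proportions: mu = M h
    M = np.array([[1.0, 1.0, 0.0, 0.0], [1.0, 0.0, 1.0, 0.0]])
    mu = M @ h
    sigma = M @ (np.diag(h) - np.outer(h, h)) @ M.T
    rows = []
    for idx, n in enumerate(n_grid):
        rng = rng_for(seed, idx)
        props = rng.multinomial(n, h, size=reps) / n
        mus = props @ M.T
        emp = np.cov(mus, rowvar=False)
        theory = sigma / n
        diff = np.abs(emp - theory)
        rows.append({
            "n": n,
            "max_abs_diff": float(diff.max()),
            "emp_var_A": float(emp[0, 0]),
            "emp_var_B": float(emp[1, 1]),
            "emp_cov_AB": float(emp[0, 1]),
            "theory_var_A": float(theory[0, 0]),
            "theory_var_B": float(theory[1, 1]),
            "theory_cov_AB": float(theory[0, 1]),
        })
    return pd.DataFrame(rows)


def exact_multinomial_mean_cov(h: np.ndarray, n: int) -> np.ndarray:
    """Exact covariance of (mu_A-hat, mu_B-hat) under multinomial sampling.

    Independent oracle for :func:`covariance_asymptotics_check`: since the
    mean vector is linear in the sampled gamete proportions, its exact
    covariance is M (diag(h) - h h^T) M^T / n.
    """
    h = np.asarray(h, dtype=float)
    M = np.array([[1.0, 1.0, 0.0, 0.0], [1.0, 0.0, 1.0, 0.0]])
    return M @ (np.diag(h) - np.outer(h, h)) @ M.T / n
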
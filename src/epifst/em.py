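"""EM estimation of two-locus gamete (haplotype) frequencies.

A diploid subject genotyped at two biallelic loci carries two gametes, each
one of AB, Ab, aB, ab (uppercase = allele counted by the dosage).  Every
genotype-pair cell determines its two gametes except the double
heterozygote (1, 1), which is either AB/ab or Ab/aB.  The EM algorithm
splits that cell between the two phase configurations in proportion
h_AB*h_ab : h_Ab*h_aB (E-step) and re-counts gametes (M-step), converging to
the maximum-likelihood gamete-frequency vector h = (h_AB, h_Ab, h_aB, h_ab)
under random union of gametes.

From h the allele-indicator moments follow directly: the indicator of
carrying the counted allele at a locus is Bernoulli, so mu_A = h_AB + h_Ab,
sigma2_A = mu_A (1 - mu_A), and the indicator covariance equals the gametic
disequilibrium D = h_AB - mu_A mu_B.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 1000

# genotype cell (g1, g2) -> fixed gamete counts (AB, Ab, aB, ab); the double
# heterozygote (1, 1) is handled separately.
_PHASE_KNOWN = {
    (2, 2): (2, 0, 0, 0), (2, 1): (1, 1, 0, 0), (2, 0): (0, 2, 0, 0),
    (1, 2): (1, 0, 1, 0), (1, 0): (0, 1, 0, 1),
    (0, 2): (0, 0, 2, 0), (0, 1): (0, 0, 1, 1), (0, 0): (0, 0, 0, 2),
}


@dataclass
class HaplotypeFreqs:
    """Gamete-frequency vector (h_AB, h_Ab, h_aB, h_ab); sums to 1."""

    h_AB: float
    h_Ab: float
    h_aB: float
    h_ab: float
    monomorphic: bool = False

    def __post_init__(self) -> None:
        h = self.as_array()
        if (h < -1e-12).any() or (h > 1 + 1e-12).any():
            raise ValueError(f"haplotype frequencies outside [0,1]: {h}")
        if abs(h.sum() - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {h.sum()}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.h_AB, self.h_Ab, self.h_aB, self.h_ab])

    @property
    def p_A(self) -> float:
        return self.h_AB + self.h_Ab

    @property
    def p_B(self) -> float:
        return self.h_AB + self.h_aB

    @property
    def D(self) -> float:
        """Gametic disequilibrium h_AB - p_A p_B."""
        return self.h_AB - self.p_A * self.p_B


@dataclass
class GroupMoments:
    """Allele-indicator moments of one group's gamete pool."""

    mu: np.ndarray          # (mu_A, mu_B): allele frequencies
    sigma2: np.ndarray      # Bernoulli variances mu (1 - mu)
    cov_AB: float           # indicator covariance = gametic disequilibrium D
    n_gametes: int          # 2 x subjects

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if not ((self.mu >= -1e-12) & (self.mu <= 1 + 1e-12)).all():
            raise ValueError(f"allele frequencies outside [0,1]: {self.mu}")
        if not np.allclose(self.sigma2, self.mu * (1 - self.mu), atol=1e-12):
            raise ValueError("sigma2 must equal mu(1-mu) for indicators")
        bound = np.sqrt(self.sigma2[0] * self.sigma2[1])
        if abs(self.cov_AB) > bound + 1e-12:
            raise ValueError(f"|cov| {self.cov_AB} exceeds sqrt(var product)")

    def covariance_matrix(self) -> np.ndarray:
        """2x2 indicator covariance matrix Sigma-hat."""
        return np.array([
            [self.sigma2[0], self.cov_AB],
            [self.cov_AB, self.sigma2[1]],
        ])


def genotype_probs(h: np.ndarray) -> np.ndarray:
    """3x3 genotype-pair probabilities under random union of gametes."""
    hAB, hAb, haB, hab = h
    p = np.empty((3, 3))
    p[2, 2] = hAB ** 2
    p[2, 1] = 2 * hAB * hAb
    p[2, 0] = hAb ** 2
    p[1, 2] = 2 * hAB * haB
    p[1, 1] = 2 * hAB * hab + 2 * hAb * haB
    p[1, 0] = 2 * hAb * hab
    p[0, 2] = haB ** 2
    p[0, 1] = 2 * haB * hab
    p[0, 0] = hab ** 2
    return p


def genotype_loglik(counts: np.ndarray, h: np.ndarray) -> float:
    """Multinomial log-likelihood of a 3x3 genotype table given h."""
    p = genotype_probs(np.asarray(h, dtype=float))
    mask = counts > 0
    if (p[mask] <= 0).any():
        return -np.inf
    return float((counts[mask] * np.log(p[mask])).sum())


def _allele_freqs(counts: np.ndarray) -> tuple[float, float]:
    tot = 2 * counts.sum()
    dos = np.arange(3)
    p_a = (counts.sum(axis=1) * dos).sum() / tot
    p_b = (counts.sum(axis=0) * dos).sum() / tot
    return float(p_a), float(p_b)


def em_haplotype_freqs(
    counts: np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    n_restarts: int = 0,
    seed: int | None = None,
) -> tuple[HaplotypeFreqs, float, int]:
    """Maximum-likelihood gamete frequencies from a 3x3 genotype table.

    Parameters
    ----------
    counts
        3x3 table, ``counts[g1, g2]`` = subjects with dosages (g1, g2).
    tol
        Convergence threshold on max |delta h| between iterations.
    max_iter
        Iteration cap.
    n_restarts
        Extra EM runs from random simplex starts; the best log-likelihood
        wins.  The default linkage-equilibrium start (outer product of the
        observed allele frequencies) is phase-neutral and suffices in
        practice; restarts guard against pathological multimodality.
    seed
        Seed for the restart starting points.

    Returns
    -------
    (HaplotypeFreqs, log-likelihood, iterations of the winning run)
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (3, 3):
        raise ValueError("counts must be a 3x3 genotype table")
    if counts.sum() < 1:
        raise ValueError("empty genotype table")
    if (counts < 0).any():
        raise ValueError("negative genotype counts")
    if tol <= 0:
        raise ValueError("tol must be positive")

    p_a, p_b = _allele_freqs(counts)
    starts = [np.array([p_a * p_b, p_a * (1 - p_b),
                        (1 - p_a) * p_b, (1 - p_a) * (1 - p_b)])]
    if n_restarts > 0:
        rng = np.random.default_rng(seed)
        starts += list(rng.dirichlet(np.ones(4), size=n_restarts))

    best: tuple[np.ndarray, float, int] | None = None
    for h0 in starts:
        h, ll, its = _em_run(counts, h0, tol, max_iter)
        if best is None or ll > best[1]:
            best = (h, ll, its)
    h, ll, its = best
    mono = p_a in (0.0, 1.0) or p_b in (0.0, 1.0)
    freqs = HaplotypeFreqs(*np.clip(h, 0.0, 1.0), monomorphic=mono)
    return freqs, ll, its


def _em_run(counts, h0, tol, max_iter):
    tot_gametes = 2 * counts.sum()
    base = np.zeros(4)
    for (g1, g2), gam in _PHASE_KNOWN.items():
        base += counts[g1, g2] * np.array(gam, dtype=float)
    n_dh = counts[1, 1]

    h = np.asarray(h0, dtype=float)
    if n_dh == 0:
        # phase-unambiguous: gamete counting is already the MLE
        h = base / tot_gametes
        return h, genotype_loglik(counts, h), 1

    iterations = 0
    for iterations in range(1, max_iter + 1):
        denom = h[0] * h[3] + h[1] * h[2]
        w = 0.5 if denom <= 0 else h[0] * h[3] / denom
        h_new = base + n_dh * np.array([w, 1 - w, 1 - w, w])
        h_new /= tot_gametes
        if np.max(np.abs(h_new - h)) < tol:
            h = h_new
            break
        h = h_new
    return h, genotype_loglik(counts, h), iterations


def moments_from_h(h: HaplotypeFreqs, n_gametes: int) -> GroupMoments:
    """Allele-indicator moments of a gamete pool with frequencies ``h``."""
    if n_gametes < 2:
        raise ValueError("need at least 2 gametes")
    mu = np.array([h.p_A, h.p_B])
    return GroupMoments(
        mu=mu,
        sigma2=mu * (1 - mu),
        cov_AB=h.D,
        n_gametes=int(n_gametes),
    )
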
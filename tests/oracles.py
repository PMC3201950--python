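"""Independent reference implementations used only by the test suite.

Each oracle reaches the target quantity by a different route than the
package (enumeration, brute-force search, closed forms), so agreement is
evidence of correctness rather than repetition.
"""

from __future__ import annotations

import itertools

import numpy as np

GAMETES = np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=float)  # AB Ab aB ab


def loglik_many(counts: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Genotype log-likelihood for an array of candidate h vectors.

    Vectorised re-derivation of the cell probabilities under random union
    of gametes (independent of epifst.em.genotype_probs).
    """
    counts = np.asarray(counts, dtype=float)
    hAB, hAb, haB, hab = (H[:, k] for k in range(4))
    cells = np.stack([
        hab ** 2, 2 * haB * hab, haB ** 2,
        2 * hAb * hab, 2 * hAB * hab + 2 * hAb * haB, 2 * hAB * haB,
        hAb ** 2, 2 * hAB * hAb, hAB ** 2,
    ], axis=1)  # row-major (g1, g2)
    c = counts.ravel()
    mask = c > 0
    with np.errstate(divide="ignore"):
        ll = (c[mask] * np.log(cells[:, mask])).sum(axis=1)
    ll[~np.isfinite(ll)] = -np.inf
    return ll


def _simplex_grid(center: np.ndarray, half_width: float, step: float) -> np.ndarray:
    """All simplex points with first three coords on a local grid."""
    axes = []
    for c in center[:3]:
        lo = max(0.0, c - half_width)
        hi = min(1.0, c + half_width)
        axes.append(np.arange(lo, hi + step / 2, step))
    pts = np.array(list(itertools.product(*axes)))
    h4 = 1.0 - pts.sum(axis=1)
    ok = h4 >= -1e-12
    return np.column_stack([pts[ok], np.clip(h4[ok], 0.0, 1.0)])


def grid_search_mle(counts: np.ndarray, step0: float = 0.02,
                    levels: int = 5, shrink: float = 5.0) -> np.ndarray:
    """Brute-force likelihood maximization over the 3-simplex.

    Exhaustive grid at ``step0``, then repeated zoom-and-enumerate around
    the incumbent; final resolution step0 / shrink**(levels-1) ~ 3e-5.
    Entirely enumeration-based — no EM, no gradients.
    """
    counts = np.asarray(counts, dtype=float)
    center = np.full(4, 0.25)
    half, step = 1.0, step0
    best = center
    for _ in range(levels):
        H = _simplex_grid(center, half, step)
        ll = loglik_many(counts, H)
        best = H[int(np.argmax(ll))]
        center = best
        half = 2 * step
        step = step / shrink
    return best


def enumerate_gamete_moments(h: np.ndarray):
    """Mean/covariance of the indicator pair by exhaustive enumeration
    over the four gamete types weighted by h."""
    h = np.asarray(h, dtype=float)
    mu = (h[:, None] * GAMETES).sum(axis=0)
    cov = np.zeros((2, 2))
    for w, x in zip(h, GAMETES):
        d = x - mu
        cov += w * np.outer(d, d)
    return mu, cov


def scatter_by_enumeration(h0, n0, h1, n1):
    """SSW, SSB and total scatter from weighted per-gamete outer products."""
    h0, h1 = np.asarray(h0, float), np.asarray(h1, float)
    mu0, cov0 = enumerate_gamete_moments(h0)
    mu1, cov1 = enumerate_gamete_moments(h1)
    ssw = n0 * cov0 + n1 * cov1
    mu_t = (n0 * mu0 + n1 * mu1) / (n0 + n1)
    total = np.zeros((2, 2))
    for h, n in ((h0, n0), (h1, n1)):
        for w, x in zip(h, GAMETES):
            d = x - mu_t
            total += n * w * np.outer(d, d)
    return ssw, total - ssw, total


def g_statistic(table: np.ndarray) -> float:
    """Likelihood-ratio (G) statistic of independence, natural log."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    e = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    mask = t > 0
    return float(2.0 * (t[mask] * np.log(t[mask] / e[mask])).sum())


def pearson_x2(table: np.ndarray) -> tuple[float, int]:
    """Pearson X^2 and df by direct summation over non-empty rows."""
    t = np.asarray(table, dtype=float)
    t = t[t.sum(axis=1) > 0]
    e = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    return float(((t - e) ** 2 / e).sum()), (t.shape[0] - 1) * (t.shape[1] - 1)


def wilks_by_eigenvalues(ssw: np.ndarray, ssb: np.ndarray) -> float:
    """Lambda as the product of 1/(1+phi) over eigenvalues of SSW^-1 SSB."""
    phi = np.linalg.eigvals(np.linalg.solve(ssw, ssb))
    return float(np.prod(1.0 / (1.0 + phi.real)))


def flip_locus1(counts3x3: np.ndarray) -> np.ndarray:
    """Relabel alleles at locus 1 (dosage 0 <-> 2)."""
    return np.asarray(counts3x3)[::-1, :].copy()


def flip_locus2(counts3x3: np.ndarray) -> np.ndarray:
    return np.asarray(counts3x3)[:, ::-1].copy()
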
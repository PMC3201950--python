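"""Monte-Carlo type-I error, power, and null-distribution calibration.

Power is the proportion of simulated replicates whose test statistic
exceeds the theoretical critical value at level alpha (the F quantile for
the Fst test, chi-square quantiles for the others), reported with binomial
Monte-Carlo standard errors.  The calibration study collects the null
statistics themselves and checks them against their claimed asymptotic laws
(F(2, 2(n-3)), chi-square(8), chi-square(1)) with Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .alttests import ld_test, mi_test, pearson_chisq_test
from .data import PairCounts
from .fst import fst_test
from .simulate import (
    DiseaseModel,
    SimulationConfig,
    rng_for,
    sample_pair_counts_cc,
    sample_pair_counts_null,
)

ALL_METHODS = ("fst", "chisq", "mi", "ld")


def _run_method(method: str, pc: PairCounts):
    if method == "fst":
        return fst_test(pc).as_test_result()
    if method == "mi":
        return mi_test(pc)
    if method == "chisq":
        return pearson_chisq_test(pc)
    if method == "ld":
        return ld_test(pc)
    raise ValueError(f"unknown method {method!r}")


def run_test(method: str, pc: PairCounts):
    """Apply one named interaction test to a genotype-pair table."""
    return _run_method(method, pc)


@dataclass
class PowerCurve:
    """Rejection proportions along a ln(RR) grid, one column per method."""

    ln_rr_grid: list[float]
    power: pd.DataFrame          # index: ln_rr, columns: methods
    mc_se: pd.DataFrame
    config: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        out = self.power.add_prefix("power_").join(self.mc_se.add_prefix("se_"))
        out.insert(0, "ln_rr", self.ln_rr_grid)
        return out.reset_index(drop=True)

    def plot(self, path=None, title: str | None = None):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        for method in self.power.columns:
            ax.errorbar(self.ln_rr_grid, self.power[method],
                        yerr=2 * self.mc_se[method], marker="o", label=method)
        ax.set_xlabel("ln(RR) of the g1 x g2 interaction")
        ax.set_ylabel("power")
        ax.set_ylim(-0.02, 1.02)
        ax.legend()
        if title:
            ax.set_title(title)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def estimate_power(
    dm: DiseaseModel,
    cfg: SimulationConfig,
    methods: tuple[str, ...] = ALL_METHODS,
    seed_stream: int = 0,
) -> pd.DataFrame:
    """Rejection proportion of each method over ``cfg.replicates`` datasets.

    Each replicate draws the functional genotype-pair table from the
    disease model's conditional distributions (exact categorical sampling;
    distributionally identical to simulating subjects then tabulating the
    pair) and rejects when the statistic exceeds the theoretical critical
    value at ``cfg.alpha``.  Degenerate replicates (monomorphic in a group)
    count as non-rejections.
    """
    rejections = {m: 0 for m in methods}
    for rep in range(cfg.replicates):
        rng = rng_for(cfg.master_seed, seed_stream, rep)
        counts = sample_pair_counts_cc(dm, cfg.n_cases, cfg.n_controls, rng)
        pc = PairCounts(counts, "g1", "g2")
        for m in methods:
            res = _run_method(m, pc)
            if np.isfinite(res.p_value) and res.p_value < cfg.alpha:
                rejections[m] += 1
    rows = []
    for m in methods:
        p = rejections[m] / cfg.replicates
        rows.append({
            "method": m,
            "power": p,
            "mc_se": float(np.sqrt(p * (1 - p) / cfg.replicates)),
            "replicates": cfg.replicates,
        })
    return pd.DataFrame(rows)


def power_curve(
    model: str,
    f_A: float,
    f_B: float,
    ln_rr_grid: list[float],
    cfg: SimulationConfig,
    methods: tuple[str, ...] = ALL_METHODS,
    prevalence: float = 0.01,
) -> PowerCurve:
    """Power of each method at every point of a ln(RR) grid."""
    if not ln_rr_grid:
        raise ValueError("empty ln_rr grid")
    power_rows, se_rows = [], []
    for k, ln_rr in enumerate(ln_rr_grid):
        dm = DiseaseModel(model=model, f_A=f_A, f_B=f_B, ln_rr=ln_rr,
                          prevalence=prevalence)
        res = estimate_power(dm, cfg, methods, seed_stream=k)
        power_rows.append(res.set_index("method")["power"])
        se_rows.append(res.set_index("method")["mc_se"])
    return PowerCurve(
        ln_rr_grid=list(ln_rr_grid),
        power=pd.DataFrame(power_rows).reset_index(drop=True),
        mc_se=pd.DataFrame(se_rows).reset_index(drop=True),
        config={
            "model": model, "f_A": f_A, "f_B": f_B, "prevalence": prevalence,
            "n_cases": cfg.n_cases, "n_controls": cfg.n_controls,
            "replicates": cfg.replicates, "alpha": cfg.alpha,
            "master_seed": cfg.master_seed,
        },
    )


@dataclass
class CalibrationReport:
    """Null-law goodness of fit and empirical type-I error."""

    n_subjects: int
    replicates: int
    ks: pd.DataFrame             # method, ks_stat, ks_p, reference
    type1: pd.DataFrame          # method, rate, ci_low, ci_high (99% binomial)
    statistics: dict[str, np.ndarray] = field(default_factory=dict)


def null_calibration_study(
    cfg: SimulationConfig,
    reps: int = 10000,
    n_subjects: int = 1000,
    keep_statistics: bool = True,
) -> CalibrationReport:
    """Simulate null datasets and check each statistic's asymptotic law.

    Collects the F-transformed Fst statistic, 2n*MI and the case-only
    N*r-squared over ``reps`` independent null replicates; runs KS tests
    against F(2, 2(n-3)) (n = gametes), chi-square(8) and chi-square(1);
    and reports empirical type-I error at ``cfg.alpha`` for all four tests.
    """
    if reps < 100:
        raise ValueError("need at least 100 replicates")
    f_vals = np.full(reps, np.nan)
    mi_vals = np.full(reps, np.nan)
    ld_vals = np.full(reps, np.nan)
    chisq_reject = 0
    for rep in range(reps):
        rng = rng_for(cfg.master_seed, 1_000_000, rep)
        counts = sample_pair_counts_null(n_subjects, cfg.maf_low, cfg.maf_high, rng)
        pc = PairCounts(counts, "snp1", "snp2")
        fr = fst_test(pc)
        if np.isfinite(fr.f_stat):
            f_vals[rep] = fr.f_stat
        mi_vals[rep] = mi_test(pc).statistic
        lr = ld_test(pc)
        if np.isfinite(lr.statistic):
            ld_vals[rep] = lr.statistic
        cr = pearson_chisq_test(pc)
        if np.isfinite(cr.p_value) and cr.p_value < cfg.alpha:
            chisq_reject += 1

    n_gam = 2 * n_subjects
    refs = {
        "fst": (f_vals, stats.f(2, 2 * (n_gam - 3)), f"F(2, {2 * (n_gam - 3)})"),
        "mi": (mi_vals, stats.chi2(8), "chi2(8)"),
        "ld": (ld_vals, stats.chi2(1), "chi2(1)"),
    }
    ks_rows, t1_rows = [], []
    z99 = stats.norm.ppf(0.995)
    half = z99 * np.sqrt(cfg.alpha * (1 - cfg.alpha) / reps)
    for method, (vals, dist, label) in refs.items():
        ok = vals[np.isfinite(vals)]
        ks = stats.kstest(ok, dist.cdf)
        ks_rows.append({"method": method, "ks_stat": float(ks.statistic),
                        "ks_p": float(ks.pvalue), "reference": label,
                        "n_used": len(ok)})
        rate = float((ok > dist.ppf(1 - cfg.alpha)).sum() / reps)
        t1_rows.append({"method": method, "rate": rate,
                        "ci_low": cfg.alpha - half, "ci_high": cfg.alpha + half})
    t1_rows.append({"method": "chisq", "rate": chisq_reject / reps,
                    "ci_low": cfg.alpha - half, "ci_high": cfg.alpha + half})
    return CalibrationReport(
        n_subjects=n_subjects,
        replicates=reps,
        ks=pd.DataFrame(ks_rows),
        type1=pd.DataFrame(t1_rows),
        statistics=(
            {"fst": f_vals, "mi": mi_vals, "ld": ld_vals}
            if keep_statistics else {}
        ),
    )
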
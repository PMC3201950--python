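"""Core data containers and genotype I/O.

Genotypes are stored as alt-allele dosages in {0, 1, 2} (``NaN`` = missing)
for a set of biallelic SNPs, together with a binary case/control status per
subject.  Every statistic in this package consumes a :class:`PairCounts`
tensor — the 3 x 3 x 2 table of genotype-pair counts split by disease
status — so tabulation lives here, next to the readers.

The sickle-cell / alpha-thalassemia genotype counts from the Kenyan birth
cohort (2104 children, hospital-admission and severe malaria phenotypes)
ship as a built-in fixture; see :func:`table1_fixture`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("epifst")

STATUS_COLUMN = "status"
MISSING_TOKENS = {".", "", "NA", "nan", "NaN"}


class ValidationError(ValueError):
    """Input violates a dataset contract (bad status, malformed file...)."""


class DegenerateInputError(ValueError):
    """A statistic cannot be formed (monomorphic locus, empty group...)."""


@dataclass
class GenotypeDataset:
    """Subjects x SNPs dosage matrix with binary case/control labels.

    Parameters
    ----------
    snp_ids
        One identifier per SNP column.
    genotypes
        Float matrix of alt-allele dosages; entries in {0, 1, 2} or NaN.
    status
        Per-subject label, 0 = control, 1 = case.
    """

    snp_ids: list[str]
    genotypes: np.ndarray
    status: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.status = np.asarray(self.status)
        if self.genotypes.ndim != 2:
            raise ValidationError("genotypes must be a 2-D matrix")
        if self.genotypes.shape[1] != len(self.snp_ids):
            raise ValidationError(
                f"{len(self.snp_ids)} SNP ids for "
                f"{self.genotypes.shape[1]} genotype columns"
            )
        if self.genotypes.shape[0] != len(self.status):
            raise ValidationError("status length must match subject count")
        status_vals = set(np.unique(self.status).tolist())
        if not status_vals <= {0, 1}:
            raise ValidationError(
                f"status must be binary 0/1, found values {sorted(status_vals)}"
            )
        if 0 not in status_vals or 1 not in status_vals:
            raise ValidationError("need at least one case and one control")
        self.status = self.status.astype(np.int8)
        finite = self.genotypes[np.isfinite(self.genotypes)]
        if not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))]
            raise ValidationError(f"dosages must be 0/1/2/missing, found {bad[:5]}")
        for k, sid in enumerate(self.snp_ids):
            if np.isnan(self.genotypes[:, k]).all():
                logger.warning("SNP %s has no called genotypes", sid)

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int((self.status == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.status == 0).sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.snp_ids == other.snp_ids
            and np.array_equal(self.status, other.status)
            and np.array_equal(self.genotypes, other.genotypes, equal_nan=True)
        )


@dataclass
class PairCounts:
    """3 x 3 x 2 genotype-pair count tensor for one SNP pair.

    ``counts[g1, g2, y]`` is the number of subjects with dosage ``g1`` at the
    first locus, ``g2`` at the second, and status ``y`` (0 control, 1 case).
    """

    counts: np.ndarray
    snp_i: str = "locus1"
    snp_j: str = "locus2"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (3, 3, 2):
            raise ValidationError("PairCounts tensor must be 3x3x2")
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise ValidationError("counts must be integers")
        self.counts = np.round(self.counts).astype(np.int64)
        if self.n_controls == 0 or self.n_cases == 0:
            raise ValidationError("both groups must be non-empty")

    @property
    def n_controls(self) -> int:
        return int(self.counts[:, :, 0].sum())

    @property
    def n_cases(self) -> int:
        return int(self.counts[:, :, 1].sum())

    @property
    def n_subjects(self) -> int:
        return self.n_controls + self.n_cases

    def group_table(self, group: int) -> np.ndarray:
        """3x3 genotype table for one group (0 control, 1 case)."""
        return self.counts[:, :, group]

    def pooled_table(self) -> np.ndarray:
        return self.counts.sum(axis=2)

    def as_9x2(self) -> np.ndarray:
        """Flatten to the 9-genotype-class x status contingency table."""
        return self.counts.reshape(9, 2)


@dataclass
class TestResult:
    """Outcome of one interaction test on one SNP pair."""

    method: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p_value {self.p_value} outside [0, 1]")

    @property
    def degenerate(self) -> bool:
        return bool(self.flags)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _parse_dosage(token: object, path: str, line: int) -> float:
    s = str(token).strip()
    if s in MISSING_TOKENS:
        return np.nan
    try:
        v = float(s)
    except ValueError:
        raise ValidationError(f"{path}, line {line}: bad dosage {s!r}") from None
    if v not in (0.0, 1.0, 2.0):
        raise ValidationError(f"{path}, line {line}: dosage {s!r} not in 0/1/2")
    return v


def read_genotype_table(
    path: str | Path,
    format: str | None = None,
    status: Sequence[int] | str | Path | None = None,
) -> GenotypeDataset:
    """Read a genotype dataset from a delimited table or a biallelic VCF.

    The table format has a header row with a ``status`` column (0/1) and one
    column per SNP holding dosages 0/1/2 ("." or empty = missing).  For VCF
    input, per-sample status must be supplied separately, either as a
    sequence aligned with the VCF sample order or as a two-column
    ``sample<TAB>status`` file.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv",
                  ".vcf": "vcf"}.get(suffix, "tsv")
    if format == "vcf":
        return _read_vcf(path, status)
    sep = "," if format == "csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    if STATUS_COLUMN not in df.columns:
        raise ValidationError(f"{path}: no '{STATUS_COLUMN}' column in header")
    status_raw = df[STATUS_COLUMN].astype(str).str.strip()
    if not status_raw.isin(["0", "1"]).all():
        bad = status_raw[~status_raw.isin(["0", "1"])].iloc[0]
        raise ValidationError(f"{path}: non-binary status value {bad!r}")
    snp_cols = [c for c in df.columns if c != STATUS_COLUMN]
    geno = np.empty((len(df), len(snp_cols)))
    for k, col in enumerate(snp_cols):
        geno[:, k] = [
            _parse_dosage(v, str(path), i + 2) for i, v in enumerate(df[col])
        ]
    return GenotypeDataset(snp_cols, geno, status_raw.astype(int).to_numpy())


def _read_vcf(path: Path, status) -> GenotypeDataset:
    from cyvcf2 import VCF  # optional dependency, only needed for VCF input

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if status is None:
        raise ValidationError("VCF input requires per-sample status")
    if isinstance(status, (str, Path)):
        mapping = {}
        for ln, line in enumerate(Path(status).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2 or parts[1] not in ("0", "1"):
                raise ValidationError(f"{status}, line {ln}: expected 'sample 0|1'")
            mapping[parts[0]] = int(parts[1])
        try:
            status_vec = np.array([mapping[s] for s in samples])
        except KeyError as exc:
            raise ValidationError(f"no status for sample {exc}") from None
    else:
        status_vec = np.asarray(list(status))
    ids, rows = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("skipping multiallelic record %s:%s", var.CHROM, var.POS)
            continue
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        g = var.gt_types.astype(float)
        g[g == 3] = np.nan
        rows.append(g)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    if not rows:
        raise ValidationError(f"{path}: no usable biallelic records")
    return GenotypeDataset(ids, np.array(rows).T, status_vec)


def write_genotype_table(ds: GenotypeDataset, path: str | Path) -> None:
    """Write the standard TSV form (status column first, '.' for missing)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join([STATUS_COLUMN, *ds.snp_ids]) + "\n")
        for row, y in zip(ds.genotypes, ds.status):
            cells = [str(int(y))]
            cells += ["." if np.isnan(g) else str(int(g)) for g in row]
            fh.write("\t".join(cells) + "\n")


def write_results_table(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Tabulation
# ---------------------------------------------------------------------------

def pair_counts(ds: GenotypeDataset, i: int, j: int) -> PairCounts:
    """Tabulate one SNP pair into a 3x3x2 count tensor.

    Subjects missing either genotype are dropped (complete-case per pair).
    """
    if i == j:
        raise ValueError("need two distinct SNP indices")
    g1, g2 = ds.genotypes[:, i], ds.genotypes[:, j]
    keep = np.isfinite(g1) & np.isfinite(g2)
    g1k = g1[keep].astype(int)
    g2k = g2[keep].astype(int)
    yk = ds.status[keep].astype(int)
    counts = np.zeros((3, 3, 2), dtype=np.int64)
    np.add.at(counts, (g1k, g2k, yk), 1)
    for grp in (0, 1):
        if counts[:, :, grp].sum() < 2:
            raise DegenerateInputError(
                f"fewer than 2 complete-case subjects in group {grp} "
                f"for pair ({ds.snp_ids[i]}, {ds.snp_ids[j]})"
            )
    return PairCounts(counts, ds.snp_ids[i], ds.snp_ids[j])


def counts_from_flat(
    case: Sequence[int], control: Sequence[int],
    snp_i: str = "locus1", snp_j: str = "locus2",
) -> PairCounts:
    """Build PairCounts from two row-major 9-vectors (g1-major order)."""
    tensor = np.zeros((3, 3, 2), dtype=np.int64)
    tensor[:, :, 1] = np.asarray(case, dtype=np.int64).reshape(3, 3)
    tensor[:, :, 0] = np.asarray(control, dtype=np.int64).reshape(3, 3)
    return PairCounts(tensor, snp_i, snp_j)


# ---------------------------------------------------------------------------
# Malaria / hemoglobin worked-example fixture
# ---------------------------------------------------------------------------

# Kilifi (Kenya) birth cohort, 2104 children genotyped at the hemoglobin
# beta (HbS) and alpha(+)-thalassemia loci.  Locus 1 is the dosage of the
# sickle allele S (HbAA -> 0, HbAS -> 1; no HbSS children survive in the
# cohort, so that row is structurally zero).  Locus 2 is the dosage of the
# thalassemia deletion "-" (aa/aa -> 0, -a/aa -> 1, -a/-a -> 2).
_TABLE1 = {
    "malaria_admission": {
        "case": [[168, 187, 56], [6, 9, 10], [0, 0, 0]],
        "control": [[458, 680, 246], [107, 141, 36], [0, 0, 0]],
    },
    "severe_malaria": {
        "case": [[67, 53, 17], [0, 2, 5], [0, 0, 0]],
        "control": [[559, 814, 285], [113, 148, 41], [0, 0, 0]],
    },
}


def table1_fixture(phenotype: str) -> PairCounts:
    """Genotype-pair counts for the malaria worked example.

    ``phenotype`` is ``"malaria_admission"`` (hospital admission with
    malaria, 436 cases / 1668 controls) or ``"severe_malaria"`` (144 cases /
    1960 controls).  Both tables cover the same 2104 children.
    """
    try:
        entry = _TABLE1[phenotype]
    except KeyError:
        raise ValueError(
            f"unknown phenotype {phenotype!r}; choose from {sorted(_TABLE1)}"
        ) from None
    tensor = np.zeros((3, 3, 2), dtype=np.int64)
    tensor[:, :, 1] = entry["case"]
    tensor[:, :, 0] = entry["control"]
    return PairCounts(tensor, snp_i="HbS", snp_j="alpha_thal")
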
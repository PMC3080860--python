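"""Domain containers for admixed-cohort association scoring.

The conventions used throughout the package:

* Local ancestry is diploid and coded as the number of European-derived
  chromosomes an individual carries at a SNP (0 = AA, 1 = AE, 2 = EE).
* Genotypes count copies of the reference allele (0, 1 or 2).
* The integer missing code in matrix files is the literal ``9``;
  vectors use ``NA``.  Both normalise to the same internal sentinels
  (:data:`MISSING` for integer matrices, ``NaN`` for real vectors).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

#: integer missing code used in genotype / local-ancestry matrices
MISSING = 9


class Status(str, Enum):
    """Outcome flag attached to every score."""

    OK = "OK"
    MONOMORPHIC = "MONOMORPHIC"
    DEGENERATE = "DEGENERATE"
    NOT_CONVERGED = "NOT_CONVERGED"


@dataclass
class ScoreResult:
    """A single association statistic.

    Attributes
    ----------
    statistic : float
        The χ² value (non-negative whenever ``status == OK``).
    dof : int
        Degrees of freedom (1 or 2).
    p_value : float
        Upper-tail probability of χ²(dof) at ``statistic``; clamped below
        at 1e-320 for reproducible text output.
    estimates : dict
        Fitted nuisance/effect parameters, keyed by name
        (``R``, ``Omega``, ``R_A``, ``R_E``, ``p_A``, ``p_E``,
        ``eps``, ``eps_A``, ``eps_E``).
    n : int
        Number of complete-data individuals that entered the statistic.
    status : Status
    """

    statistic: float
    dof: int
    p_value: float
    estimates: dict = field(default_factory=dict)
    n: int = 0
    status: Status = Status.OK

    def __post_init__(self) -> None:
        if self.status == Status.OK and not self.statistic >= 0:
            raise ValueError(f"OK score with negative statistic {self.statistic}")


def _check_int_matrix(values: np.ndarray, what: str) -> np.ndarray:
    values = np.asarray(values)
    if values.ndim != 2:
        raise ValueError(f"{what} matrix must be 2-D, got shape {values.shape}")
    if not np.issubdtype(values.dtype, np.integer):
        raise ValueError(f"{what} matrix must be integer-valued")
    bad = ~np.isin(values, (0, 1, 2, MISSING))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{what} matrix entry ({i}, {j}) = {values[i, j]} not in {{0,1,2,{MISSING}}}"
        )
    return values


@dataclass
class GenotypeMatrix:
    """SNP × individual reference-allele counts, optionally with dosages."""

    snp_ids: list
    values: np.ndarray
    dosage: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = _check_int_matrix(self.values, "genotype")
        if len(self.snp_ids) != self.values.shape[0]:
            raise ValueError("snp_ids length does not match matrix rows")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids are not unique")
        if self.dosage is not None:
            self.dosage = np.asarray(self.dosage, dtype=float)
            if self.dosage.shape != self.values.shape:
                raise ValueError("dosage shape differs from genotype shape")
            finite = np.isfinite(self.dosage)
            if ((self.dosage[finite] < 0) | (self.dosage[finite] > 2)).any():
                raise ValueError("dosage entries must lie in [0, 2]")

    @property
    def n_snps(self) -> int:
        return self.values.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.values.shape[1]


@dataclass
class LocalAncestryMatrix:
    """SNP × individual counts of European-derived chromosomes (0/1/2)."""

    snp_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_int_matrix(self.values, "local-ancestry")
        if len(self.snp_ids) != self.values.shape[0]:
            raise ValueError("snp_ids length does not match matrix rows")

    @property
    def n_snps(self) -> int:
        return self.values.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.values.shape[1]


@dataclass
class PhenotypeVector:
    """Binary (0 = control, 1 = case) or continuous phenotype; NaN = missing."""

    ids: list
    y: np.ndarray
    kind: str = "binary"  # "binary" | "quantitative"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 1 or len(self.ids) != self.y.size:
            raise ValueError("phenotype ids and values do not align")
        if self.kind not in ("binary", "quantitative"):
            raise ValueError(f"unknown phenotype kind {self.kind!r}")
        if self.kind == "binary":
            obs = self.y[np.isfinite(self.y)]
            if not np.isin(obs, (0.0, 1.0)).all():
                raise ValueError("binary phenotype values must be 0, 1 or NA")

    def require_cases_and_controls(self) -> None:
        obs = self.y[np.isfinite(self.y)]
        if not ((obs == 1).any() and (obs == 0).any()):
            raise ValueError("binary phenotype needs at least one case and one control")


@dataclass
class GlobalAncestryVector:
    """Per-individual genome-wide European ancestry fraction θ ∈ [0, 1]."""

    ids: list
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 1 or len(self.ids) != self.theta.size:
            raise ValueError("theta ids and values do not align")
        if ((self.theta < 0) | (self.theta > 1)).any():
            bad = self.theta[(self.theta < 0) | (self.theta > 1)][0]
            raise ValueError(f"theta value {bad} outside [0, 1]")


@dataclass
class ImputationQualityTable:
    """Per-SNP ancestry-specific imputation accuracy (squared correlations)."""

    snp_ids: list
    rsq_afr: np.ndarray
    rsq_eur: np.ndarray

    def __post_init__(self) -> None:
        self.rsq_afr = np.asarray(self.rsq_afr, dtype=float)
        self.rsq_eur = np.asarray(self.rsq_eur, dtype=float)
        for name, r in (("rsq_afr", self.rsq_afr), ("rsq_eur", self.rsq_eur)):
            if r.ndim != 1 or r.size != len(self.snp_ids):
                raise ValueError(f"{name} does not align with snp_ids")
            if ((r < 0) | (r > 1)).any():
                raise ValueError(f"{name} values must lie in [0, 1]")

    def lookup(self, snp_id: str) -> tuple:
        idx = self.snp_ids.index(snp_id)
        return float(self.rsq_afr[idx]), float(self.rsq_eur[idx])


@dataclass
class StratifiedCounts:
    """Genotype counts cross-classified by local-ancestry stratum and phenotype.

    ``n[l, y, g]`` counts individuals with ``l`` European chromosomes
    (0 = AA, 1 = AE, 2 = EE), phenotype ``y`` (0 = control, 1 = case) and
    genotype ``g``; the 18-cell table is the sufficient statistic for the
    SNP1, MIX and HET likelihoods.
    """

    n: np.ndarray

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n)
        if self.n.shape != (3, 2, 3):
            raise ValueError(f"counts must have shape (3, 2, 3), got {self.n.shape}")
        if (self.n < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.n.sum())


@dataclass
class AncestryProfile:
    """Per-case genome-wide ancestry θ and locus European-allele count N.

    This is the sufficient statistic for the case-only admixture score:
    under ancestry odds ratio Ω, case ``i`` carries
    ``N_i ~ Binomial(2, q_i)`` European alleles with per-allele probability
    ``q_i(Ω) = θ_i Ω / (θ_i Ω + 1 − θ_i)``.
    """

    theta: np.ndarray
    n_eur: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.n_eur = np.asarray(self.n_eur)
        if self.theta.shape != self.n_eur.shape or self.theta.ndim != 1:
            raise ValueError("theta and n_eur must be aligned 1-D arrays")
        if ((self.theta < 0) | (self.theta > 1)).any():
            raise ValueError("theta values must lie in [0, 1]")
        if not np.isin(self.n_eur, (0, 1, 2)).all():
            raise ValueError("n_eur values must be 0, 1 or 2")

    def consistent(self) -> np.ndarray:
        """Mask of cases whose (θ, N) pair is internally consistent.

        θ = 0 forbids European alleles and θ = 1 forbids African ones;
        offending individuals are excluded from the likelihood with a warning.
        """
        return ~(((self.theta == 0) & (self.n_eur > 0))
                 | ((self.theta == 1) & (self.n_eur < 2)))

    @property
    def size(self) -> int:
        return self.theta.size


@dataclass
class GenomeAncestrySummary:
    """Genome-wide spread of per-SNP average case ancestry, for GC scores.

    The scale ``sd`` is estimated by median calibration,
    ``sqrt(median((ā − μ̄)²) / 0.454936)``, rather than the sample standard
    deviation: it is robust to contamination by true association signals
    (the same reason genomic control uses medians) and it makes the
    resulting ((ā − μ̄)/σ̂)² statistics have unit genomic-control λ exactly,
    which is what "dividing the admixture statistics by λ_GC" amounts to.
    For Gaussian ā the two estimators coincide in expectation.
    """

    abar: np.ndarray          # per-SNP mean of N/2 across cases
    mean: float               # genome-wide mean of abar
    sd: float                 # median-calibrated scale of abar across SNPs
    lambda_adm: float | None = None  # λ_GC of the raw ADM statistics, if known

    @classmethod
    def from_abar(cls, abar, lambda_adm=None) -> "GenomeAncestrySummary":
        from scipy.stats import chi2
        abar = np.asarray(abar, dtype=float)
        if abar.size < 2:
            raise ValueError("need at least 2 SNPs to form a genome summary")
        mean = float(abar.mean())
        sd = float(np.sqrt(np.median((abar - mean) ** 2) / chi2.median(1)))
        if sd == 0.0:
            sd = float(abar.std(ddof=1))
        return cls(abar=abar, mean=mean, sd=sd, lambda_adm=lambda_adm)
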
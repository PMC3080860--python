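"""Synthetic admixed cohorts and phenotypes.

The generator emulates the statistical structure of a two-way
African/European admixed GWAS cohort:

* genome-wide European ancestry θ ~ Beta, moment-matched to mean 0.192
  and SD 0.120 (the published moments for African-American cohorts);
* differentiated ancestral allele frequencies, either from a
  Balding–Nichols drift model around a shared ancestral frequency or by
  explicit construction of pairs with |p_E − p_A| ≥ Δ;
* diploid local ancestry N ∈ {0, 1, 2} European chromosomes — unlinked
  Binomial(2, θ) draws per SNP, or a two-chain Markov block model with
  exponential segment lengths for linkage-aware experiments;
* alleles drawn Bernoulli(p_E) on European and Bernoulli(p_A) on African
  background, genotype = sum;
* case-control phenotypes by weighted selection (controls uniform first,
  then cases with relative probabilities 1 : R : R² for 0/1/2 reference
  alleles under the multiplicative model), quantitative phenotypes by a
  0 : ε : 2ε mean shift plus standard normal noise, mean-centred.

Every draw is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .types import GenotypeMatrix, GlobalAncestryVector, LocalAncestryMatrix, \
    PhenotypeVector

DISEASE_MODELS = ("multiplicative", "dominant", "recessive", "two_locus")
THETA_CLIP = (0.001, 0.999)


def beta_moment_match(mean, sd):
    """(α, β) of the Beta distribution with the given mean and SD."""
    if not 0 < mean < 1:
        raise ValueError("theta mean must lie in (0, 1)")
    if sd ** 2 >= mean * (1 - mean):
        raise ValueError("theta sd too large for a Beta distribution")
    nu = mean * (1 - mean) / sd ** 2 - 1.0
    return mean * nu, (1 - mean) * nu


@dataclass
class SimulationConfig:
    """Study-condition bundle for one simulated experiment."""

    n_snps: int
    n_individuals: int = 6209
    freq_model: str = "balding_nichols"      # or "explicit_delta"
    fst: float = 0.15
    ancestral_range: tuple = (0.1, 0.9)
    delta: float = 0.4
    theta_mean: float = 0.192
    theta_sd: float = 0.120
    linkage: str = "unlinked"                # or "markov_blocks"
    generations: float = 6.0
    map_length: float = 1.0                  # Morgans spanned by the SNPs
    phenotype_model: str = "null"            # null | case_control | quantitative
    odds_ratio: float = 1.0
    disease_model: str = "multiplicative"
    effect_size: float = 0.0
    n_cases: int = 1000
    n_controls: int = 1000
    n_samples_quant: int = 2000
    seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory: every draw must be reproducible")
        if self.freq_model not in ("balding_nichols", "explicit_delta"):
            raise ValueError(f"unknown frequency model {self.freq_model!r}")
        if self.linkage not in ("unlinked", "markov_blocks"):
            raise ValueError(f"unknown linkage mode {self.linkage!r}")
        if self.phenotype_model not in ("null", "case_control", "quantitative"):
            raise ValueError(f"unknown phenotype model {self.phenotype_model!r}")
        if self.disease_model not in DISEASE_MODELS:
            raise ValueError(f"unknown disease model {self.disease_model!r}")
        if self.odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")
        if self.delta > 0.98:
            raise ValueError("requested frequency difference is infeasible")
        beta_moment_match(self.theta_mean, self.theta_sd)  # validates moments

    def to_yaml(self, path):
        d = asdict(self)
        d["ancestral_range"] = list(self.ancestral_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "ancestral_range" in d:
            d["ancestral_range"] = tuple(d["ancestral_range"])
        return cls(**d)


def _rng(seed_or_rng):
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def draw_frequencies(config, seed, n=None):
    """Per-SNP (p_A, p_E) control frequencies, clipped to [0.01, 0.99]."""
    rng = _rng(seed)
    n = config.n_snps if n is None else n
    if config.freq_model == "balding_nichols":
        lo, hi = config.ancestral_range
        p = rng.uniform(lo, hi, size=n)
        F = config.fst
        if F <= 0:
            pa = pe = p
        else:
            a = p * (1 - F) / F
            b = (1 - p) * (1 - F) / F
            pa = rng.beta(a, b)
            pe = rng.beta(a, b)
    else:
        d = config.delta
        low = rng.uniform(0.01, 0.99 - d, size=n)
        high = low + rng.uniform(d, 0.99 - low)
        swap = rng.random(n) < 0.5
        pa = np.where(swap, high, low)
        pe = np.where(swap, low, high)
    return np.clip(pa, 0.01, 0.99), np.clip(pe, 0.01, 0.99)


def draw_theta(config, seed, n=None):
    """Genome-wide ancestry fractions, Beta moment-matched and clamped."""
    rng = _rng(seed)
    n = config.n_individuals if n is None else n
    a, b = beta_moment_match(config.theta_mean, config.theta_sd)
    return np.clip(rng.beta(a, b, size=n), *THETA_CLIP)


def _draw_local_ancestry(config, theta, n_snps, rng):
    n_ind = theta.size
    if config.linkage == "unlinked":
        u = rng.random((2, n_snps, n_ind))
        return (u[0] < theta).astype(np.int8) + (u[1] < theta).astype(np.int8)
    # markov_blocks: two haploid chains per individual; ancestry switches at
    # rate G per Morgan towards the stationary mix (θ, 1−θ)
    pos = np.linspace(0.0, config.map_length, n_snps)
    N = np.empty((n_snps, n_ind), dtype=np.int8)
    chains = rng.random((2, n_ind)) < theta          # True = European
    N[0] = chains.sum(axis=0)
    for s in range(1, n_snps):
        d = pos[s] - pos[s - 1]
        stay = np.exp(-config.generations * d)
        # after an exponential waiting time the chain redraws from (θ, 1−θ)
        redraw = rng.random((2, n_ind)) >= stay
        new_state = rng.random((2, n_ind)) < theta
        chains = np.where(redraw, new_state, chains)
        N[s] = chains.sum(axis=0)
    return N


def _draw_genotypes(N, pa, pe, rng):
    """Alleles per chromosome given the local-ancestry matrix (n_snps × n_ind)."""
    n_snps, n_ind = N.shape
    p1 = np.where(N >= 1, pe[:, None], pa[:, None])
    p2 = np.where(N == 2, pe[:, None], pa[:, None])
    u = rng.random((2, n_snps, n_ind))
    return (u[0] < p1).astype(np.int8) + (u[1] < p2).astype(np.int8)


def draw_cohort(config, freqs, seed):
    """Generate (GenotypeMatrix, LocalAncestryMatrix, GlobalAncestryVector).

    θ is drawn first from the moment-matched Beta; local ancestry and
    alleles follow the model in the module docstring.
    """
    rng = _rng(seed)
    pa, pe = freqs
    n_snps = pa.size
    theta = draw_theta(config, rng)
    N = _draw_local_ancestry(config, theta, n_snps, rng)
    g = _draw_genotypes(N, pa, pe, rng)
    snp_ids = [f"snp{i + 1}" for i in range(n_snps)]
    ids = [f"ind{i + 1}" for i in range(config.n_individuals)]
    return (GenotypeMatrix(snp_ids, g),
            LocalAncestryMatrix(snp_ids, N),
            GlobalAncestryVector(ids, theta))


def disease_weights(g, odds_ratio, disease_model="multiplicative"):
    """Relative selection probabilities for prospective cases.

    multiplicative: 1 : R : R² per reference-allele count; dominant
    (1, R, R); recessive (1, 1, R); two_locus multiplies the per-locus
    multiplicative weights of two causal SNPs.
    """
    g = np.asarray(g, dtype=float)
    R = float(odds_ratio)
    if disease_model == "two_locus":
        if g.ndim != 2 or g.shape[1] != 2:
            raise ValueError("two_locus model needs an (n, 2) genotype array")
        return R ** g[:, 0] * R ** g[:, 1]
    if g.ndim != 1:
        raise ValueError("single-locus models need an (n,) genotype column")
    if disease_model == "multiplicative":
        return R ** g
    if disease_model == "dominant":
        return np.where(g > 0, R, 1.0)
    if disease_model == "recessive":
        return np.where(g == 2, R, 1.0)
    raise ValueError(f"unknown disease model {disease_model!r}")


def simulate_case_control(g, config, seed):
    """Select controls and cases from the cohort for one causal SNP.

    Controls are drawn uniformly without replacement first; cases are then
    drawn from the remainder without replacement, with probability
    proportional to the disease-model weights (exponential-sort scheme).
    Unselected individuals get a missing phenotype.
    """
    rng = _rng(seed)
    g = np.asarray(g, dtype=float)
    n = g.shape[0]
    if config.n_cases + config.n_controls > n:
        raise ValueError("pool too small for the requested cases + controls")
    u = rng.random(n)
    controls = np.argpartition(u, config.n_controls - 1)[:config.n_controls]
    w = disease_weights(g, config.odds_ratio, config.disease_model)
    keys = rng.exponential(size=n) / w
    keys[controls] = np.inf
    cases = np.argpartition(keys, config.n_cases - 1)[:config.n_cases]
    y = np.full(n, np.nan)
    y[controls] = 0.0
    y[cases] = 1.0
    ids = [f"ind{i + 1}" for i in range(n)]
    return PhenotypeVector(ids, y, kind="binary")


def simulate_quantitative(g, epsilon, seed):
    """y = ε·g + N(0, 1), then mean-centred."""
    rng = _rng(seed)
    g = np.asarray(g, dtype=float)
    y = float(epsilon) * g + rng.standard_normal(g.shape[0])
    y = y - y.mean()
    ids = [f"ind{i + 1}" for i in range(g.shape[0])]
    return PhenotypeVector(ids, y, kind="quantitative")


def emulate_imputation(g, l, rsq_afr, rsq_eur, seed):
    """Degrade true genotypes to dosages of a target ancestry-specific accuracy.

    Within each local-ancestry stratum, Gaussian noise with variance
    var(g)·(1 − r²)/r² is added so that the squared correlation between
    dosage and truth is approximately the target r² (AA uses r²_A, EE uses
    r²_E, AE their mean).  Returns (dosages clipped to [0, 2], maximum-
    likelihood integer calls, realised r² per homozygous-ancestry stratum).
    """
    rng = _rng(seed)
    g = np.asarray(g, dtype=float)
    l = np.asarray(l)
    for r in (rsq_afr, rsq_eur):
        if not 0 < r <= 1:
            raise ValueError("imputation r-squared must lie in (0, 1]")
    targets = {0: rsq_afr, 1: 0.5 * (rsq_afr + rsq_eur), 2: rsq_eur}
    dosage = g.astype(float).copy()
    for stratum, r in targets.items():
        mask = l == stratum
        if mask.sum() < 2 or r == 1.0:
            continue
        gm = g[mask]
        if gm.var() == 0:
            continue
        noise = rng.standard_normal(mask.sum())
        # clipping to [0, 2] truncates the noise and would leave the realised
        # accuracy above target, so the pre-clip scale is calibrated by
        # bisection against the post-clip squared correlation
        base = np.sqrt(gm.var() * (1.0 - r) / r)
        lo_s, hi_s = base, 4.0 * base
        scale = base
        for _ in range(30):
            scale = 0.5 * (lo_s + hi_s)
            trial = np.clip(gm + scale * noise, 0.0, 2.0)
            realized_r = np.corrcoef(gm, trial)[0, 1] ** 2
            if realized_r > r:
                lo_s = scale
            else:
                hi_s = scale
        dosage[mask] = gm + scale * noise
    dosage = np.clip(dosage, 0.0, 2.0)
    calls = np.clip(np.rint(dosage), 0, 2).astype(np.int8)
    realized = {}
    for name, stratum in (("afr", 0), ("eur", 2)):
        mask = l == stratum
        if mask.sum() > 2 and g[mask].var() > 0 and dosage[mask].var() > 0:
            realized[name] = float(np.corrcoef(g[mask], dosage[mask])[0, 1] ** 2)
        else:
            realized[name] = np.nan
    return dosage, calls, realized
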
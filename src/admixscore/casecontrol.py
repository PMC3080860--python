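"""Case-control association scores for two-way admixed cohorts.

Seven statistics are provided, all χ²-distributed under their nulls:

========  ====  =======================================================
score     dof   tests
========  ====  =======================================================
ATT        1    genotype–phenotype trend, adjusted for genome-wide θ
SNP1       1    allelic odds ratio R ≠ 1, conditioned on local ancestry
ADM        1    case-only ancestry odds ratio Ω ≠ 1
SUM        2    SNP1 + ADM (independent components)
MIX        1    joint SNP + admixture signal with Ω implied by R
HET        1    ancestry-specific odds ratios R_A ≠ R_E
ADMGC      1    ADM with genome-wide empirical variance of ancestry
MIXGC      1    MIX with the same empirically calibrated admixture term
========  ====  =======================================================

The public per-SNP functions (``score_*``) return :class:`ScoreResult`;
each is a thin wrapper over the batch engine (``*_batch``) that the
genome-wide evaluation machinery drives directly on arrays of sufficient
statistics.  The batch admixture likelihood optionally compresses case
(θ, N) profiles into θ-bins; per-SNP calls always use the exact per-case
form.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2

from . import likelihood as lk
from .types import (MISSING, AncestryProfile, GenomeAncestrySummary, ScoreResult,
                    Status, StratifiedCounts)

# status codes used inside batch arrays
_OK, _MONO, _DEGEN, _NOCONV = 0, 1, 2, 3
_STATUS = [Status.OK, Status.MONOMORPHIC, Status.DEGENERATE, Status.NOT_CONVERGED]

#: p-values are clamped here before being written to text reports
P_FLOOR = 1e-320

#: default number of θ-bins used by the batch admixture likelihood
DEFAULT_BINS = 128


def _pval(stat, dof):
    return np.maximum(chi2.sf(stat, dof), P_FLOOR)


# ---------------------------------------------------------------------------
# sufficient statistics
# ---------------------------------------------------------------------------

def tabulate_counts(g, l, y):
    """Cross-classify one SNP into the 18-cell (stratum, phenotype, genotype)
    table, excluding individuals with any missing entry pairwise."""
    g = np.asarray(g, dtype=float)
    l = np.asarray(l, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = (np.isfinite(g) & (g != MISSING)
            & np.isfinite(l) & (l != MISSING)
            & np.isfinite(y))
    gi = np.rint(g[keep]).astype(int)
    li = l[keep].astype(int)
    yi = y[keep].astype(int)
    if keep.sum() == 0:
        return StratifiedCounts(np.zeros((3, 2, 3), dtype=int))
    flat = (li * 2 + yi) * 3 + gi
    n = np.bincount(flat, minlength=18).reshape(3, 2, 3)
    return StratifiedCounts(n)


def profile_bins(theta, n_eur, n_bins=None, clamp=1e-6):
    """Compress case ancestry profiles to the sufficient pieces of the
    Ω-likelihood.

    ``theta`` and ``n_eur`` are ``(B, m)`` arrays of case genome-wide
    ancestries and locus European-allele counts.  With ``n_bins=None``
    every case is its own bin and the likelihood is exact; with
    ``n_bins=K`` cases are pooled into K equal-width θ-bins carrying their
    within-bin mean θ (first-moment matching), which is what genome-wide
    batch runs use.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    n_eur = np.atleast_2d(np.asarray(n_eur, dtype=float))
    tc = np.clip(theta, clamp, 1.0 - clamp)
    B, m = tc.shape
    sum_n = n_eur.sum(axis=1)
    if n_bins is None:
        c = np.ones((B, m))
        tbar = tc
    else:
        K = int(n_bins)
        idx = np.minimum((tc * K).astype(np.int64), K - 1)
        flat = idx + K * np.arange(B)[:, None]
        c = np.bincount(flat.ravel(), minlength=B * K).reshape(B, K).astype(float)
        st = np.bincount(flat.ravel(), weights=tc.ravel(),
                         minlength=B * K).reshape(B, K)
        tbar = np.where(c > 0, st / np.maximum(c, 1.0), 0.5)
    return {
        "c": c,
        "tbar": tbar,
        "sum_n": sum_n,
        "m": np.full(B, m, dtype=float),
        "mean_theta": tc.mean(axis=1),
        "abar": n_eur.mean(axis=1) / 2.0,
        "informative": ((theta > 0) & (theta < 1)).sum(axis=1),
    }


def _adm_part(bins, omega, rows):
    """Ω-dependent part of the case-only admixture log-likelihood.

    Equals the full log-likelihood up to an Ω-free constant, so LR
    statistics built from differences of this part are exact.  The part is
    identically 0 at Ω = 1.
    """
    c = bins["c"][rows]
    tb = bins["tbar"][rows]
    sn = bins["sum_n"][rows]
    om1 = (omega - 1.0)[:, None]
    return sn * np.log(omega) - 2.0 * np.einsum(
        "bk,bk->b", c, np.log1p(tb * om1)
    )


def _ll_counts(m, a, e):
    """Σ m·log P for one phenotype group; ``m`` is (B, 3, 3), a/e are (B,)."""
    P = lk.stratum_genotype_probs(a, e)
    return np.einsum("bij,bij->b", m, np.log(P))


def _init_freqs(m):
    """Allele-counting starting values (AE hets split half-and-half)."""
    g = np.arange(3.0)
    afr_alleles = m[:, 0, :] @ g + 0.5 * (m[:, 1, :] @ g)
    eur_alleles = m[:, 2, :] @ g + 0.5 * (m[:, 1, :] @ g)
    n_afr = 2.0 * m[:, 0, :].sum(axis=1) + m[:, 1, :].sum(axis=1)
    n_eur = 2.0 * m[:, 2, :].sum(axis=1) + m[:, 1, :].sum(axis=1)
    pa = np.where(n_afr > 0, afr_alleles / np.maximum(n_afr, 1.0), 0.5)
    pe = np.where(n_eur > 0, eur_alleles / np.maximum(n_eur, 1.0), 0.5)
    lo, hi = 0.01, 0.99
    return np.clip(pa, lo, hi), np.clip(pe, lo, hi)


def _fit_freqs(m, pa0, pe0):
    """Maximise the stratified genotype likelihood of one group over (p_A, p_E)."""
    def f(params, rows):
        return _ll_counts(m[rows], params[0], params[1])

    (pa, pe), ll, conv = lk.coordinate_ascent(
        f, [pa0, pe0], [(lk.FREQ_LO, lk.FREQ_HI)] * 2
    )
    return pa, pe, ll, conv


def _counts_status(counts):
    """Per-SNP status codes from the raw 18-cell tables."""
    total = counts.sum(axis=(1, 2, 3))
    by_g = counts.sum(axis=(1, 2))
    mono = (by_g > 0).sum(axis=1) <= 1
    n_case = counts[:, :, 1, :].sum(axis=(1, 2))
    n_ctrl = counts[:, :, 0, :].sum(axis=(1, 2))
    status = np.zeros(counts.shape[0], dtype=np.int8)
    status[mono] = _MONO
    status[(total == 0) | (n_case == 0) | (n_ctrl == 0)] = _DEGEN
    return status, total


# ---------------------------------------------------------------------------
# batch engines
# ---------------------------------------------------------------------------

def snp1_batch(counts, rsq=None):
    """SNP association conditioned on local ancestry, for a batch of tables.

    LR of the shared allelic odds ratio: 2·[max_{R,p_A,p_E} ℓ − max_{p_A,p_E} ℓ|R=1],
    1 dof.  ``rsq`` is an optional ``(rsq_afr, rsq_eur)`` pair of (B,) arrays
    attenuating the case-frequency shift at imputed SNPs.
    """
    counts = np.asarray(counts, dtype=float)
    B = counts.shape[0]
    status, total = _counts_status(counts)
    ctrl = counts[:, :, 0, :]
    case = counts[:, :, 1, :]
    comb = ctrl + case
    pa0, pe0 = _init_freqs(comb)
    # null: R = 1 makes case and control frequencies equal
    pa_n, pe_n, ll_null, conv_n = _fit_freqs(comb, pa0, pe0)

    rsq_a = rsq_e = None
    if rsq is not None:
        rsq_a = np.asarray(rsq[0], dtype=float)
        rsq_e = np.asarray(rsq[1], dtype=float)

    def f_alt(params, rows):
        r = np.exp(params[0])
        pa, pe = params[1], params[2]
        if rsq_a is None:
            qa = lk.case_frequency(pa, r)
            qe = lk.case_frequency(pe, r)
        else:
            qa = lk.attenuated_case_frequency(pa, r, rsq_a[rows])
            qe = lk.attenuated_case_frequency(pe, r, rsq_e[rows])
        return _ll_counts(ctrl[rows], pa, pe) + _ll_counts(case[rows], qa, qe)

    (logr, pa, pe), ll_alt, conv_a = lk.coordinate_ascent(
        f_alt,
        [np.zeros(B), pa_n.copy(), pe_n.copy()],
        [(lk.LOG_OR_LO, lk.LOG_OR_HI), (lk.FREQ_LO, lk.FREQ_HI), (lk.FREQ_LO, lk.FREQ_HI)],
    )
    stat = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    status[(status == _OK) & ~(conv_n & conv_a)] = _NOCONV
    stat[status == _MONO] = 0.0
    return {
        "stat": stat, "dof": 1, "p": _pval(stat, 1),
        "R": np.exp(logr), "p_A": pa, "p_E": pe,
        "null_p_A": pa_n, "null_p_E": pe_n, "ll_null": ll_null, "ll_alt": ll_alt,
        "status": status, "n": total,
    }


def adm_batch(bins):
    """Case-only admixture LR statistic 2·[ℓ(Ω̂) − ℓ(1)], 1 dof, per SNP."""
    B = bins["sum_n"].shape[0]

    def f(params, rows):
        return _adm_part(bins, np.exp(params[0]), rows)

    (logw,), part, conv = lk.coordinate_ascent(
        f, [np.zeros(B)], [(lk.LOG_OR_LO, lk.LOG_OR_HI)]
    )
    stat = np.maximum(2.0 * part, 0.0)   # the part is 0 at Ω = 1
    status = np.zeros(B, dtype=np.int8)
    status[bins["informative"] == 0] = _DEGEN
    status[(status == _OK) & ~conv] = _NOCONV
    return {"stat": stat, "dof": 1, "p": _pval(stat, 1),
            "Omega": np.exp(logw), "status": status, "n": bins["m"].astype(int)}


def sum_batch(snp1, adm):
    """χ²(2) sum of the SNP1 and ADM statistics."""
    stat = snp1["stat"] + adm["stat"]
    status = np.maximum(snp1["status"], adm["status"])
    return {"stat": stat, "dof": 2, "p": _pval(stat, 2), "status": status,
            "n": snp1["n"]}


def mix_batch(counts, bins, rsq=None, snp1=None):
    """Joint SNP + admixture LR score with Ω implied by R, 1 dof.

    The alternative maximises the SNP1 likelihood plus the admixture
    likelihood evaluated at Ω(R, p_A, p_E) over the three free parameters;
    the null is the SNP1 null (Ω(1, ·, ·) = 1).  Imputation-quality
    attenuation applies only to the genotype component: local ancestry is
    observed, not imputed.
    """
    counts = np.asarray(counts, dtype=float)
    if snp1 is None:
        snp1 = snp1_batch(counts, rsq=rsq)
    B = counts.shape[0]
    status = snp1["status"].copy()
    status[bins["informative"] == 0] = _DEGEN
    ctrl = counts[:, :, 0, :]
    case = counts[:, :, 1, :]
    rsq_a = rsq_e = None
    if rsq is not None:
        rsq_a = np.asarray(rsq[0], dtype=float)
        rsq_e = np.asarray(rsq[1], dtype=float)

    def f_alt(params, rows):
        r = np.exp(params[0])
        pa, pe = params[1], params[2]
        if rsq_a is None:
            qa = lk.case_frequency(pa, r)
            qe = lk.case_frequency(pe, r)
        else:
            qa = lk.attenuated_case_frequency(pa, r, rsq_a[rows])
            qe = lk.attenuated_case_frequency(pe, r, rsq_e[rows])
        omega = (1.0 - pe + r * pe) / (1.0 - pa + r * pa)
        return (_ll_counts(ctrl[rows], pa, pe) + _ll_counts(case[rows], qa, qe)
                + _adm_part(bins, omega, rows))

    (logr, pa, pe), ll_alt, conv = lk.coordinate_ascent(
        f_alt,
        [np.zeros(B), snp1["null_p_A"].copy(), snp1["null_p_E"].copy()],
        [(lk.LOG_OR_LO, lk.LOG_OR_HI), (lk.FREQ_LO, lk.FREQ_HI), (lk.FREQ_LO, lk.FREQ_HI)],
    )
    ll_null = snp1["ll_null"]            # admixture part vanishes at Ω = 1
    stat = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    status[(status == _OK) & ~conv] = _NOCONV
    stat[status == _MONO] = 0.0
    r = np.exp(logr)
    omega = (1.0 - pe + r * pe) / (1.0 - pa + r * pa)
    return {"stat": stat, "dof": 1, "p": _pval(stat, 1),
            "R": r, "p_A": pa, "p_E": pe, "Omega": omega,
            "status": status, "n": snp1["n"]}


def het_batch(counts, snp1=None):
    """Heterogeneity of the odds ratio across ancestral backgrounds, 1 dof.

    The 4-parameter alternative decomposes exactly into two independent
    2-parameter fits (control frequencies; free case frequencies); the null
    is the shared-R SNP1 alternative.
    """
    counts = np.asarray(counts, dtype=float)
    if snp1 is None:
        snp1 = snp1_batch(counts)
    B = counts.shape[0]
    ctrl = counts[:, :, 0, :]
    case = counts[:, :, 1, :]
    status = snp1["status"].copy()
    for grp in (ctrl, case):
        afr_chrom = 2.0 * grp[:, 0, :].sum(axis=1) + grp[:, 1, :].sum(axis=1)
        eur_chrom = 2.0 * grp[:, 2, :].sum(axis=1) + grp[:, 1, :].sum(axis=1)
        status[(afr_chrom == 0) | (eur_chrom == 0)] = _DEGEN

    pa0, pe0 = _init_freqs(ctrl)
    qa0, qe0 = _init_freqs(case)
    pa, pe, ll_c, conv_c = _fit_freqs(ctrl, pa0, pe0)
    qa, qe, ll_k, conv_k = _fit_freqs(case, qa0, qe0)
    stat = np.maximum(2.0 * (ll_c + ll_k - snp1["ll_alt"]), 0.0)
    status[(status == _OK) & ~(conv_c & conv_k)] = _NOCONV
    stat[(status == _MONO) | (status == _DEGEN)] = 0.0
    odds = lambda p: p / (1.0 - p)
    return {"stat": stat, "dof": 1, "p": _pval(stat, 1),
            "R_A": odds(qa) / odds(pa), "R_E": odds(qe) / odds(pe),
            "status": status, "n": snp1["n"]}


def admgc_batch(abar, summary):
    """Admixture score against the genome-wide *empirical* ancestry spread:
    ((ā − μ̄)/σ̂)², 1 dof."""
    abar = np.asarray(abar, dtype=float)
    if summary.sd <= 0:
        status = np.full(abar.shape, _DEGEN, dtype=np.int8)
        stat = np.zeros_like(abar)
    else:
        status = np.zeros(abar.shape, dtype=np.int8)
        stat = ((abar - summary.mean) / summary.sd) ** 2
    return {"stat": stat, "dof": 1, "p": _pval(stat, 1), "status": status}


def mixgc_batch(counts, bins, abar, summary, rsq=None, snp1=None):
    """MIX with the binomial admixture term replaced by a normal model of ā.

    ā is taken normal with empirical SD σ̂ and mean
    m(Ω) = μ̄ + (mean_i q_i(Ω) − mean_i θ_i); at Ω = 1 the mean anchors at
    the observed genome-wide average μ̄.
    """
    counts = np.asarray(counts, dtype=float)
    if snp1 is None:
        snp1 = snp1_batch(counts, rsq=rsq)
    if summary.sd <= 0:
        raise ValueError("degenerate genome summary: zero ancestry spread")
    abar = np.asarray(abar, dtype=float)
    B = counts.shape[0]
    ctrl = counts[:, :, 0, :]
    case = counts[:, :, 1, :]
    inv2s2 = 1.0 / (2.0 * summary.sd ** 2)
    rsq_a = rsq_e = None
    if rsq is not None:
        rsq_a = np.asarray(rsq[0], dtype=float)
        rsq_e = np.asarray(rsq[1], dtype=float)

    def gc_part(omega, rows):
        c = bins["c"][rows]
        tb = bins["tbar"][rows]
        om = omega[:, None]
        q = tb * om / (tb * om + 1.0 - tb)
        mean_q = np.einsum("bk,bk->b", c, q) / bins["m"][rows]
        mu = summary.mean + mean_q - bins["mean_theta"][rows]
        return -((abar[rows] - mu) ** 2) * inv2s2

    def f_alt(params, rows):
        r = np.exp(params[0])
        pa, pe = params[1], params[2]
        if rsq_a is None:
            qa = lk.case_frequency(pa, r)
            qe = lk.case_frequency(pe, r)
        else:
            qa = lk.attenuated_case_frequency(pa, r, rsq_a[rows])
            qe = lk.attenuated_case_frequency(pe, r, rsq_e[rows])
        omega = (1.0 - pe + r * pe) / (1.0 - pa + r * pa)
        return (_ll_counts(ctrl[rows], pa, pe) + _ll_counts(case[rows], qa, qe)
                + gc_part(omega, rows))

    (logr, pa, pe), ll_alt, conv = lk.coordinate_ascent(
        f_alt,
        [np.zeros(B), snp1["null_p_A"].copy(), snp1["null_p_E"].copy()],
        [(lk.LOG_OR_LO, lk.LOG_OR_HI), (lk.FREQ_LO, lk.FREQ_HI), (lk.FREQ_LO, lk.FREQ_HI)],
    )
    ll_null = snp1["ll_null"] + gc_part(np.ones(B), np.arange(B))
    stat = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    status = snp1["status"].copy()
    status[(status == _OK) & ~conv] = _NOCONV
    stat[status == _MONO] = 0.0
    return {"stat": stat, "dof": 1, "p": _pval(stat, 1),
            "R": np.exp(logr), "status": status, "n": snp1["n"]}


def att_batch(g, theta, y):
    """Ancestry-adjusted Armitage trend statistic for (B, n) batches.

    Both genotype (or dosage) and phenotype are residualised on an
    intercept and θ; the statistic is (N − 2) times the squared correlation
    of the residuals.
    """
    g = np.atleast_2d(np.asarray(g, dtype=float))
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    B, n = g.shape
    gc = g - g.mean(axis=1, keepdims=True)
    tc = theta - theta.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    Sgg = np.einsum("bi,bi->b", gc, gc)
    Stt = np.einsum("bi,bi->b", tc, tc)
    Syy = np.einsum("bi,bi->b", yc, yc)
    Sgt = np.einsum("bi,bi->b", gc, tc)
    Syt = np.einsum("bi,bi->b", yc, tc)
    Sgy = np.einsum("bi,bi->b", gc, yc)
    scale = np.maximum(Stt, 1e-300)
    adjust = Stt / n > 1e-14
    Sgg_r = np.where(adjust, Sgg - Sgt ** 2 / scale, Sgg)
    Syy_r = np.where(adjust, Syy - Syt ** 2 / scale, Syy)
    Sgy_r = np.where(adjust, Sgy - Sgt * Syt / scale, Sgy)
    status = np.zeros(B, dtype=np.int8)
    status[Sgg_r / n <= 1e-12] = _MONO
    status[Syy_r / n <= 1e-14] = _DEGEN
    denom = np.where(status == _OK, Sgg_r * Syy_r, 1.0)
    stat = np.where(status == _OK, (n - 2) * Sgy_r ** 2 / denom, 0.0)
    return {"stat": stat, "dof": 1, "p": _pval(stat, 1),
            "status": status, "n": np.full(B, n)}


# ---------------------------------------------------------------------------
# per-SNP public API
# ---------------------------------------------------------------------------

def _result(batch, i=0, keys=()):
    status = _STATUS[int(batch["status"][i])]
    est = {k: float(batch[k][i]) for k in keys}
    n = int(batch["n"][i]) if "n" in batch else 0
    return ScoreResult(statistic=float(batch["stat"][i]), dof=int(batch["dof"]),
                       p_value=float(batch["p"][i]), estimates=est, n=n,
                       status=status)


def score_att(g, y, theta):
    """Armitage trend test with adjustment for genome-wide ancestry.

    Accepts integer genotypes or real imputation dosages in [0, 2]
    (the "ATT-dose" variant); individuals missing any of g, y or θ at the
    SNP are excluded.
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    theta = np.asarray(theta, dtype=float)
    keep = (np.isfinite(g) & (g != MISSING) & np.isfinite(y) & np.isfinite(theta))
    if keep.sum() < 3:
        return ScoreResult(0.0, 1, 1.0, {}, int(keep.sum()), Status.DEGENERATE)
    batch = att_batch(g[keep][None, :], theta[keep][None, :], y[keep][None, :])
    return _result(batch)


def score_snp1(counts, rsq=None):
    """SNP association conditioned on local ancestry (shared odds ratio R)."""
    counts = np.asarray(counts.n if isinstance(counts, StratifiedCounts) else counts)
    rsq_arr = None if rsq is None else (np.atleast_1d(float(rsq[0])),
                                        np.atleast_1d(float(rsq[1])))
    batch = snp1_batch(counts[None, ...], rsq=rsq_arr)
    return _result(batch, keys=("R", "p_A", "p_E"))


def score_adm(profile):
    """Case-only admixture association (locus vs genome-wide ancestry)."""
    keep = profile.consistent()
    theta = profile.theta[keep]
    n_eur = profile.n_eur[keep]
    if ((theta > 0) & (theta < 1)).sum() == 0:
        return ScoreResult(0.0, 1, 1.0, {}, int(theta.size), Status.DEGENERATE)
    bins = profile_bins(theta[None, :], np.asarray(n_eur, float)[None, :])
    batch = adm_batch(bins)
    return _result(batch, keys=("Omega",))


def score_sum(snp1, adm):
    """χ²(2) sum of SNP1 and ADM results."""
    for r in (snp1, adm):
        if r.status not in (Status.OK, Status.NOT_CONVERGED):
            return ScoreResult(0.0, 2, 1.0, {}, r.n, r.status)
    stat = snp1.statistic + adm.statistic
    status = Status.NOT_CONVERGED if Status.NOT_CONVERGED in (
        snp1.status, adm.status) else Status.OK
    return ScoreResult(stat, 2, float(_pval(stat, 2)), {}, snp1.n, status)


def score_mix(counts, profile, rsq=None):
    """Mixed SNP + admixture score with the implied ancestry odds ratio."""
    counts = np.asarray(counts.n if isinstance(counts, StratifiedCounts) else counts)
    keep = profile.consistent()
    theta = profile.theta[keep]
    n_eur = np.asarray(profile.n_eur, float)[keep]
    if ((theta > 0) & (theta < 1)).sum() == 0:
        return ScoreResult(0.0, 1, 1.0, {}, int(theta.size), Status.DEGENERATE)
    bins = profile_bins(theta[None, :], n_eur[None, :])
    rsq_arr = None if rsq is None else (np.atleast_1d(float(rsq[0])),
                                        np.atleast_1d(float(rsq[1])))
    batch = mix_batch(counts[None, ...], bins, rsq=rsq_arr)
    return _result(batch, keys=("R", "p_A", "p_E", "Omega"))


def score_het(counts):
    """Test for ancestry-specific odds ratios R_A ≠ R_E."""
    counts = np.asarray(counts.n if isinstance(counts, StratifiedCounts) else counts)
    batch = het_batch(counts[None, ...])
    return _result(batch, keys=("R_A", "R_E"))


def score_admgc(abar, summary):
    """Admixture score standardised by the genome-wide empirical spread of ā."""
    if summary.abar.size < 100:
        raise ValueError("genome summary must be built from at least 100 SNPs")
    batch = admgc_batch(np.atleast_1d(float(abar)), summary)
    res = _result({**batch, "n": np.array([0])})
    return res


def score_mixgc(counts, profile, summary, rsq=None):
    """MIX with the empirically calibrated normal admixture component."""
    if summary.abar.size < 100:
        raise ValueError("genome summary must be built from at least 100 SNPs")
    counts = np.asarray(counts.n if isinstance(counts, StratifiedCounts) else counts)
    keep = profile.consistent()
    theta = profile.theta[keep]
    n_eur = np.asarray(profile.n_eur, float)[keep]
    bins = profile_bins(theta[None, :], n_eur[None, :])
    rsq_arr = None if rsq is None else (np.atleast_1d(float(rsq[0])),
                                        np.atleast_1d(float(rsq[1])))
    abar = np.atleast_1d(float(n_eur.mean() / 2.0))
    batch = mixgc_batch(counts[None, ...], bins, abar, summary, rsq=rsq_arr)
    return _result(batch, keys=("R",))


# ---------------------------------------------------------------------------
# whole-dataset driver
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["snp", "n", "ATT", "SNP1", "ADM", "SUM", "MIX", "HET",
                  "p_ATT", "p_SNP1", "p_ADM", "p_SUM", "p_MIX", "p_HET",
                  "R_hat", "Omega_hat", "status"]


def score_dataset(geno, anc, theta, pheno, rsq=None, gc=False):
    """Score every SNP of a dataset and return the report table.

    Parameters mirror the text-table inputs: a :class:`GenotypeMatrix`,
    the paired :class:`LocalAncestryMatrix`, a :class:`GlobalAncestryVector`
    and a binary :class:`PhenotypeVector`.  With ``gc=True`` a first pass
    over all SNPs builds the :class:`GenomeAncestrySummary` needed by the
    ADMGC/MIXGC columns (requires ≥ 100 SNPs).
    """
    pheno.require_cases_and_controls()
    y = pheno.y
    th = theta.theta
    rows = []
    per_snp = []
    for i, snp in enumerate(geno.snp_ids):
        g = geno.values[i].astype(float)
        l = anc.values[i].astype(float)
        counts = tabulate_counts(g, l, y)
        case_keep = ((y == 1) & np.isfinite(y) & (l != MISSING)
                     & np.isfinite(th) & (g != MISSING))
        profile = AncestryProfile(th[case_keep], anc.values[i][case_keep])
        pair = None
        if rsq is not None:
            pair = rsq.lookup(snp)
        att = score_att(g, y, th)
        snp1 = score_snp1(counts, rsq=pair)
        adm = score_adm(profile)
        ssum = score_sum(snp1, adm)
        mix = score_mix(counts, profile, rsq=pair)
        het = score_het(counts)
        statuses = {"ATT": att, "SNP1": snp1, "ADM": adm, "SUM": ssum,
                    "MIX": mix, "HET": het}
        flag = ",".join(f"{k}:{v.status.value}" for k, v in statuses.items()
                        if v.status != Status.OK) or "OK"
        rows.append([snp, counts.total,
                     att.statistic, snp1.statistic, adm.statistic,
                     ssum.statistic, mix.statistic, het.statistic,
                     att.p_value, snp1.p_value, adm.p_value,
                     ssum.p_value, mix.p_value, het.p_value,
                     mix.estimates.get("R", np.nan),
                     adm.estimates.get("Omega", np.nan), flag])
        keep_ok = profile.consistent()
        per_snp.append((counts, profile,
                        float(np.asarray(profile.n_eur, float)[keep_ok].mean() / 2.0)
                        if keep_ok.any() else np.nan, pair))
    table = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    if gc:
        abar = np.array([a for (_, _, a, _) in per_snp])
        from .evaluation import lambda_gc
        adm_stats = table["ADM"].to_numpy()
        summary = GenomeAncestrySummary.from_abar(
            abar[np.isfinite(abar)], lambda_adm=lambda_gc(adm_stats, 1))
        if summary.abar.size < 100:
            raise ValueError("GC scores need a genome-wide pass over >= 100 SNPs")
        admgc, mixgc = [], []
        for (counts, profile, a, pair) in per_snp:
            admgc.append(score_admgc(a, summary))
            mixgc.append(score_mixgc(counts, profile, summary, rsq=pair))
        table["ADMGC"] = [r.statistic for r in admgc]
        table["MIXGC"] = [r.statistic for r in mixgc]
        table["p_ADMGC"] = [r.p_value for r in admgc]
        table["p_MIXGC"] = [r.p_value for r in mixgc]
    return table
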
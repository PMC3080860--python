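"""Quantitative-trait analogues of the case-control scores.

All five statistics are residual-regression χ² scores: the phenotype is
centred, predictor and phenotype are residualised on the covariate, and
the statistic is N times the proportion of residual phenotypic variance
explained —

========  ====  ===========  ===========
score     dof   predictor    covariate
========  ====  ===========  ===========
QATT       1    genotype g   genome-wide θ
QSNP1      1    genotype g   local ancestry l
QADM       1    ancestry l   genome-wide θ
QSUM       2    QSNP1 + QADM
QHET       1    (g_A, g_E) joint 2-dof fit minus QSNP1
========  ====  ===========  ===========

QHET splits the genotype into reference alleles carried on African
versus European background; when both genotype and local ancestry are
heterozygous the split is ambiguous and its expectation under the
stratified frequency estimates is used.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2

from . import likelihood as lk
from .casecontrol import P_FLOOR, _fit_freqs
from .types import MISSING, ScoreResult, Status


def _pval(stat, dof):
    return float(np.maximum(chi2.sf(stat, dof), P_FLOOR))


def _complete(*arrays):
    keep = np.ones(np.asarray(arrays[0]).shape[0], dtype=bool)
    for a in arrays:
        a = np.asarray(a, dtype=float)
        keep &= np.isfinite(a) & (a != MISSING)
    return keep


def residual_chisq(y, x, covariates=None):
    """N × (variance proportion of residual y explained by residual x).

    ``x`` may be a single predictor ``(n,)`` or several ``(n, k)``; all
    variables are centred and, when given, residualised on the covariates
    (with intercept).  Returns a :class:`ScoreResult` with ``dof = k`` and
    the least-squares coefficients as effect sizes.
    """
    y = np.asarray(y, dtype=float).copy()
    X = np.asarray(x, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    X = X.copy()
    n = y.size
    if n < 3:
        return ScoreResult(0.0, X.shape[1], 1.0, {}, n, Status.DEGENERATE)
    y -= y.mean()
    X -= X.mean(axis=0)
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        C = C - C.mean(axis=0)
        if (C.var(axis=0) > 1e-14).any():
            beta_y, *_ = np.linalg.lstsq(C, y, rcond=None)
            y = y - C @ beta_y
            beta_x, *_ = np.linalg.lstsq(C, X, rcond=None)
            X = X - C @ beta_x
    syy = float(y @ y)
    if syy / n <= 1e-14:
        return ScoreResult(0.0, X.shape[1], 1.0, {}, n, Status.DEGENERATE)
    if (X.var(axis=0) <= 1e-12).any():
        return ScoreResult(0.0, X.shape[1], 1.0, {}, n, Status.MONOMORPHIC)
    S = X.T @ X
    if X.shape[1] > 1:
        cond = np.linalg.cond(S)
        if not np.isfinite(cond) or cond > 1e12:
            return ScoreResult(0.0, X.shape[1], 1.0, {}, n, Status.DEGENERATE)
    b = np.linalg.solve(S, X.T @ y)
    r2 = float(b @ (X.T @ y)) / syy
    stat = max(n * r2, 0.0)
    dof = X.shape[1]
    effects = {f"eps_{i}": float(v) for i, v in enumerate(b)} if dof > 1 \
        else {"eps": float(b[0])}
    return ScoreResult(stat, dof, _pval(stat, dof), effects, n, Status.OK)


def score_qatt(g, y, theta):
    """Quantitative trend test: genotype (or dosage) adjusted for θ."""
    g, y, theta = (np.asarray(a, dtype=float) for a in (g, y, theta))
    keep = _complete(g, y, theta)
    return residual_chisq(y[keep], g[keep], theta[keep])


def score_qsnp1(g, y, l):
    """SNP association conditioned on local ancestry (covariate l, not θ)."""
    g, y, l = (np.asarray(a, dtype=float) for a in (g, y, l))
    keep = _complete(g, y, l)
    return residual_chisq(y[keep], g[keep], l[keep])


def score_qadm(l, y, theta):
    """Admixture association: local ancestry predicting y, adjusted for θ."""
    l, y, theta = (np.asarray(a, dtype=float) for a in (l, y, theta))
    keep = _complete(l, y, theta)
    return residual_chisq(y[keep], l[keep], theta[keep])


def score_qsum(qsnp1, qadm):
    """χ²(2) sum of QSNP1 and QADM."""
    for r in (qsnp1, qadm):
        if r.status not in (Status.OK,):
            return ScoreResult(0.0, 2, 1.0, {}, r.n, r.status)
    stat = qsnp1.statistic + qadm.statistic
    return ScoreResult(stat, 2, _pval(stat, 2), {}, qsnp1.n, Status.OK)


def ancestry_specific_dosage(g, l, p_a, p_e):
    """Split genotypes into (g_A, g_E) reference-allele counts by background.

    Unambiguous except in the het-het case (g = 1, l = 1), where the
    European-background expectation
    E[g_E] = p_E(1−p_A) / (p_E(1−p_A) + p_A(1−p_E)) is used.
    """
    g = np.asarray(g, dtype=float)
    l = np.asarray(l, dtype=float)
    w = p_e * (1.0 - p_a) / (p_e * (1.0 - p_a) + p_a * (1.0 - p_e))
    g_e = np.where(l == 0, 0.0,
                   np.where(l == 2, g,
                            np.where(g == 0, 0.0,
                                     np.where(g == 2, 1.0, w))))
    g_a = g - g_e
    return g_a, g_e


def estimate_background_freqs(g, l):
    """(p̂_A, p̂_E) maximising the stratified genotype likelihood of one group."""
    g = np.asarray(g, dtype=float)
    l = np.asarray(l, dtype=float)
    keep = _complete(g, l)
    gi = np.rint(g[keep]).astype(int)
    li = l[keep].astype(int)
    m = np.bincount(li * 3 + gi, minlength=9).reshape(1, 3, 3).astype(float)
    from .casecontrol import _init_freqs
    pa0, pe0 = _init_freqs(m)
    pa, pe, _, _ = _fit_freqs(m, pa0, pe0)
    return float(pa[0]), float(pe[0])


def score_qhet(g, l, y, p_a=None, p_e=None):
    """Heterogeneity of quantitative effect size across backgrounds.

    The joint χ²(2) fit of y on (g_A, g_E) with covariate l, minus QSNP1,
    testing ε_A ≠ ε_E on 1 dof.  Frequencies for the het-het split default
    to stratified estimates from all supplied individuals; pass control-only
    estimates for case-control-derived data.
    """
    g, l, y = (np.asarray(a, dtype=float) for a in (g, l, y))
    keep = _complete(g, l, y)
    g, l, y = g[keep], l[keep], y[keep]
    if p_a is None or p_e is None:
        p_a, p_e = estimate_background_freqs(g, l)
    g_a, g_e = ancestry_specific_dosage(g, l, p_a, p_e)
    joint = residual_chisq(y, np.column_stack([g_a, g_e]), covariates=l)
    if joint.status != Status.OK:
        return ScoreResult(0.0, 1, 1.0, {}, joint.n, joint.status)
    qsnp1 = residual_chisq(y, g, covariates=l)
    if qsnp1.status != Status.OK:
        return ScoreResult(0.0, 1, 1.0, {}, qsnp1.n, qsnp1.status)
    stat = max(joint.statistic - qsnp1.statistic, 0.0)
    est = {"eps_A": joint.estimates.get("eps_0", np.nan),
           "eps_E": joint.estimates.get("eps_1", np.nan)}
    return ScoreResult(stat, 1, _pval(stat, 1), est, joint.n, Status.OK)


# ---------------------------------------------------------------------------
# batch engine used by genome-wide simulation runs
# ---------------------------------------------------------------------------

def _moments(a, b):
    return np.einsum("bi,bi->b", a, b)


def _residualize(rows, cov):
    """Remove the per-row projection on an already-centred covariate."""
    Scc = np.maximum(_moments(cov, cov), 1e-300)
    out = []
    for r in rows:
        out.append(r - (_moments(r, cov) / Scc)[:, None] * cov)
    return out


def qscores_batch(g, l, theta, y):
    """All five quantitative statistics for (B, n) batches without missing data."""
    g = np.asarray(g, dtype=float)
    l = np.asarray(l, dtype=float)
    theta = np.asarray(theta, dtype=float)
    y = np.asarray(y, dtype=float)
    B, n = g.shape
    gc = g - g.mean(axis=1, keepdims=True)
    lc = l - l.mean(axis=1, keepdims=True)
    tc = theta - theta.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)

    def chi1(x, yv):
        sxx = _moments(x, x)
        syy = _moments(yv, yv)
        sxy = _moments(x, yv)
        ok = (sxx / n > 1e-12) & (syy / n > 1e-14)
        denom = np.where(ok, sxx * syy, 1.0)
        return np.where(ok, n * sxy ** 2 / denom, 0.0), ok

    g_t, y_t = _residualize([gc, yc], tc)
    qatt, ok_att = chi1(g_t, y_t)
    g_l, y_l = _residualize([gc, yc], lc)
    qsnp1, ok_s1 = chi1(g_l, y_l)
    l_t = _residualize([lc], tc)[0]
    qadm, ok_adm = chi1(l_t, y_t)
    qsum = qsnp1 + qadm

    # het-het split frequencies from the stratified fit over everyone
    li = np.rint(l).astype(int)
    gi = np.rint(g).astype(int)
    flat = (li * 3 + gi) + 9 * np.arange(B)[:, None]
    m = np.bincount(flat.ravel(), minlength=9 * B).reshape(B, 3, 3).astype(float)
    from .casecontrol import _init_freqs
    pa0, pe0 = _init_freqs(m)
    pa, pe, _, _ = _fit_freqs(m, pa0, pe0)
    w = (pe * (1 - pa) / (pe * (1 - pa) + pa * (1 - pe)))[:, None]
    g_e = np.where(l == 0, 0.0,
                   np.where(l == 2, g,
                            np.where(g == 0, 0.0, np.where(g == 2, 1.0, w))))
    g_a = g - g_e
    ac = g_a - g_a.mean(axis=1, keepdims=True)
    ec = g_e - g_e.mean(axis=1, keepdims=True)
    a_l, e_l = _residualize([ac, ec], lc)
    Saa = _moments(a_l, a_l)
    See = _moments(e_l, e_l)
    Sae = _moments(a_l, e_l)
    Say = _moments(a_l, y_l)
    Sey = _moments(e_l, y_l)
    Syy = np.maximum(_moments(y_l, y_l), 1e-300)
    det = Saa * See - Sae ** 2
    ok_het = (det > 1e-9 * np.maximum(Saa * See, 1e-300)) & (Saa / n > 1e-12) \
        & (See / n > 1e-12) & ok_s1
    det_s = np.where(ok_het, det, 1.0)
    b_a = (See * Say - Sae * Sey) / det_s
    b_e = (Saa * Sey - Sae * Say) / det_s
    joint = np.where(ok_het, n * (b_a * Say + b_e * Sey) / Syy, 0.0)
    qhet = np.where(ok_het, np.maximum(joint - qsnp1, 0.0), 0.0)

    return {
        "QATT": qatt, "QSNP1": qsnp1, "QADM": qadm, "QSUM": qsum, "QHET": qhet,
        "ok": {"QATT": ok_att, "QSNP1": ok_s1, "QADM": ok_adm,
               "QSUM": ok_s1 & ok_adm, "QHET": ok_het},
        "dof": {"QATT": 1, "QSNP1": 1, "QADM": 1, "QSUM": 2, "QHET": 1},
    }
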
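"""Shared probability kernels and bounded coordinate maximisers.

Every likelihood-ratio score in the package is built from three kernels:

* the stratified genotype likelihood — within each diploid local-ancestry
  stratum (AA, AE, EE) genotypes are multinomial with Hardy–Weinberg-style
  cell probabilities formed from the African- and European-background
  reference-allele frequencies; cases use frequencies shifted by the
  allelic odds ratio R on the odds scale;
* the case-only admixture likelihood — the number of European alleles a
  case carries at the locus is Binomial(2, q(Ω)) with
  q_i(Ω) = θ_i Ω / (θ_i Ω + 1 − θ_i);
* the implied ancestry odds ratio Ω(R, p_A, p_E) that couples the two
  under a single multiplicative causal variant.

Maximisation is cyclic and one-dimensional over each free parameter in
turn (odds ratios on the log scale).  Two routes are provided:
:func:`maximize` (scipy bounded Brent per coordinate, with a
golden-section fallback) for single instances, and
:func:`coordinate_ascent` — a lockstep golden-section engine vectorised
over a batch of independent problems — used for genome-wide runs.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

# parameter boxes: frequencies interior to (0, 1); odds ratios within
# [1/100, 100], optimised on the log scale
FREQ_LO = 1e-4
FREQ_HI = 1.0 - 1e-4
OR_LO = 1.0 / 100.0
OR_HI = 100.0
LOG_OR_LO = float(np.log(OR_LO))
LOG_OR_HI = float(np.log(OR_HI))

LL_TOL = 1e-8      # convergence tolerance on the log-likelihood
PARAM_TOL = 1e-6   # and on parameters
MAX_SWEEPS = 100

_NEG_INF = -np.inf


class OptimizerSpec:
    """Bounds and tolerances for the coordinate maximisers.

    Frequencies live in [1e-4, 1−1e-4] and odds ratios in [1/100, 100]
    (log scale); both boxes must be strictly positive and the tolerances
    strictly greater than zero.
    """

    def __init__(self, freq_bounds=(FREQ_LO, FREQ_HI),
                 log_or_bounds=(LOG_OR_LO, LOG_OR_HI),
                 ll_tol=LL_TOL, param_tol=PARAM_TOL, max_sweeps=MAX_SWEEPS):
        if freq_bounds[0] <= 0 or freq_bounds[1] >= 1:
            raise ValueError("frequency bounds must lie strictly inside (0, 1)")
        if ll_tol <= 0 or param_tol <= 0 or max_sweeps < 1:
            raise ValueError("tolerances must be positive")
        self.freq_bounds = tuple(freq_bounds)
        self.log_or_bounds = tuple(log_or_bounds)
        self.ll_tol = float(ll_tol)
        self.param_tol = float(param_tol)
        self.max_sweeps = int(max_sweeps)


def case_frequency(p, r):
    """Map a control frequency to the case frequency under odds ratio ``r``.

    Solves odds(p⁺) = r · odds(p), i.e. p⁺ = r p / (1 − p + r p).
    """
    p = np.asarray(p, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("frequency must lie strictly inside (0, 1)")
    if np.any(r <= 0):
        raise ValueError("odds ratio must be positive")
    out = r * p / (1.0 - p + r * p)
    return float(out) if out.ndim == 0 else out


_STRATA = {"AA": 0, "AE": 1, "EE": 2, 0: 0, 1: 1, 2: 2}


def stratum_genotype_probs(a, e):
    """Genotype probabilities per stratum, shape ``(..., 3, 3)``.

    Index order is ``[l, g]`` with ``l`` the number of European
    chromosomes.  AA and EE strata are Binomial(2, ·); the AE stratum
    draws one allele on each background, which is the diploid form that
    needs no allele-level ancestry assignment.
    """
    a, e = np.broadcast_arrays(np.asarray(a, float), np.asarray(e, float))
    P = np.empty(a.shape + (3, 3))
    P[..., 0, 0] = (1 - a) ** 2
    P[..., 0, 1] = 2 * a * (1 - a)
    P[..., 0, 2] = a * a
    P[..., 1, 0] = (1 - a) * (1 - e)
    P[..., 1, 1] = a * (1 - e) + e * (1 - a)
    P[..., 1, 2] = a * e
    P[..., 2, 0] = (1 - e) ** 2
    P[..., 2, 1] = 2 * e * (1 - e)
    P[..., 2, 2] = e * e
    return P


def genotype_probs(stratum, a, e):
    """(P₀, P₁, P₂) for one local-ancestry stratum (``"AA"``/``"AE"``/``"EE"``)."""
    if np.any(np.asarray(a, float) <= 0) or np.any(np.asarray(a, float) >= 1) \
            or np.any(np.asarray(e, float) <= 0) or np.any(np.asarray(e, float) >= 1):
        raise ValueError("frequencies must lie strictly inside (0, 1)")
    li = _STRATA[stratum]
    P = stratum_genotype_probs(a, e)[..., li, :]
    return tuple(float(P[..., g]) if P.ndim == 1 else P[..., g] for g in range(3))


def implied_ancestry_or(r, p_a, p_e):
    """Ancestry odds ratio Ω implied by a single causal SNP of odds ratio ``r``.

    Ω = (1 − p_E + r p_E) / (1 − p_A + r p_A): the ratio of mean
    per-allele risk on a European versus an African background.
    """
    r = np.asarray(r, float)
    p_a = np.asarray(p_a, float)
    p_e = np.asarray(p_e, float)
    if np.any(r <= 0):
        raise ValueError("odds ratio must be positive")
    if np.any((p_a <= 0) | (p_a >= 1)) or np.any((p_e <= 0) | (p_e >= 1)):
        raise ValueError("frequencies must lie strictly inside (0, 1)")
    out = (1.0 - p_e + r * p_e) / (1.0 - p_a + r * p_a)
    return float(out) if out.ndim == 0 else out


def attenuated_case_frequency(p, r, rsq):
    """Observed case frequency at an imputed SNP.

    Imputation noise shrinks the case-control frequency shift; the shift is
    attenuated linearly by the ancestry-specific accuracy r²:
    p⁺_obs = p + r² (p⁺ − p).  With r² = 1 this is the exact odds map.
    """
    shifted = case_frequency(p, r)
    return p + np.asarray(rsq, float) * (shifted - p)


def _xlogy(n, p):
    """n·log(p) with the 0·log(0) = 0 convention and −inf on p = 0, n > 0."""
    n = np.asarray(n, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = np.where(p > 0, np.log(np.maximum(p, 1e-320)), _NEG_INF)
        out = np.where(n > 0, n * lp, 0.0)
    return out


def snp1_loglik(counts, r_a, r_e, p_a, p_e, rsq_afr=None, rsq_eur=None):
    """Stratified multinomial log-likelihood of an 18-cell count table.

    ``counts`` has shape ``(..., 3, 2, 3)`` indexed by (stratum, phenotype,
    genotype).  Controls use (p_a, p_e); cases use the odds-shifted
    frequencies under ancestry-specific odds ratios ``r_a`` and ``r_e``
    (the shared-odds-ratio score sets r_a = r_e).  When ancestry-specific
    imputation accuracies are supplied the case-frequency shift is
    attenuated by r² within each ancestry.
    """
    counts = np.asarray(counts, float)
    if counts.shape[-3:] != (3, 2, 3):
        raise ValueError("counts must have trailing shape (3, 2, 3)")
    if rsq_afr is None:
        qa = case_frequency(p_a, r_a)
    else:
        qa = attenuated_case_frequency(p_a, r_a, rsq_afr)
    if rsq_eur is None:
        qe = case_frequency(p_e, r_e)
    else:
        qe = attenuated_case_frequency(p_e, r_e, rsq_eur)
    Pc = stratum_genotype_probs(p_a, p_e)           # (..., 3, 3)
    Pk = stratum_genotype_probs(qa, qe)
    ll = (_xlogy(counts[..., :, 0, :], Pc).sum(axis=(-2, -1))
          + _xlogy(counts[..., :, 1, :], Pk).sum(axis=(-2, -1)))
    return float(ll) if ll.ndim == 0 else ll


def adm_loglik(profile, omega, clamp=1e-6):
    """Case-only admixture log-likelihood Σᵢ ln Binomial(Nᵢ; 2, qᵢ(Ω)).

    θ values at exactly 0 or 1 carry no Ω information and are clamped to
    [clamp, 1 − clamp] before q is formed; cases with inconsistent (θ, N)
    pairs are excluded (see :meth:`AncestryProfile.consistent`).
    """
    omega = float(omega)
    if omega <= 0:
        raise ValueError("ancestry odds ratio must be positive")
    keep = profile.consistent()
    theta = np.clip(profile.theta[keep], clamp, 1.0 - clamp)
    n = np.asarray(profile.n_eur[keep], float)
    q = theta * omega / (theta * omega + 1.0 - theta)
    logcoef = gammaln(3.0) - gammaln(n + 1.0) - gammaln(3.0 - n)
    return float(np.sum(logcoef + n * np.log(q) + (2.0 - n) * np.log1p(-q)))


# ---------------------------------------------------------------------------
# maximisers
# ---------------------------------------------------------------------------

def golden_section_max(f, lo, hi, iters=40):
    """Golden-section maximisation over per-element brackets, vectorised.

    ``f`` maps a ``(B,)`` array of coordinates to ``(B,)`` objective values;
    ``lo``/``hi`` give each element its own bracket.  Returns
    ``(argmax, value)``.  After 40 iterations the bracket has shrunk by
    0.618⁴⁰ ≈ 4e-9 of its width, far inside the parameter tolerance.
    """
    invphi = 0.6180339887498949
    invphi2 = 0.3819660112501051
    a = np.array(lo, dtype=float, copy=True)
    b = np.array(hi, dtype=float, copy=True)
    a, b = np.broadcast_arrays(a, b)
    a, b = a.copy(), b.copy()
    h = b - a
    c = a + invphi2 * h
    d = a + invphi * h
    yc = f(c)
    yd = f(d)
    for _ in range(iters):
        pick_c = yc > yd
        b = np.where(pick_c, d, b)
        a = np.where(pick_c, a, c)
        h = b - a
        cn = a + invphi2 * h
        dn = a + invphi * h
        xe = np.where(pick_c, cn, dn)
        ye = f(xe)
        c_new = np.where(pick_c, cn, d)
        d_new = np.where(pick_c, c, dn)
        yc_new = np.where(pick_c, ye, yd)
        yd_new = np.where(pick_c, yc, ye)
        c, d, yc, yd = c_new, d_new, yc_new, yd_new
    xstar = np.where(yc > yd, c, d)
    ystar = np.maximum(yc, yd)
    return xstar, ystar


def coordinate_ascent(f, x0, bounds, iters=36, max_sweeps=30, ll_tol=1e-9):
    """Lockstep coordinate ascent over a batch of independent problems.

    Parameters
    ----------
    f : callable
        ``f(params, rows)`` where ``params`` is a list of ``(len(rows),)``
        arrays and ``rows`` indexes the active subset of the batch; returns
        the ``(len(rows),)`` log-likelihoods.
    x0 : list of (B,) arrays
        Initial coordinates; the objective must be finite there.
    bounds : list of (lo, hi) scalars
        Per-coordinate box.

    Candidate coordinates are accepted only if they improve the objective,
    so the returned value never falls below ``f(x0)`` — with a null-model
    start this guarantees non-negative LR statistics.  Rows whose sweep
    improvement drops below ``ll_tol`` are frozen, so late sweeps only
    touch the stragglers.
    """
    xs = [np.array(x, dtype=float, copy=True) for x in x0]
    B = xs[0].shape[0]
    all_rows = np.arange(B)
    best = np.asarray(f(xs, all_rows), dtype=float).copy()
    converged = np.zeros(B, dtype=bool)
    active = all_rows
    for _ in range(max_sweeps):
        prev = best[active].copy()
        sub = [x[active] for x in xs]
        for j, (lo, hi) in enumerate(bounds):
            def fj(t, j=j, sub=sub, rows=active):
                trial = [t if k == j else sub[k] for k in range(len(sub))]
                return f(trial, rows)

            xj, _ = golden_section_max(
                fj, np.full(active.size, lo), np.full(active.size, hi), iters
            )
            cand = [xj if k == j else sub[k] for k in range(len(sub))]
            val = np.asarray(f(cand, active), dtype=float)
            upd = val > best[active]
            sub[j] = np.where(upd, xj, sub[j])
            ba = best[active]
            ba[upd] = val[upd]
            best[active] = ba
        for k in range(len(xs)):
            xs[k][active] = sub[k]
        done = best[active] - prev < ll_tol
        converged[active[done]] = True
        active = active[~done]
        if active.size == 0:
            break
    return xs, best, converged


def maximize(objective, x0, bounds, spec=None, ll_tol=None, max_sweeps=None):
    """Cyclic bounded one-dimensional maximisation of a scalar objective.

    Brent's bounded method is applied to each free parameter in turn until
    a full sweep improves the log-likelihood by less than ``ll_tol``.  If a
    Brent step fails to improve a coordinate, a golden-section (binary-
    search-class) pass over the same bracket is tried before moving on.

    Returns ``(argmax, max value, converged flag)``; the value never falls
    below ``objective(x0)``.
    """
    spec = spec or OptimizerSpec()
    ll_tol = spec.ll_tol if ll_tol is None else ll_tol
    max_sweeps = spec.max_sweeps if max_sweeps is None else max_sweeps
    x = np.asarray(x0, dtype=float).copy()
    best = float(objective(x))
    if not np.isfinite(best):
        raise ValueError("objective must be finite at the initial point")
    converged = False
    for _ in range(max_sweeps):
        prev = best
        for j, (lo, hi) in enumerate(bounds):
            def neg(t, j=j):
                trial = x.copy()
                trial[j] = t
                v = objective(trial)
                return -v if np.isfinite(v) else 1e300

            res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-8})
            if np.isfinite(res.fun) and -res.fun > best:
                x[j] = float(np.clip(res.x, lo, hi))
                best = -float(res.fun)
            else:
                # fallback: derivative-free bracket shrinking on this coordinate
                def fj(t, j=j):
                    trial = np.broadcast_to(x, (t.size, x.size)).copy()
                    trial[:, j] = t
                    return np.array([objective(row) for row in trial])

                xj, yj = golden_section_max(fj, np.array([lo]), np.array([hi]))
                if float(yj[0]) > best:
                    x[j] = float(xj[0])
                    best = float(yj[0])
        if best - prev < ll_tol:
            converged = True
            break
    return x, best, converged
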
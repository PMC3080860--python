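"""Independent brute-force oracles used to validate the likelihood engine.

Everything here is written from first principles — per-stratum allele
enumeration for genotype probabilities, closed-form odds shifts, dense
grids with local refinement for maxima — and never calls the package's
own optimiser or likelihood code.
"""

import numpy as np

LOG_OR_LO = float(np.log(1 / 100))
LOG_OR_HI = float(np.log(100))
FREQ_BOX = (1e-4, 1 - 1e-4)


def probs_oracle(a, e):
    """Genotype probabilities by enumerating the two ordered allele draws."""
    a = np.asarray(a, float)
    e = np.asarray(e, float)
    P = np.empty((3, 3) + a.shape)
    P[0, 0] = (1 - a) * (1 - a)
    P[0, 1] = a * (1 - a) + (1 - a) * a
    P[0, 2] = a * a
    P[1, 0] = (1 - a) * (1 - e)
    P[1, 1] = a * (1 - e) + (1 - a) * e
    P[1, 2] = a * e
    P[2, 0] = (1 - e) * (1 - e)
    P[2, 1] = e * (1 - e) + (1 - e) * e
    P[2, 2] = e * e
    return P


def group_loglik_oracle(group_counts, a, e):
    """Σ n·log P for one phenotype group; grids broadcast over (a, e)."""
    return np.tensordot(group_counts, np.log(probs_oracle(a, e)),
                        axes=([0, 1], [0, 1]))


def snp1_loglik_oracle(counts, R, pa, pe):
    qa = R * pa / (1 - pa + R * pa)
    qe = R * pe / (1 - pe + R * pe)
    return (group_loglik_oracle(counts[:, 0, :], pa, pe)
            + group_loglik_oracle(counts[:, 1, :], qa, qe))


def adm_part_oracle(theta, n_eur, omega):
    """Case-only admixture log-likelihood up to an Ω-free constant."""
    om = np.asarray(omega, float)[..., None]
    q = theta * om / (theta * om + 1 - theta)
    return (n_eur * np.log(q) + (2 - n_eur) * np.log(1 - q)).sum(axis=-1)


def refine_max(f, grids, n_refine=3, pts=21):
    """Dense grid maximum with two local refinements around the best cell."""
    lo = np.array([g[0] for g in grids], float)
    hi = np.array([g[1] for g in grids], float)
    glo, ghi = lo.copy(), hi.copy()
    best = -np.inf
    for _ in range(n_refine + 1):
        axes = [np.linspace(lo[i], hi[i], pts) for i in range(len(grids))]
        mesh = np.meshgrid(*axes, indexing="ij")
        vals = f(*mesh)
        k = np.unravel_index(np.argmax(vals), vals.shape)
        best = float(vals[k])
        ctr = np.array([axes[i][k[i]] for i in range(len(grids))])
        step = (hi - lo) / (pts - 1)
        lo = np.maximum(ctr - step, glo)
        hi = np.minimum(ctr + step, ghi)
    return best


def snp1_stat_oracle(counts, pts=21):
    f_alt = lambda lr, pa, pe: snp1_loglik_oracle(counts, np.exp(lr), pa, pe)
    alt = refine_max(f_alt, [(LOG_OR_LO, LOG_OR_HI), FREQ_BOX, FREQ_BOX], pts=pts)
    f_null = lambda pa, pe: snp1_loglik_oracle(counts, np.ones_like(pa), pa, pe)
    null = refine_max(f_null, [FREQ_BOX, FREQ_BOX], pts=2 * pts - 1)
    return 2 * (alt - null), alt, null


def mix_stat_oracle(counts, theta, n_eur, pts=21):
    def f_mix(lr, pa, pe):
        R = np.exp(lr)
        om = (1 - pe + R * pe) / (1 - pa + R * pa)
        return (snp1_loglik_oracle(counts, R, pa, pe)
                + adm_part_oracle(theta, n_eur, om))

    alt = refine_max(f_mix, [(LOG_OR_LO, LOG_OR_HI), FREQ_BOX, FREQ_BOX], pts=pts)
    _, _, null_snp1 = snp1_stat_oracle(counts, pts=pts)
    null = null_snp1 + float(adm_part_oracle(theta, n_eur, 1.0))
    return 2 * (alt - null)


def het_stat_oracle(counts, pts=21):
    _, alt_shared, _ = snp1_stat_oracle(counts, pts=pts)
    llc = refine_max(lambda pa, pe: group_loglik_oracle(counts[:, 0, :], pa, pe),
                     [FREQ_BOX, FREQ_BOX], pts=2 * pts - 1)
    llk = refine_max(lambda pa, pe: group_loglik_oracle(counts[:, 1, :], pa, pe),
                     [FREQ_BOX, FREQ_BOX], pts=2 * pts - 1)
    return 2 * (llc + llk - alt_shared)


def adm_stat_oracle(theta, n_eur, pts=4001):
    grid = np.linspace(LOG_OR_LO, LOG_OR_HI, pts)
    part = adm_part_oracle(theta, n_eur, np.exp(grid))
    return 2 * float(part.max() - adm_part_oracle(theta, n_eur, 1.0))
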
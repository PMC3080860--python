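"""Genome-wide calibration and power machinery.

Implements the standard genomic-control inflation factor λ_GC
(median-based), power at per-score significance thresholds, region-max
scoring for regions where the causal SNP is untyped, and the
orchestration of the simulation experiments: a synthetic cohort is
generated once and, for every SNP in turn, a fresh phenotype is drawn
(null, case-control at odds ratio R, or quantitative at effect size ε)
and the requested scores computed.  Case/control selections reuse common
random numbers across odds-ratio values so that power comparisons across
R are paired.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from . import casecontrol as cc
from . import quantitative as qt
from . import simulate as sim
from .types import GenomeAncestrySummary

#: genome-wide significance defaults: 5e-8 everywhere except the admixture
#: scan, whose coarse ancestry blocks mean far fewer independent hypotheses
DEFAULT_THRESHOLD = 5e-8
ADM_THRESHOLD = 1e-5

CASE_CONTROL_SCORES = ("ATT", "SNP1", "ADM", "SUM", "MIX", "HET", "ADMGC", "MIXGC")
QUANT_SCORES = ("QATT", "QSNP1", "QADM", "QSUM", "QHET")


def default_thresholds(scores):
    return {s: (ADM_THRESHOLD if s in ("ADM", "ADMGC", "QADM") else DEFAULT_THRESHOLD)
            for s in scores}


def lambda_gc(statistics, dof=1):
    """median(χ²) / median of the null χ²(dof) distribution.

    The 1-dof null median is 0.454936…; values near 1 indicate calibration,
    larger values inflation.
    """
    stats = np.asarray(statistics, dtype=float)
    stats = stats[np.isfinite(stats)]
    if stats.size < 100:
        raise ValueError("lambda_GC needs at least 100 finite statistics")
    return float(np.median(stats) / chi2.median(dof))


def power(p_values, threshold):
    """Fraction of p-values strictly below the threshold."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("power of an empty p-value set is undefined")
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    return float(np.mean(p < threshold))


def region_max(statistics, center, half_width=20, exclude_center=False):
    """Maximum statistic over the window of ``half_width`` SNPs on each side.

    The window is clipped at the array edges; with ``exclude_center`` the
    centre SNP (e.g. a masked causal SNP) is ignored, leaving the 40-SNP
    variant of the 41-SNP region score.  Returns (max, argmax index).
    """
    stats = np.asarray(statistics, dtype=float)
    n = stats.size
    if not 0 <= center < n:
        raise IndexError(f"center {center} outside array of length {n}")
    lo = max(0, center - half_width)
    hi = min(n, center + half_width + 1)
    idx = np.arange(lo, hi)
    if exclude_center:
        idx = idx[idx != center]
    if idx.size == 0:
        raise ValueError("empty window after excluding the center SNP")
    k = idx[np.argmax(stats[idx])]
    return float(stats[k]), int(k)


@dataclass
class EvaluationSummary:
    """Aggregate outcome of one simulation experiment."""

    n_snps: int
    scores: tuple
    lambda_gc: dict = field(default_factory=dict)
    power: dict = field(default_factory=dict)
    mean_stat: dict = field(default_factory=dict)
    n_ok: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [(s, self.n_ok.get(s), self.mean_stat.get(s),
                 self.lambda_gc.get(s), self.thresholds.get(s),
                 self.power.get(s)) for s in self.scores]
        return pd.DataFrame(rows, columns=["score", "n_ok", "mean_stat",
                                           "lambda_gc", "threshold", "power"])


def _log(msg, verbose):
    if verbose:
        print(msg, file=sys.stderr, flush=True)


def _tabulate_chunk(N_g, g_g, y_is_case):
    """(B, 3, 3) genotype-by-stratum tables for one phenotype group."""
    B = N_g.shape[0]
    flat = (N_g.astype(np.int64) * 3 + g_g) + 9 * np.arange(B)[:, None]
    return np.bincount(flat.ravel(), minlength=9 * B).reshape(B, 3, 3)


def run_power_experiment(config, scores=("ATT", "SNP1", "ADM", "SUM", "MIX"),
                         seed=None, chunk_size=2048, n_bins=cc.DEFAULT_BINS,
                         thresholds=None, return_table=False, verbose=False):
    """Simulate per-SNP phenotypes on a synthetic cohort and score them.

    For each simulated SNP the phenotype is re-drawn according to
    ``config.phenotype_model`` and the requested scores are computed;
    the summary tabulates per-score λ_GC, mean statistic and power at the
    per-score thresholds.  Identical (config, seed) pairs reproduce the
    summary exactly, and selections are paired across odds-ratio values
    (common random numbers).
    """
    seed = config.seed if seed is None else seed
    seed = list(seed) if isinstance(seed, (list, tuple)) else [seed]
    scores = tuple(scores)
    if config.phenotype_model == "quantitative" or set(scores) & set(QUANT_SCORES):
        return _run_quantitative(config, scores, seed, chunk_size,
                                 thresholds, return_table, verbose)
    thresholds = thresholds or default_thresholds(scores)
    theta = sim.draw_theta(config, np.random.default_rng(seed + [0]))
    n_ind = theta.size
    nc, nk = config.n_controls, config.n_cases
    if nc + nk > n_ind:
        raise ValueError("cohort smaller than cases + controls")
    if config.linkage == "markov_blocks":
        chunk_size = config.n_snps
    null_model = config.phenotype_model == "null" or config.odds_ratio == 1.0

    counts_parts, att_parts, bin_parts = [], [], []
    starts = list(range(0, config.n_snps, chunk_size))
    for ci, start in enumerate(starts):
        B = min(chunk_size, config.n_snps - start)
        rng_c = np.random.default_rng(seed + [1, ci])
        rng_p = np.random.default_rng(seed + [2, ci])
        pa, pe = sim.draw_frequencies(config, rng_c, n=B)
        N = sim._draw_local_ancestry(config, theta, B, rng_c)
        g = sim._draw_genotypes(N, pa, pe, rng_c)
        u = rng_p.random((B, n_ind))
        e = rng_p.exponential(size=(B, n_ind))
        controls = np.argpartition(u, nc - 1, axis=1)[:, :nc]
        if null_model:
            keys = e
        elif config.disease_model == "two_locus":
            pa2, pe2 = sim.draw_frequencies(config, rng_c, n=B)
            g2 = sim._draw_genotypes(N, pa2, pe2, rng_c)
            R = config.odds_ratio
            keys = e / (R ** g.astype(float) * R ** g2.astype(float))
        else:
            w = sim.disease_weights(np.arange(3.0), config.odds_ratio,
                                    config.disease_model)
            keys = e / w[g]
        np.put_along_axis(keys, controls, np.inf, axis=1)
        cases = np.argpartition(keys, nk - 1, axis=1)[:, :nk]

        g_ctrl = np.take_along_axis(g, controls, axis=1)
        N_ctrl = np.take_along_axis(N, controls, axis=1)
        g_case = np.take_along_axis(g, cases, axis=1)
        N_case = np.take_along_axis(N, cases, axis=1)
        counts = np.zeros((B, 3, 2, 3), dtype=np.int32)
        counts[:, :, 0, :] = _tabulate_chunk(N_ctrl, g_ctrl, False)
        counts[:, :, 1, :] = _tabulate_chunk(N_case, g_case, True)
        counts_parts.append(counts)
        bin_parts.append(cc.profile_bins(theta[cases], N_case.astype(float),
                                         n_bins=n_bins))
        if "ATT" in scores:
            g_sel = np.concatenate([g_ctrl, g_case], axis=1).astype(float)
            th_sel = np.concatenate([np.take_along_axis(
                np.broadcast_to(theta, (B, n_ind)), controls, axis=1),
                theta[cases]], axis=1)
            y_sel = np.concatenate([np.zeros((B, nc)), np.ones((B, nk))], axis=1)
            att_parts.append(cc.att_batch(g_sel, th_sel, y_sel))
        _log(f"chunk {ci + 1}/{len(starts)}: sampled {B} SNPs", verbose)

    counts = np.concatenate(counts_parts, axis=0)
    bins = {k: np.concatenate([bp[k] for bp in bin_parts], axis=0)
            for k in bin_parts[0]}

    results = {}
    need_snp1 = set(scores) & {"SNP1", "SUM", "MIX", "HET", "MIXGC"}
    snp1 = cc.snp1_batch(counts) if need_snp1 else None
    _log("SNP1 fits done" if need_snp1 else "SNP1 skipped", verbose)
    if "ATT" in scores:
        results["ATT"] = {k: np.concatenate([ap[k] for ap in att_parts])
                          for k in ("stat", "p", "status")}
        results["ATT"]["dof"] = 1
    if "SNP1" in scores:
        results["SNP1"] = snp1
    adm = None
    if set(scores) & {"ADM", "SUM", "ADMGC"}:
        adm = cc.adm_batch(bins)
        _log("ADM fits done", verbose)
    if "ADM" in scores:
        results["ADM"] = adm
    if "SUM" in scores:
        results["SUM"] = cc.sum_batch(snp1, adm)
    if "MIX" in scores:
        results["MIX"] = cc.mix_batch(counts, bins, snp1=snp1)
        _log("MIX fits done", verbose)
    if "HET" in scores:
        results["HET"] = cc.het_batch(counts, snp1=snp1)
        _log("HET fits done", verbose)
    summary_gc = None
    if set(scores) & {"ADMGC", "MIXGC"}:
        summary_gc = GenomeAncestrySummary.from_abar(
            bins["abar"], lambda_adm=lambda_gc(adm["stat"], 1) if adm else None)
    if "ADMGC" in scores:
        results["ADMGC"] = cc.admgc_batch(bins["abar"], summary_gc)
    if "MIXGC" in scores:
        results["MIXGC"] = cc.mixgc_batch(counts, bins, bins["abar"],
                                          summary_gc, snp1=snp1)
        _log("MIXGC fits done", verbose)

    summary = EvaluationSummary(n_snps=config.n_snps, scores=scores,
                                thresholds=thresholds)
    table = {} if return_table else None
    for s in scores:
        r = results[s]
        ok = (r["status"] == cc._OK) | (r["status"] == cc._NOCONV)
        summary.n_ok[s] = int(ok.sum())
        summary.mean_stat[s] = float(r["stat"][ok].mean()) if ok.any() else np.nan
        try:
            summary.lambda_gc[s] = lambda_gc(r["stat"][ok], r["dof"])
        except ValueError:
            summary.lambda_gc[s] = np.nan
        summary.power[s] = power(r["p"][ok], thresholds[s]) if ok.any() else np.nan
        if return_table:
            table[s] = r["stat"]
            table[f"p_{s}"] = r["p"]
    if return_table:
        return summary, pd.DataFrame(table)
    return summary


def _run_quantitative(config, scores, seed, chunk_size, thresholds,
                      return_table, verbose):
    scores = tuple(s for s in scores if s in QUANT_SCORES) or QUANT_SCORES
    thresholds = thresholds or default_thresholds(scores)
    seed = list(seed) if isinstance(seed, (list, tuple)) else [seed]
    theta = sim.draw_theta(config, np.random.default_rng(seed + [0]))
    n_ind = theta.size
    ns = min(config.n_samples_quant, n_ind)
    eps = config.effect_size if config.phenotype_model == "quantitative" else 0.0
    parts = []
    starts = list(range(0, config.n_snps, chunk_size))
    for ci, start in enumerate(starts):
        B = min(chunk_size, config.n_snps - start)
        rng_c = np.random.default_rng(seed + [1, ci])
        rng_p = np.random.default_rng(seed + [2, ci])
        pa, pe = sim.draw_frequencies(config, rng_c, n=B)
        N = sim._draw_local_ancestry(config, theta, B, rng_c)
        g = sim._draw_genotypes(N, pa, pe, rng_c)
        u = rng_p.random((B, n_ind))
        sel = np.argpartition(u, ns - 1, axis=1)[:, :ns]
        g_sel = np.take_along_axis(g, sel, axis=1).astype(float)
        N_sel = np.take_along_axis(N, sel, axis=1).astype(float)
        th_sel = theta[sel]
        y = eps * g_sel + rng_p.standard_normal((B, ns))
        y = y - y.mean(axis=1, keepdims=True)
        parts.append(qt.qscores_batch(g_sel, N_sel, th_sel, y))
        _log(f"chunk {ci + 1}/{len(starts)}: scored {B} SNPs", verbose)

    summary = EvaluationSummary(n_snps=config.n_snps, scores=scores,
                                thresholds=thresholds)
    table = {} if return_table else None
    for s in scores:
        stat = np.concatenate([p[s] for p in parts])
        ok = np.concatenate([p["ok"][s] for p in parts])
        dof = parts[0]["dof"][s]
        pv = chi2.sf(stat, dof)
        summary.n_ok[s] = int(ok.sum())
        summary.mean_stat[s] = float(stat[ok].mean()) if ok.any() else np.nan
        try:
            summary.lambda_gc[s] = lambda_gc(stat[ok], dof)
        except ValueError:
            summary.lambda_gc[s] = np.nan
        summary.power[s] = power(pv[ok], thresholds[s]) if ok.any() else np.nan
        if return_table:
            table[s] = stat
            table[f"p_{s}"] = pv
    if return_table:
        return summary, pd.DataFrame(table)
    return summary
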
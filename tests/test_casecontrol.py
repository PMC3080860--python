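"""Tests of the case-control scores: examples, oracles and invariances."""

import numpy as np
import pytest

import oracles
import admixscore as ax
from admixscore import casecontrol as cc
from admixscore.types import AncestryProfile, GenomeAncestrySummary, Status

MISSING = 9


class TestTabulateCounts:
    def test_two_individuals_two_cells(self):
        counts = ax.tabulate_counts([2, 0], [0, 2], [1, 0])
        assert counts.n[0, 1, 2] == 1       # case, AA, g=2
        assert counts.n[2, 0, 0] == 1       # control, EE, g=0
        assert counts.total == 2

    def test_totals_conserve_complete_data(self, rng):
        g = rng.integers(0, 3, 200)
        l = rng.integers(0, 3, 200)
        y = rng.integers(0, 2, 200).astype(float)
        g[:13] = MISSING
        y[13:20] = np.nan
        counts = ax.tabulate_counts(g, l, y)
        assert counts.total == 200 - 20

    def test_missing_ancestry_excluded(self):
        counts = ax.tabulate_counts([1, 1], [MISSING, 1], [1, 1])
        assert counts.total == 1


class TestATT:
    def test_constant_theta_equals_unadjusted_trend(self, rng):
        n = 300
        g = rng.integers(0, 3, n).astype(float)
        y = rng.integers(0, 2, n).astype(float)
        theta = np.full(n, 0.25)
        res = ax.score_att(g, y, theta)
        r = np.corrcoef(g, y)[0, 1]
        assert res.statistic == pytest.approx((n - 2) * r ** 2, abs=1e-8)

    def test_matches_statsmodels_partial_regression(self, rng):
        import statsmodels.api as sm
        n = 400
        theta = rng.uniform(0, 1, n)
        g = rng.binomial(2, 0.3 + 0.3 * theta).astype(float)
        y = rng.integers(0, 2, n).astype(float)
        X = sm.add_constant(theta)
        gr = g - sm.OLS(g, X).fit().fittedvalues
        yr = y - sm.OLS(y, X).fit().fittedvalues
        r2 = np.corrcoef(gr, yr)[0, 1] ** 2
        res = ax.score_att(g, y, theta)
        assert res.statistic == pytest.approx((n - 2) * r2, abs=1e-8)

    def test_null_mean_statistic_near_one(self, rng):
        # 1,000 permutation replicates of 2,000 individuals
        n, reps = 2000, 1000
        theta = rng.uniform(0.05, 0.5, n)
        g = rng.binomial(2, 0.2 + 0.5 * theta, size=(reps, n)).astype(float)
        y = np.tile(np.r_[np.zeros(n // 2), np.ones(n // 2)], (reps, 1))
        for row in y:
            rng.shuffle(row)
        batch = cc.att_batch(g, np.tile(theta, (reps, 1)), y)
        assert batch["stat"].mean() == pytest.approx(1.0, abs=0.1)

    def test_constant_genotype_is_monomorphic(self):
        res = ax.score_att(np.ones(50), np.r_[np.zeros(25), np.ones(25)],
                           np.linspace(0.1, 0.9, 50))
        assert res.status == Status.MONOMORPHIC

    def test_accepts_real_dosages(self, rng):
        n = 200
        d = rng.uniform(0, 2, n)
        y = rng.integers(0, 2, n).astype(float)
        res = ax.score_att(d, y, rng.uniform(0, 1, n))
        assert res.status == Status.OK and res.statistic >= 0


class TestSNP1:
    def test_proportional_case_control_counts_fit_null(self):
        counts = np.zeros((3, 2, 3))
        counts[0, 0] = [10, 20, 10]; counts[0, 1] = [5, 10, 5]
        counts[1, 0] = [8, 12, 4];   counts[1, 1] = [4, 6, 2]
        counts[2, 0] = [2, 6, 8];    counts[2, 1] = [1, 3, 4]
        res = ax.score_snp1(counts)
        assert res.statistic == pytest.approx(0.0, abs=1e-6)
        assert res.estimates["R"] == pytest.approx(1.0, abs=1e-3)

    def test_single_stratum_equals_binomial_lr_oracle(self, rng):
        # counts confined to AA reduce to a one-population 2-parameter problem
        counts = np.zeros((3, 2, 3))
        counts[0, 0] = rng.integers(5, 30, 3)
        counts[0, 1] = rng.integers(5, 30, 3)
        stat, _, _ = oracles.snp1_stat_oracle(counts, pts=31)
        res = ax.score_snp1(counts)
        assert res.statistic == pytest.approx(stat, abs=1e-4)

    def test_grid_oracle_agreement(self, random_counts):
        for _ in range(8):
            counts = random_counts()
            stat, _, _ = oracles.snp1_stat_oracle(counts)
            assert ax.score_snp1(counts).statistic == pytest.approx(stat, abs=1e-3)

    def test_monomorphic_table_flagged(self):
        counts = np.zeros((3, 2, 3))
        counts[:, :, 0] = 10
        res = ax.score_snp1(counts)
        assert res.status == Status.MONOMORPHIC and res.statistic == 0.0

    def test_rsq_one_equals_unadjusted(self, random_counts):
        counts = random_counts()
        plain = ax.score_snp1(counts)
        adj = ax.score_snp1(counts, rsq=(1.0, 1.0))
        assert adj.statistic == pytest.approx(plain.statistic, abs=1e-6)

    def test_rsq_attenuation_shrinks_signal(self):
        counts = np.zeros((3, 2, 3))
        counts[0, 0] = [40, 40, 20]
        counts[0, 1] = [10, 40, 50]     # strong case shift
        counts[2, 0] = [10, 20, 10]
        counts[2, 1] = [5, 15, 20]
        plain = ax.score_snp1(counts)
        adj = ax.score_snp1(counts, rsq=(0.5, 0.5))
        assert plain.statistic > 0
        assert adj.estimates["R"] > plain.estimates["R"]  # R compensates shrink


class TestADM:
    def test_symmetric_cases_give_null(self):
        prof = AncestryProfile(np.array([0.5, 0.5]), np.array([0, 2]))
        res = ax.score_adm(prof)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.estimates["Omega"] == pytest.approx(1.0, abs=1e-4)

    def test_exact_match_of_ancestry_gives_zero(self):
        # per-allele European fraction equals θ exactly
        prof = AncestryProfile(np.full(40, 0.5), np.ones(40, dtype=int))
        assert ax.score_adm(prof).statistic == pytest.approx(0.0, abs=1e-9)

    def test_single_case_hits_upper_bound(self):
        prof = AncestryProfile(np.array([0.5]), np.array([2]))
        res = ax.score_adm(prof)
        # closed form at Ω = 100: 2·[2 ln q(100) − 2 ln 0.5]
        assert res.statistic == pytest.approx(4 * np.log(200 / 101), abs=1e-6)
        assert res.estimates["Omega"] == pytest.approx(100.0, rel=1e-3)

    def test_grid_oracle_agreement(self, random_profile):
        for _ in range(5):
            theta, n_eur = random_profile(60)
            stat = oracles.adm_stat_oracle(theta, n_eur)
            res = ax.score_adm(AncestryProfile(theta, n_eur))
            assert res.statistic == pytest.approx(stat, abs=1e-3)

    def test_no_informative_cases_degenerate(self):
        prof = AncestryProfile(np.array([0.0, 1.0]), np.array([0, 2]))
        assert ax.score_adm(prof).status == Status.DEGENERATE


class TestSUM:
    def test_zero_plus_zero(self, random_counts, random_profile):
        counts = np.zeros((3, 2, 3))
        counts[0, 0] = [5, 5, 5]; counts[0, 1] = [5, 5, 5]
        s1 = ax.score_snp1(counts)
        adm = ax.score_adm(AncestryProfile(np.array([0.5] * 2), np.array([0, 2])))
        res = ax.score_sum(s1, adm)
        assert res.dof == 2 and res.statistic == pytest.approx(0.0, abs=1e-6)

    def test_chi2_two_dof_survival(self, random_counts, random_profile):
        counts = random_counts()
        theta, n_eur = random_profile()
        s1 = ax.score_snp1(counts)
        adm = ax.score_adm(AncestryProfile(theta, n_eur))
        res = ax.score_sum(s1, adm)
        assert res.statistic == pytest.approx(s1.statistic + adm.statistic)
        assert res.p_value == pytest.approx(np.exp(-res.statistic / 2), rel=1e-10)

    def test_known_value(self):
        # a 3.84 χ²(1) statistic loses significance on 2 dof: p ≈ 0.1466
        assert np.exp(-3.84 / 2) == pytest.approx(0.1466, abs=5e-4)

    def test_degenerate_propagates(self):
        from admixscore.types import ScoreResult
        bad = ScoreResult(0.0, 1, 1.0, {}, 0, Status.DEGENERATE)
        ok = ScoreResult(1.0, 1, 0.3, {}, 10, Status.OK)
        assert ax.score_sum(ok, bad).status == Status.DEGENERATE


class TestMIX:
    def test_null_counts_and_balanced_ancestry(self):
        counts = np.zeros((3, 2, 3))
        counts[0, 0] = [10, 20, 10]; counts[0, 1] = [10, 20, 10]
        counts[2, 0] = [10, 20, 10]; counts[2, 1] = [10, 20, 10]
        prof = AncestryProfile(np.full(40, 0.5), np.ones(40, dtype=int))
        assert ax.score_mix(counts, prof).statistic == pytest.approx(0.0, abs=1e-6)

    def test_mix_bounded_by_sum(self, random_counts, random_profile):
        # max of a sum never exceeds the sum of maxima
        for _ in range(10):
            counts = random_counts()
            theta, n_eur = random_profile()
            prof = AncestryProfile(theta, n_eur)
            mix = ax.score_mix(counts, prof).statistic
            s1 = ax.score_snp1(counts).statistic
            adm = ax.score_adm(prof).statistic
            assert mix <= s1 + adm + 1e-8

    def test_grid_oracle_agreement(self, random_counts, random_profile):
        for _ in range(6):
            counts = random_counts()
            theta, n_eur = random_profile()
            stat = oracles.mix_stat_oracle(counts, theta, n_eur)
            res = ax.score_mix(counts, AncestryProfile(theta, n_eur))
            assert res.statistic == pytest.approx(stat, abs=1e-3)


class TestHET:
    def test_nonnegative(self, random_counts):
        for _ in range(10):
            assert ax.score_het(random_counts()).statistic >= 0

    def test_grid_oracle_agreement(self, random_counts):
        for _ in range(6):
            counts = random_counts()
            stat = oracles.het_stat_oracle(counts)
            assert ax.score_het(counts).statistic == pytest.approx(stat, abs=1e-3)

    def test_absent_background_degenerate(self):
        counts = np.zeros((3, 2, 3))
        counts[0, 0] = [10, 10, 10]     # only African chromosomes anywhere
        counts[0, 1] = [10, 10, 10]
        assert ax.score_het(counts).status == Status.DEGENERATE


class TestAlleleRelabelInvariance:
    """Swapping the reference allele (g -> 2−g) relabels p -> 1−p and
    R -> 1/R and must leave every p-value unchanged."""

    @staticmethod
    def _flip(counts):
        return counts[:, :, ::-1].copy()

    def test_counts_scores_invariant(self, random_counts, random_profile):
        for _ in range(5):
            counts = random_counts()
            theta, n_eur = random_profile()
            prof = AncestryProfile(theta, n_eur)
            flipped = self._flip(counts)
            for fn in (ax.score_snp1, ax.score_het):
                assert fn(flipped).p_value == pytest.approx(
                    fn(counts).p_value, abs=1e-10)
            assert ax.score_mix(flipped, prof).p_value == pytest.approx(
                ax.score_mix(counts, prof).p_value, abs=1e-10)

    def test_att_invariant(self, rng):
        n = 500
        g = rng.integers(0, 3, n).astype(float)
        y = rng.integers(0, 2, n).astype(float)
        theta = rng.uniform(0, 1, n)
        a = ax.score_att(g, y, theta)
        b = ax.score_att(2 - g, y, theta)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-10)


class TestGCScores:
    def _summary(self, rng, n=300):
        abar = rng.normal(0.21, 0.01, n)
        return GenomeAncestrySummary.from_abar(abar)

    def test_admgc_anchor_points(self, rng):
        summary = self._summary(rng)
        assert ax.score_admgc(summary.mean, summary).statistic == 0.0
        res = ax.score_admgc(summary.mean + summary.sd, summary)
        assert res.statistic == pytest.approx(1.0, abs=1e-12)

    def test_admgc_requires_genome_wide_pass(self, rng):
        small = GenomeAncestrySummary.from_abar(rng.normal(0.2, 0.01, 50))
        with pytest.raises(ValueError):
            ax.score_admgc(0.2, small)

    def test_admgc_equivalent_to_adm_over_lambda_fixed_cases(self, rng):
        # with one case set across the genome (the real-data regime) the
        # z-score form tracks ADM divided by its lambda almost perfectly
        from scipy.stats import spearmanr
        from admixscore import evaluation as ev
        theta = np.clip(rng.beta(1.88, 7.9, 4000), 0.001, 0.999)
        cases = rng.choice(4000, 800, replace=False)
        tc = theta[cases]
        B = 1500
        N = rng.binomial(2, tc, size=(B, tc.size)).astype(float)
        bins = cc.profile_bins(np.broadcast_to(tc, (B, tc.size)), N, n_bins=128)
        adm = cc.adm_batch(bins)
        lam = ev.lambda_gc(adm["stat"], 1)
        summary = GenomeAncestrySummary.from_abar(bins["abar"], lambda_adm=lam)
        admgc = cc.admgc_batch(bins["abar"], summary)
        rho = spearmanr(admgc["stat"], adm["stat"] / lam).statistic
        assert rho > 0.99
        assert ev.lambda_gc(admgc["stat"], 1) == pytest.approx(1.0, abs=0.05)

    def test_mixgc_null_anchors_at_genome_mean(self, random_counts, rng):
        # when the SNP's mean case ancestry equals mu-bar and the table is
        # null, MIXGC collapses to ~0 like MIX
        counts = np.zeros((3, 2, 3))
        counts[0, 0] = [20, 40, 20]; counts[0, 1] = [20, 40, 20]
        counts[1, 0] = [10, 20, 10]; counts[1, 1] = [10, 20, 10]
        summary = self._summary(rng)
        theta = np.full(100, summary.mean)
        n_eur = rng.binomial(2, summary.mean, 100)
        prof = AncestryProfile(theta, n_eur)
        bins = cc.profile_bins(theta[None], n_eur[None].astype(float))
        abar = np.atleast_1d(n_eur.mean() / 2)
        res = cc.mixgc_batch(counts[None], bins, abar, summary)
        mix = ax.score_mix(counts, prof)
        assert res["stat"][0] >= 0
        assert abs(res["stat"][0] - mix.statistic) < 2.0

    def test_mixgc_grid_oracle(self, random_counts, rng):
        # summary scaled to the profiles' own ancestry level so the normal
        # admixture term is informative but not needle-sharp
        summary = GenomeAncestrySummary.from_abar(rng.normal(0.5, 0.04, 300))
        for _ in range(4):
            counts = random_counts()
            theta = rng.uniform(0.3, 0.7, 50)
            n_eur = rng.binomial(2, theta)
            bins = cc.profile_bins(theta[None], n_eur[None].astype(float))
            abar = np.atleast_1d(n_eur.mean() / 2)
            res = cc.mixgc_batch(counts[None], bins, abar, summary)

            inv2s2 = 1 / (2 * summary.sd ** 2)
            tcl = np.clip(theta, 1e-6, 1 - 1e-6)

            def gc_part(om):
                q = tcl * om[..., None] / (tcl * om[..., None] + 1 - tcl)
                mu = summary.mean + q.mean(axis=-1) - tcl.mean()
                return -((abar[0] - mu) ** 2) * inv2s2

            def f(lr, pa, pe):
                R = np.exp(lr)
                om = (1 - pe + R * pe) / (1 - pa + R * pa)
                return oracles.snp1_loglik_oracle(counts, R, pa, pe) + gc_part(om)

            alt = oracles.refine_max(f, [(oracles.LOG_OR_LO, oracles.LOG_OR_HI),
                                         oracles.FREQ_BOX, oracles.FREQ_BOX],
                                     n_refine=4)
            _, _, null_snp1 = oracles.snp1_stat_oracle(counts)
            null = null_snp1 + gc_part(np.array(1.0))
            assert res["stat"][0] == pytest.approx(2 * (alt - null), abs=1e-3)


class TestBatchMatchesPerSnp:
    def test_batch_and_single_agree(self, random_counts, random_profile):
        tables = np.stack([random_counts() for _ in range(8)])
        profs = [random_profile(40) for _ in range(8)]
        theta = np.stack([p[0] for p in profs])
        n_eur = np.stack([p[1] for p in profs]).astype(float)
        bins = cc.profile_bins(theta, n_eur)
        snp1 = cc.snp1_batch(tables)
        mix = cc.mix_batch(tables, bins, snp1=snp1)
        het = cc.het_batch(tables, snp1=snp1)
        adm = cc.adm_batch(bins)
        for i in range(8):
            prof = AncestryProfile(theta[i], n_eur[i].astype(int))
            assert ax.score_snp1(tables[i]).statistic == pytest.approx(
                snp1["stat"][i], abs=1e-6)
            assert ax.score_mix(tables[i], prof).statistic == pytest.approx(
                mix["stat"][i], abs=1e-6)
            assert ax.score_het(tables[i]).statistic == pytest.approx(
                het["stat"][i], abs=1e-6)
            assert ax.score_adm(prof).statistic == pytest.approx(
                adm["stat"][i], abs=1e-6)


class TestScoreDataset:
    def test_small_dataset_roundtrip(self, rng):
        from admixscore import simulate as sim
        cfg = sim.SimulationConfig(n_snps=120, n_individuals=160, n_cases=40,
                                   n_controls=40, phenotype_model="case_control",
                                   odds_ratio=1.5, seed=7)
        freqs = sim.draw_frequencies(cfg, 1)
        g, l, t = sim.draw_cohort(cfg, freqs, 2)
        y = sim.simulate_case_control(g.values[0].astype(float), cfg, 3)
        table = ax.score_dataset(g, l, t, y, gc=True)
        assert len(table) == 120
        assert {"ATT", "SNP1", "ADM", "SUM", "MIX", "HET", "ADMGC",
                "MIXGC"} <= set(table.columns)
        # SUM is SNP1 + ADM by construction
        np.testing.assert_allclose(table["SUM"], table["SNP1"] + table["ADM"],
                                   atol=1e-8)
        # MIX never exceeds SUM
        assert (table["MIX"] <= table["SUM"] + 1e-8).all()
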
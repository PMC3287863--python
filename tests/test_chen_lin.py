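"""CPG likelihood, logistic arm, homogeneity test and weighted combination."""

import numpy as np
import pytest
from scipy import stats

import famcombine as fc
from famcombine.chen_lin import (
    BETA_CAP,
    CCFit,
    CPGFit,
    cpg_score_info,
    chen_lin_test,
    transmission_probs,
)
from famcombine.core import Status


def grid_search_cpg(g_f, g_m, g_o, lo=-5.0, hi=5.0, step=1e-4):
    """Independent oracle: dense grid maximization of the CPG likelihood,
    written directly from its closed form via logsumexp (trios aggregated by
    mating type so the full 1e-4 grid is cheap)."""
    from scipy.special import logsumexp

    grid = np.arange(lo, hi + step, step)
    tau = transmission_probs(g_f, g_m)
    types, counts = np.unique(tau, axis=0, return_counts=True)
    with np.errstate(divide="ignore"):
        log_tau = np.log(types)  # -inf where unreachable
    k = np.arange(3.0)
    # log normalizer per (grid point, mating type)
    log_z = logsumexp(log_tau[None, :, :] + grid[:, None, None] * k, axis=2)
    const = np.log(tau[np.arange(len(g_o)), np.asarray(g_o)]).sum()
    ll = const + grid * np.sum(g_o) - log_z @ counts
    return grid[int(np.argmax(ll))]


def simulate_case_trios(n, maf, beta, rng):
    """Case trios drawn from the CPG model itself: HWE parents, offspring
    genotype from the exp(beta*g)-tilted Mendelian law."""
    f = rng.binomial(2, maf, size=n)
    m = rng.binomial(2, maf, size=n)
    tau = transmission_probs(f, m)
    w = tau * np.exp(beta * np.arange(3.0))
    w /= w.sum(axis=1, keepdims=True)
    u = rng.random(n)
    o = (u[:, None] > np.cumsum(w, axis=1)[:, :2]).sum(axis=1)
    return f, m, o


class TestCPGLoglik:
    def test_het_by_het_null_is_mendelian_half(self):
        assert fc.cpg_loglik(0.0, [1], [1], [1]) == pytest.approx(np.log(0.5))

    def test_het_by_homref_tilted(self):
        # e^b * 1/2 / (1/2 + e^b * 1/2) with b = log 2 -> 2/3
        assert fc.cpg_loglik(np.log(2), [1], [0], [1]) == pytest.approx(np.log(2 / 3))

    def test_null_loglik_is_mendelian_probability(self, rng):
        f, m, o = simulate_case_trios(50, 0.3, 0.0, rng)
        tau = transmission_probs(f, m)
        expected = np.log(tau[np.arange(50), o]).sum()
        assert fc.cpg_loglik(0.0, f, m, o) == pytest.approx(expected)

    def test_hom_by_hom_trios_contribute_constant(self):
        # both parents homozygous: likelihood does not depend on beta
        for b in (-2.0, 0.0, 3.0):
            assert fc.cpg_loglik(b, [0, 2], [0, 2], [0, 2]) == pytest.approx(0.0)


class TestFitCPG:
    def test_balanced_transmissions_give_zero(self):
        # Aa x aa trios, minor allele transmitted exactly half the time
        f = np.ones(10, dtype=int)
        m = np.zeros(10, dtype=int)
        o = np.array([1, 0] * 5)
        fit = fc.fit_cpg(f, m, o)
        assert fit.status == Status.OK
        assert fit.beta_hat == pytest.approx(0.0, abs=1e-10)

    def test_fourteen_of_twenty_transmissions_match_grid_oracle(self):
        f = np.ones(20, dtype=int)
        m = np.zeros(20, dtype=int)
        o = np.array([1] * 14 + [0] * 6)
        fit = fc.fit_cpg(f, m, o)
        assert fit.beta_hat == pytest.approx(grid_search_cpg(f, m, o), abs=1e-4)
        # binary-transmission closed form: log(b/c)
        assert fit.beta_hat == pytest.approx(np.log(14 / 6), abs=1e-6)

    def test_matches_grid_oracle_on_many_random_instances(self):
        """Newton maximizer agrees with a 1e-4 grid search across >= 50
        random trio datasets spanning MAFs and effect sizes."""
        rng = np.random.default_rng(2026)
        checked = 0
        while checked < 50:
            maf = rng.uniform(0.05, 0.5)
            beta = rng.uniform(-1.5, 1.5)
            n = rng.integers(10, 80)
            f, m, o = simulate_case_trios(int(n), maf, beta, rng)
            fit = fc.fit_cpg(f, m, o)
            if fit.status != Status.OK or abs(fit.beta_hat) > 4.5:
                continue
            assert fit.beta_hat == pytest.approx(
                grid_search_cpg(f, m, o), abs=1e-4
            )
            checked += 1

    def test_hom_by_hom_only_is_uninformative(self):
        fit = fc.fit_cpg([0, 2], [0, 0], [0, 1])
        assert fit.status == Status.NO_INFORMATIVE_TRIOS
        assert fit.n_informative_trios == 0

    def test_one_sided_transmissions_flagged_degenerate(self):
        f = np.ones(8, dtype=int)
        m = np.zeros(8, dtype=int)
        o = np.ones(8, dtype=int)  # minor allele always transmitted
        assert fc.fit_cpg(f, m, o).status == Status.DEGENERATE

    def test_tdt_score_structure_at_null(self):
        """With only Aa x aa parents the CPG score test at beta = 0 is the
        transmission count contrast: score = (b - c)/2, information n/4, so
        score^2/info = (b - c)^2/(b + c) — the TDT statistic."""
        for b, c in [(14, 6), (3, 9), (10, 10)]:
            f = np.ones(b + c, dtype=int)
            m = np.zeros(b + c, dtype=int)
            o = np.array([1] * b + [0] * c)
            score, info = cpg_score_info(0.0, f, m, o)
            assert score == pytest.approx((b - c) / 2)
            assert info == pytest.approx((b + c) / 4)
            assert score**2 / info == pytest.approx((b - c) ** 2 / (b + c))


class TestLogisticArm:
    def test_symmetric_counts_give_zero(self):
        y = np.array([1] * 20 + [0] * 20)
        g = np.array([0] * 10 + [1] * 10 + [0] * 10 + [1] * 10)
        fit = fc.fit_cc_logistic(y, g)
        assert fit.beta_hat == pytest.approx(0.0, abs=1e-8)

    def test_two_by_two_closed_form_odds_ratio(self):
        y = np.repeat([1, 1, 0, 0], [30, 70, 10, 90])
        g = np.repeat([1, 0, 1, 0], [30, 70, 10, 90])
        fit = fc.fit_cc_logistic(y, g)
        assert fit.beta_hat == pytest.approx(np.log(30 * 90 / (70 * 10)), abs=1e-6)
        assert (fit.n_cases, fit.n_controls) == (100, 100)

    def test_constant_genotype_degenerate(self):
        fit = fc.fit_cc_logistic(np.array([1, 0, 1, 0]), np.zeros(4))
        assert fit.status == Status.DEGENERATE

    def test_separation_degenerate(self):
        y = np.array([1] * 10 + [0] * 10)
        g = np.array([2] * 10 + [0] * 10)
        assert fc.fit_cc_logistic(y, g).status == Status.DEGENERATE


class TestCrossCovariance:
    def test_disjoint_samples_give_exact_zero(self, rng):
        f, m, o = simulate_case_trios(40, 0.3, 0.0, rng)
        cpg = fc.fit_cpg(f, m, o)
        y = rng.integers(0, 2, 200)
        g = rng.binomial(2, 0.3, 200)
        cc = fc.fit_cc_logistic(y, g)
        rows = np.full(40, -1)  # no proband appears in the CC arm
        assert fc.cross_covariance(cpg, cc, f, m, o, rows) == 0.0

    def test_agrees_with_bootstrap_over_units(self):
        """Influence-function cross-covariance vs a bootstrap over independent
        units (trios and unrelated subjects) on one mixed sample."""
        rng = np.random.default_rng(8)
        n_t, n_u = 120, 240
        f, m, o = simulate_case_trios(n_t, 0.35, 0.3, rng)
        g_u = rng.binomial(2, 0.35, n_u)
        y_u = np.zeros(n_u)  # unrelated controls
        y_cc = np.concatenate([np.ones(n_t), y_u])
        g_cc = np.concatenate([o, g_u])

        cpg = fc.fit_cpg(f, m, o)
        cc = fc.fit_cc_logistic(y_cc, g_cc)
        rows = np.arange(n_t)
        cov_if = fc.cross_covariance(cpg, cc, f, m, o, rows)

        boots = []
        for _ in range(300):
            ti = rng.integers(0, n_t, n_t)
            ui = rng.integers(0, n_u, n_u)
            b_cpg = fc.fit_cpg(f[ti], m[ti], o[ti])
            b_cc = fc.fit_cc_logistic(
                np.concatenate([np.ones(n_t), y_u]),
                np.concatenate([o[ti], g_u[ui]]),
            )
            if b_cpg.status == Status.OK and b_cc.status == Status.OK:
                boots.append((b_cpg.beta_hat, b_cc.beta_hat))
        boots = np.array(boots)
        cov_boot = np.cov(boots.T)[0, 1]
        se = np.sqrt(
            (np.cov(boots.T)[0, 0] * np.cov(boots.T)[1, 1] + cov_boot**2)
            / len(boots)
        )
        assert cov_if == pytest.approx(cov_boot, abs=4 * se)
        # shared probands induce positive dependence, bounded correlation
        corr = cov_if / (cpg.se * cc.se)
        assert 0 < corr < 1

    def test_covariance_halves_when_units_double(self, rng):
        f, m, o = simulate_case_trios(100, 0.3, 0.2, rng)
        g_u = rng.binomial(2, 0.3, 150)
        y_cc = np.concatenate([np.ones(100), np.zeros(150)])
        g_cc = np.concatenate([o, g_u])
        cpg = fc.fit_cpg(f, m, o)
        cc = fc.fit_cc_logistic(y_cc, g_cc)
        cov1 = fc.cross_covariance(cpg, cc, f, m, o, np.arange(100))

        f2, m2, o2 = np.tile(f, 2), np.tile(m, 2), np.tile(o, 2)
        y2 = np.concatenate([np.ones(200), np.zeros(300)])
        g2 = np.concatenate([o2, np.tile(g_u, 2)])
        cpg2 = fc.fit_cpg(f2, m2, o2)
        cc2 = fc.fit_cc_logistic(y2, g2)
        cov2 = fc.cross_covariance(
            cpg2, cc2, f2, m2, o2, np.arange(200)
        )
        assert cov2 == pytest.approx(cov1 / 2, rel=0.05)


class TestHomogeneityAndCombination:
    def test_equal_estimates_never_rejected(self):
        a = CPGFit(0.4, 0.2, -10.0, 30)
        b = CCFit(0.4, 0.3, 50, 50)
        stat, p = fc.homogeneity_wald(a, b, 0.0)
        assert stat == 0.0 and p == 1.0

    def test_worked_wald_example(self):
        a = CPGFit(0.5, np.sqrt(0.04), -10.0, 30)
        b = CCFit(0.0, np.sqrt(0.05), 50, 50)
        stat, p = fc.homogeneity_wald(a, b, 0.0)
        assert stat == pytest.approx(0.25 / 0.09, rel=1e-12)
        assert p == pytest.approx(stats.chi2.sf(0.25 / 0.09, 1), rel=1e-12)
        assert p == pytest.approx(0.0956, abs=2e-3)

    def test_equal_variances_average_the_estimates(self):
        a = CPGFit(0.2, 0.2, -5.0, 20)
        b = CCFit(0.4, 0.2, 40, 40)
        res = fc.combine_and_test(a, b, 0.0, snp_id="s")
        assert not res.extras["homogeneity_rejected"]
        assert res.extras["w1"] == pytest.approx(0.5)
        assert res.estimate == pytest.approx(0.3)

    def test_inverse_variance_weights_closed_form(self):
        a = CPGFit(0.30, np.sqrt(0.04), -5.0, 20)
        b = CCFit(0.25, np.sqrt(0.01), 40, 40)
        res = fc.combine_and_test(a, b, 0.0, snp_id="s")
        assert not res.extras["homogeneity_rejected"]
        assert res.extras["w1"] == pytest.approx(0.2)
        assert res.extras["w2"] == pytest.approx(0.8)
        assert res.se == pytest.approx(np.sqrt(0.008))

    def test_both_null_estimates_give_p_one(self):
        a = CPGFit(0.0, 0.2, -5.0, 20)
        b = CCFit(0.0, 0.3, 40, 40)
        res = fc.combine_and_test(a, b, 0.0, snp_id="s")
        assert res.estimate == 0.0 and res.p_value == 1.0

    def test_combined_se_beats_both_components(self):
        """Weighted-LS efficiency: se_c <= min(se1, se2) when the cross
        covariance does not exceed the smaller variance."""
        rng = np.random.default_rng(4)
        for _ in range(25):
            se1, se2 = rng.uniform(0.05, 0.5, 2)
            cov = rng.uniform(0, min(se1, se2) ** 2)
            a = CPGFit(0.1, se1, -5.0, 20)
            b = CCFit(0.1, se2, 40, 40)
            res = fc.combine_and_test(a, b, cov, snp_id="s")
            assert res.p_value is not None
            assert res.se <= min(se1, se2) + 1e-12

    def test_homogeneity_rejection_falls_back_to_cpg(self):
        a = CPGFit(1.5, 0.1, -5.0, 20)
        b = CCFit(-1.5, 0.1, 40, 40)
        res = fc.combine_and_test(a, b, 0.0, snp_id="s")
        assert res.extras["homogeneity_rejected"]
        assert res.estimate == pytest.approx(1.5)
        assert res.statistic == pytest.approx((1.5 / 0.1) ** 2)


class TestEndToEnd:
    def test_full_pipeline_on_common_snp(self, small_design):
        sample, truth, _ = small_design
        j = int(np.argmax([t.maf for t in truth]))
        res = chen_lin_test(sample, j)
        assert res.status == Status.OK
        assert res.method == "chen_lin"
        assert 0 <= res.p_value <= 1
        assert res.extras["n_informative_trios"] >= 1
        assert res.homogeneity_p is not None

    def test_assume_independent_switch_zeroes_covariance(self, small_design):
        sample, truth, _ = small_design
        j = int(np.argmax([t.maf for t in truth]))
        res = chen_lin_test(sample, j, assume_independent=True)
        if res.status == Status.OK and not res.extras["homogeneity_rejected"]:
            assert res.extras["cross_cov"] == 0.0
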
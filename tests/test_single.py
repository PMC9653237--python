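"""Single-compartment closed forms against independent oracles.

Oracles used here: the Catalan closed form with exact integer Catalan
numbers (independent of the ratio recursion), numerically summed power
series (independent of the algebraic pgf), finite differences, and the
Monte-Carlo simulator (a separate code path).
"""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import cellcascade as cc
from cellcascade import FateProbs, Rates
from cellcascade.single import discriminant, tail_asymptote

SP4_RATES = Rates(lam=0.181, mu=0.040, nu=0.231)


def catalan_closed_form(fp: FateProbs, k_max: int) -> np.ndarray:
    """q_k = (p_b/Delta)^(k-1) (p_e/Delta)^k c_{k-1} with exact integer
    Catalan numbers c_{k-1} = comb(2k-2, k-1)/k; independent of the ratio
    recursion used by the implementation."""
    d = discriminant(fp)
    out = np.empty(k_max)
    for k in range(1, k_max + 1):
        c = math.comb(2 * k - 2, k - 1) // k
        out[k - 1] = float(c) * (fp.p_b / d) ** (k - 1) * (fp.p_e / d) ** k
    return out


subcritical = st.builds(
    lambda b, frac: FateProbs(p_b=b, p_d=frac * (1.0 - b) * 0.999),
    b=st.floats(0.01, 0.48),
    frac=st.floats(0.0, 1.0),
)


class TestFateProbConstruction:
    @pytest.mark.parametrize(
        "rates, pb, pd",
        [
            (SP4_RATES, 0.4004, 0.0885),
            (Rates(lam=0.085, mu=0.110, nu=0.152), 0.2449, 0.3170),
            (Rates(lam=1, mu=1, nu=1), 1 / 3, 1 / 3),
        ],
    )
    def test_from_rates(self, rates, pb, pd):
        fp = cc.fate_probs_from_rates(rates)
        assert fp.p_b == pytest.approx(pb, abs=1e-4)
        assert fp.p_d == pytest.approx(pd, abs=1e-4)
        assert fp.p_b + fp.p_d + fp.p_e == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "N, p_d, pb",
        [(25, 0.0, 0.4898), (5, 0.0, 0.4444), (1, 0.0, 0.0)],
    )
    def test_from_N_pd(self, N, p_d, pb):
        fp = cc.fate_probs_from_N_pd(N, p_d)
        assert fp.p_b == pytest.approx(pb, abs=5e-5)
        assert cc.amplification(fp) == pytest.approx(N, rel=1e-12)

    def test_caption_division_probability_implies_N(self):
        # ten-stage cascade building block: p_b = 0.2158 at zero death
        fp = FateProbs(p_b=0.2158, p_d=0.0)
        assert cc.amplification(fp) == pytest.approx(1.38, abs=0.005)

    def test_from_N_pd_singularity(self):
        with pytest.raises(cc.ParameterError):
            cc.fate_probs_from_N_pd(0.5, 0.0)

    def test_supercritical_rejected(self):
        with pytest.raises(cc.SupercriticalError):
            FateProbs(p_b=0.5, p_d=0.2, p_e=0.3)
        with pytest.raises(cc.SupercriticalError):
            FateProbs(p_b=0.3, p_d=0.2, p_e=0.1, p_a=0.4)  # 2p_b + p_a = 1

    def test_probability_sum_enforced(self):
        with pytest.raises(cc.ParameterError):
            FateProbs(p_b=0.2, p_d=0.2, p_e=0.2)

    def test_p_e_defaults_to_complement(self):
        fp = FateProbs(p_b=0.3, p_d=0.2)
        assert fp.p_e == pytest.approx(0.5, abs=1e-15)


class TestAmplification:
    def test_sp4_value(self, sp4):
        assert cc.amplification(sp4) == pytest.approx(2.57, abs=0.005)

    def test_sp8_below_one(self, sp8):
        assert cc.amplification(sp8) == pytest.approx(0.86, abs=0.005)

    @pytest.mark.parametrize(
        "p_a, p_d, expected",
        [(0.45, 0.55, 9 / 11), (0.1, 0.9, 1 / 9)],
    )
    def test_asymmetric_only_compartment(self, p_a, p_d, expected):
        fp = FateProbs(p_b=0.0, p_d=p_d, p_e=0.0, p_a=p_a)
        assert cc.amplification(fp) == pytest.approx(expected, rel=1e-14)


class TestExtinction:
    def test_no_death_never_extinct(self):
        assert cc.extinction_no_exit(FateProbs(p_b=0.4, p_d=0.0, p_e=0.6)) == 0.0

    def test_no_division_is_single_draw(self):
        fp = FateProbs(p_b=0.0, p_d=0.3, p_e=0.7)
        assert cc.extinction_no_exit(fp) == pytest.approx(0.3, abs=1e-15)

    def test_fixed_point_and_pgf_consistency(self, sp4):
        q0 = cc.extinction_no_exit(sp4)
        assert q0 == pytest.approx(sp4.p_d + sp4.p_b * q0**2, abs=1e-14)
        assert q0 == pytest.approx(cc.pgf_phi(sp4, 0.0), abs=1e-14)
        expected = 2 * 0.0885 / (1 + math.sqrt(1 - 4 * 0.0885 * 0.4004))
        assert q0 == pytest.approx(expected, abs=5e-5)

    def test_against_monte_carlo(self, sp4):
        s = cc.simulate_summary(cc.CompartmentChain((sp4,)), 50_000, rng_seed=11)
        se = math.sqrt(cc.extinction_no_exit(sp4) / 50_000)
        assert s.empirical_R_pmf.probs[0] == pytest.approx(
            cc.extinction_no_exit(sp4), abs=4 * se
        )


class TestPGF:
    def test_normalization_and_derivative(self, sp4):
        assert cc.pgf_phi(sp4, 1.0) == pytest.approx(1.0, abs=1e-12)
        h = 1e-6
        deriv = (cc.pgf_phi(sp4, 1.0) - cc.pgf_phi(sp4, 1.0 - h)) / h
        assert deriv == pytest.approx(cc.amplification(sp4), rel=1e-4)

    def test_matches_summed_series(self, sp4):
        pmf = cc.family_size_pmf(sp4, 10_000)
        for z in np.arange(0.1, 1.0, 0.1):
            series = float(np.polynomial.polynomial.polyval(z, pmf.probs))
            assert series == pytest.approx(cc.pgf_phi(sp4, z), abs=1e-10)

    def test_beyond_singularity_raises(self, sp4):
        with pytest.raises(cc.PGFDomainError):
            cc.pgf_phi(sp4, 3.0)

    def test_no_division_linear_limit(self):
        fp = FateProbs(p_b=0.0, p_d=0.55, p_e=0.0, p_a=0.45)
        z = 0.7
        assert cc.pgf_phi(fp, z) == pytest.approx(
            (0.55) / (1 - 0.45 * z), rel=1e-12
        )


class TestFamilySizePmf:
    def test_first_terms(self, sp4):
        pmf = cc.family_size_pmf(sp4, 100)
        assert pmf.probs[0] == pytest.approx(cc.extinction_no_exit(sp4), abs=1e-15)
        assert pmf.probs[1] == pytest.approx(sp4.p_e / discriminant(sp4), abs=1e-15)

    def test_recursion_equals_catalan_closed_form(self, sp4):
        """Ratio recursion reproduces the closed form to 12 digits, k <= 500."""
        pmf = cc.family_size_pmf(sp4, 500)
        expected = catalan_closed_form(sp4, 500)
        np.testing.assert_allclose(pmf.probs[1:], expected, rtol=1e-12)

    def test_mean_is_amplification(self, sp4):
        pmf = cc.family_size_pmf(sp4, 5000)
        assert pmf.tail_mass < 1e-12
        assert pmf.mean() == pytest.approx(cc.amplification(sp4), rel=1e-9)

    def test_tail_mass_decreases_with_K(self, sp4):
        tails = [cc.family_size_pmf(sp4, K).tail_mass for K in (10, 50, 200, 1000)]
        assert all(a > b for a, b in zip(tails, tails[1:]))

    def test_negative_K_rejected(self, sp4):
        with pytest.raises(cc.ParameterError):
            cc.family_size_pmf(sp4, -1)

    def test_matches_monte_carlo_histogram(self, sp4):
        n = 100_000
        s = cc.simulate_summary(cc.CompartmentChain((sp4,)), n, rng_seed=42)
        exact = cc.family_size_pmf(sp4, 200).probs
        emp = s.empirical_R_pmf.probs
        width = max(exact.size, emp.size)
        tv = 0.5 * np.abs(
            np.pad(exact, (0, width - exact.size)) - np.pad(emp, (0, width - emp.size))
        ).sum()
        # expected TV for a multinomial sample of this size; documented margin
        assert tv < 0.02


class TestVariance:
    def test_bernoulli_exit_limit(self):
        fp = FateProbs(p_b=0.0, p_d=0.4, p_e=0.6)
        assert cc.variance_R(fp) == pytest.approx(0.6 * 0.4, abs=1e-14)

    def test_closed_forms_agree(self, sp4, sp8):
        for fp in (sp4, sp8):
            n = cc.amplification(fp)
            eq_a = 2 * fp.p_b / fp.p_e * n**3 + n - n * n
            eq_b = 2 / (1 - 2 * fp.p_d) * (n - 1 + fp.p_d) * n**2 + n - n * n
            assert cc.variance_R(fp) == pytest.approx(eq_a, rel=1e-12)
            assert cc.variance_R(fp) == pytest.approx(eq_b, rel=1e-12)

    def test_against_monte_carlo(self, sp4):
        n_fam = 100_000
        s = cc.simulate_summary(cc.CompartmentChain((sp4,)), n_fam, rng_seed=7)
        v = cc.variance_R(sp4)
        # SE of the sample variance ~ sqrt((m4 - v^2)/n); bound m4 via the pmf
        pmf = cc.family_size_pmf(sp4, 2000)
        mu = cc.amplification(sp4)
        m4 = float(np.dot((pmf.support - mu) ** 4, pmf.probs))
        se = math.sqrt((m4 - v * v) / n_fam)
        assert s.var_R == pytest.approx(v, abs=3 * se)


class TestTailConstant:
    def test_direct_formula(self):
        fp = FateProbs(p_b=0.45, p_d=0.0, p_e=0.55)
        assert cc.tail_constant_gamma1(fp) == pytest.approx(0.99, abs=1e-12)

    def test_sp4_value_and_large_k_ratio(self, sp4):
        g = cc.tail_constant_gamma1(sp4)
        expected = 4 * 0.4004 * 0.5111 / (1 - 4 * 0.0885 * 0.4004)
        assert g == pytest.approx(expected, abs=1e-4)
        pmf = cc.family_size_pmf(sp4, 1200)
        k = np.arange(1000, 1199)
        ratio = pmf.probs[k + 1] / pmf.probs[k] * (1 + 1 / k) ** 1.5
        np.testing.assert_allclose(ratio, g, rtol=1e-6)

    def test_large_N_approximation(self):
        fp = cc.fate_probs_from_N_pd(50.0, 0.0)
        n = cc.amplification(fp)
        approx = 1 - (1 - 2 * fp.p_d) / (4 * n * n)
        assert cc.tail_constant_gamma1(fp) == pytest.approx(approx, abs=1e-4)

    def test_asymptote_approached_from_above(self, sp4):
        """q_k exceeds the gamma_1^k k^(-3/2) form and converges to it."""
        pmf = cc.family_size_pmf(sp4, 2000)
        k = np.arange(10, 2001)
        ratio = pmf.probs[10:] / tail_asymptote(sp4, k)
        assert np.all(ratio > 1.0)
        assert ratio[-1] == pytest.approx(1.0, abs=2e-3)
        assert np.all(np.diff(ratio) < 1e-12)  # monotone decrease toward 1

    def test_two_regime_crossover(self):
        """Per-step decay of q_k is dominated by the k^(-3/2) factor below the
        crossover 3/(2 |ln gamma_1|) and by the geometric factor above it;
        for large N this crossover is the familiar 6N^2/(1-2p_d)."""
        fp = cc.fate_probs_from_N_pd(25.0, 0.0)
        g = cc.tail_constant_gamma1(fp)
        n = cc.amplification(fp)
        exact_cross = 1.5 / (-math.log(g))
        assert exact_cross == pytest.approx(6 * n * n / (1 - 2 * fp.p_d), rel=0.05)
        k = np.arange(2, 20_000)
        power_term = 1.5 * np.log(1 + 1 / k)
        geometric_term = -math.log(g)
        assert np.all(power_term[k < exact_cross * 0.95] > geometric_term)
        assert np.all(power_term[k > exact_cross * 1.05] < geometric_term)


class TestK50:
    @pytest.mark.parametrize("N, expected", [(10, 83), (100, 9009)])
    def test_published_values(self, N, expected):
        assert cc.k50(cc.fate_probs_from_N_pd(N, 0.0)) == expected

    def test_degenerate_all_singletons(self):
        assert cc.k50(FateProbs(p_b=0.0, p_d=0.0, p_e=1.0)) == 1

    def test_pmf_input_agrees(self):
        fp = cc.fate_probs_from_N_pd(10.0, 0.0)
        pmf = cc.family_size_pmf(fp, 2000)
        assert cc.k50(pmf, N=cc.amplification(fp)) == cc.k50(fp)

    @pytest.mark.parametrize(
        "N, printed", [(10, 71), (100, 7775)]
    )
    def test_analytic_bound_values(self, N, printed):
        assert cc.k50_analytic_bound(N, 0.0) == pytest.approx(printed, abs=1.0)

    @pytest.mark.parametrize("N, p_d", [(2.0, 0.0), (10.0, 0.1), (30.0, 0.2)])
    def test_bound_below_true_k50(self, N, p_d):
        fp = cc.fate_probs_from_N_pd(N, p_d)
        assert cc.k50(fp) > cc.k50_analytic_bound(N, p_d)

    def test_bound_requires_N_above_one(self):
        with pytest.raises(cc.ParameterError):
            cc.k50_analytic_bound(0.9)


class TestProperties:
    @given(fp=subcritical)
    def test_pmf_is_a_distribution_with_mean_N(self, fp):
        pmf = cc.family_size_pmf(fp, 4000)
        assert np.all(pmf.probs >= 0)
        assert pmf.probs.sum() <= 1 + 1e-9
        if pmf.tail_mass < 1e-10:
            assert pmf.mean() == pytest.approx(cc.amplification(fp), rel=1e-6)

    @given(fp=subcritical, z=st.floats(0.0, 1.0))
    def test_pgf_monotone_and_bounded(self, fp, z):
        val = cc.pgf_phi(fp, z)
        assert cc.extinction_no_exit(fp) - 1e-12 <= val <= 1 + 1e-12
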
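import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import forcemap.bayes_core as bc
from conftest import make_natural_parameters
from forcemap.local_stats import BinStatistics


def closed_form_minimum_log10(np_):
    """log10 of η^d[(v+η²ζ⊥²)/(v+ζ⊥²)]^{−κ}, the K^M floor at ζ_sp=ζ_par=0.

    With ζ_sp = 0 and no drift component along it, the whole total-drift
    signal is the orthogonal ζ⊥, i.e. |ζ_t|.
    """
    perp2 = np_.zeta_par**2 + np_.zeta_perp**2
    ratio = (np_.v + np_.eta**2 * perp2) / (np_.v + perp2)
    return (np_.d * math.log(np_.eta) - np_.kappa * math.log(ratio)) \
        / math.log(10.0)


class TestNaturalParameters:
    def test_eta_substitution(self):
        np_ = make_natural_parameters(n=497, d=2)
        assert np_.eta == pytest.approx(math.sqrt(3 / 500))

    def test_v_substitution_at_unit_u(self):
        st_ = BinStatistics(n=50, dr_mean=np.zeros(2), V=0.05, dt=0.04, d=2)
        np_ = bc.natural_parameters(st_, None, bc.PriorHyperparameters(u=1.0))
        assert np_.v == pytest.approx(1 + 3 / 50)

    def test_zero_mean_displacement_gives_zero_zetas(self):
        st_ = BinStatistics(n=50, dr_mean=np.zeros(2), V=0.05, dt=0.04, d=2)
        np_ = bc.natural_parameters(st_, np.array([0.5, 0.0]))
        assert np_.zeta_par == 0.0
        assert np_.zeta_perp == 0.0
        np.testing.assert_allclose(np_.zeta_t, 0.0)

    def test_pythagorean_split(self, rng):
        for _ in range(20):
            st_ = BinStatistics(n=30, dr_mean=rng.normal(0, 0.05, 2), V=0.04,
                                dt=0.04, d=2)
            np_ = bc.natural_parameters(st_, rng.normal(0, 0.3, 2))
            assert np_.zeta_par**2 + np_.zeta_perp**2 == pytest.approx(
                float(np_.zeta_t @ np_.zeta_t))

    def test_small_bin_excluded(self):
        st_ = BinStatistics(n=2, dr_mean=np.zeros(2), V=0.05, dt=0.04, d=2)
        with pytest.raises(ValueError):
            bc.natural_parameters(st_, None)

    def test_localization_correction_flags_noise_dominated(self):
        st_ = BinStatistics(n=50, dr_mean=np.zeros(2), V=0.001, dt=0.04, d=2)
        np_ = bc.natural_parameters(
            st_, None, bc.PriorHyperparameters(localization_sigma=0.03))
        assert np_.noise_dominated

    def test_sigma_zero_reproduces_uncorrected(self):
        V_eff, flag = bc.effective_variance(0.05, 2, 0.0)
        assert V_eff == 0.05 and not flag


class TestProperPriorScan:
    @pytest.mark.parametrize("d,expected", [(1, 4), (2, 3)])
    def test_minimal_proper_prior_strength(self, d, expected):
        assert bc.min_proper_n_pi(d) == expected
        assert bc.min_proper_n_pi(d, numeric=True) == expected

    def test_improper_n_pi_rejected(self):
        with pytest.raises(ValueError):
            bc.PriorHyperparameters(n_pi=2).resolve_n_pi(2)


class TestFixedLambdaBayesFactor:
    def test_lambda_independence_when_no_gradient(self):
        np_ = make_natural_parameters(zeta_perp=1.2, zeta_sp=0.0, n=200)
        vals = [bc.bayes_factor_fixed(np_, lam) for lam in (0.0, 0.5, 1.0)]
        km = bc.bayes_factor_marginalized(np_)
        for val in vals:
            assert val == pytest.approx(vals[0], abs=1e-12)
            assert km == pytest.approx(val, abs=1e-12)

    def test_null_data_floor_is_eta_to_the_d(self):
        for d in (1, 2):
            np_ = make_natural_parameters(d=d, n=100)
            n_pi = 4 if d == 1 else 3
            expected = (d / 2) * math.log10(n_pi / (100 + n_pi))
            assert bc.bayes_factor_fixed(np_, 0.5) == pytest.approx(expected)

    def test_monotone_in_shifted_norm(self):
        base = make_natural_parameters(zeta_sp=0.5, n=100)
        vals = [bc.bayes_factor_fixed(
            make_natural_parameters(zeta_par=zp, zeta_sp=0.5, n=100), 0.0)
            for zp in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals[-1] > bc.bayes_factor_fixed(base, 0.0)


class TestMarginalizedBayesFactor:
    def test_global_minimum_closed_form(self):
        # at ζ_sp = 0 and ζ_par = 0 the marginalized factor collapses to the
        # closed form, which is its global minimum over (ζ_sp, ζ_par)
        np0 = make_natural_parameters(zeta_perp=0.8, n=150)
        km0 = bc.bayes_factor_marginalized(np0)
        assert km0 == pytest.approx(closed_form_minimum_log10(np0), abs=1e-9)
        for zsp in (0.0, 0.3, 0.8):
            for zpar in (-0.5, 0.0, 0.4, 1.0):
                np_ = make_natural_parameters(zeta_par=zpar, zeta_perp=0.8,
                                              zeta_sp=zsp, n=150)
                assert bc.bayes_factor_marginalized(np_) >= km0 - 1e-9

    def test_absolute_minimum_is_eta_to_the_d(self):
        np_ = make_natural_parameters(n=100, d=2)
        assert bc.bayes_factor_marginalized(np_) == pytest.approx(
            math.log10(3 / 103), abs=1e-10)

    def test_weighted_average_identity(self):
        # K^M equals the mean of K(λ) weighted by the H0 integrand f0(λ)
        np_ = make_natural_parameters(zeta_par=0.7, zeta_perp=0.3,
                                      zeta_sp=0.9, n=60)
        lam = np.linspace(0, 1, 20001)
        sp = float(np.linalg.norm(np_.zeta_sp))
        q = (np_.zeta_par - lam * sp) ** 2 + np_.zeta_perp**2
        log_f0 = -np_.kappa * np.log(np_.v + q)
        w = np.exp(log_f0 - log_f0.max())
        # log10 K(λ) on the same grid, via the public fixed-λ closed form
        k_lam = 10.0 ** np.array(
            [bc.bayes_factor_fixed(np_, float(x)) for x in lam])
        km_avg = float(np.trapezoid(w * k_lam, lam)
                       / np.trapezoid(w, lam))
        assert 10.0 ** bc.bayes_factor_marginalized(np_) == pytest.approx(
            km_avg, rel=1e-6)

    def test_evidence_identity(self):
        np_ = make_natural_parameters(zeta_par=0.4, zeta_sp=0.6, n=40)
        km = (bc.log_evidence(np_, "H1") - bc.log_evidence(np_, "H0")) \
            / math.log(10)
        assert bc.bayes_factor_marginalized(np_) == pytest.approx(
            km, abs=1e-12)

    def test_data_dominance(self):
        # fixed nonzero residual: evidence for a force grows without bound
        vals = [bc.bayes_factor_marginalized(
            make_natural_parameters(zeta_par=1.5, zeta_sp=0.5, n=n))
            for n in (10, 100, 1000, 10000)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals[-1] > 100

    def test_detectability_plateau(self):
        # K^M is nearly flat for 0 <= ζ_par/ζ_sp <= 1 and rises sharply
        # outside that band
        zsp, n = 2.0, 300
        inside = [bc.bayes_factor_marginalized(
            make_natural_parameters(zeta_par=f * zsp, zeta_sp=zsp, n=n))
            for f in np.linspace(0.05, 0.95, 7)]
        outside = [bc.bayes_factor_marginalized(
            make_natural_parameters(zeta_par=f * zsp, zeta_sp=zsp, n=n))
            for f in (-0.5, 1.5)]
        inside_range = max(inside) - min(inside)
        rise = min(outside) - max(inside)
        assert rise > inside_range

    def test_envelope_on_fine_grid(self):
        np_ = make_natural_parameters(zeta_par=0.3, zeta_perp=0.2,
                                      zeta_sp=1.1, n=80)
        km = bc.bayes_factor_marginalized(np_)
        grid = [bc.bayes_factor_fixed(np_, lam)
                for lam in np.linspace(0, 1, 1001)]
        assert min(grid) - 1e-9 <= km <= max(grid) + 1e-9

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(zeta_par=st.floats(-3, 3), zeta_perp=st.floats(0, 3),
           zeta_sp=st.floats(0, 3), n=st.integers(4, 500),
           d=st.sampled_from([1, 2]))
    def test_envelope_property(self, zeta_par, zeta_perp, zeta_sp, n, d):
        if d == 1:
            zeta_perp = 0.0
        np_ = make_natural_parameters(zeta_par=zeta_par, zeta_perp=zeta_perp,
                                      zeta_sp=zeta_sp, n=n, d=d)
        res = bc.compute_bayes_factors(np_)   # raises if envelope violated
        assert math.isfinite(res.log10_KM)


class TestOracleEquivalence:
    def test_closed_form_matches_brute_force_marginalization(self):
        from _oracles import brute_force_log_bayes_factor
        rng = np.random.default_rng(42)
        for _ in range(20):
            d = int(rng.integers(1, 3))
            n_pi = 4 if d == 1 else 3
            n = max(int(rng.integers(4, 51)), n_pi)
            V = float(rng.uniform(0.01, 0.1))
            dt = 0.04
            dr = rng.uniform(-3, 3, d) * math.sqrt(V)
            g = rng.uniform(-3, 3, d) * math.sqrt(V) / dt
            u = float(rng.uniform(0.5, 2.0))
            st_ = BinStatistics(n=n, dr_mean=dr, V=V, dt=dt, d=d)
            np_ = bc.natural_parameters(st_, g, bc.PriorHyperparameters(u=u))
            closed = bc.bayes_factor_marginalized(np_) * math.log(10)
            oracle = brute_force_log_bayes_factor(n, d, dr, V, g, dt, n_pi,
                                                  u * V)
            assert closed == pytest.approx(oracle, rel=1e-4, abs=1e-6)


class TestClassification:
    @pytest.mark.parametrize("value,expected", [
        (2.0, bc.NONSPURIOUS),
        (1.0, bc.NONSPURIOUS),
        (0.0, bc.INCONCLUSIVE),
        (-0.99, bc.INCONCLUSIVE),
        (-1.0, bc.SPURIOUS_ONLY),
        (-5.0, bc.SPURIOUS_ONLY),
    ])
    def test_threshold_rule(self, value, expected):
        assert bc.classify(value) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            bc.classify(float("nan"))


class TestLambdaMapH0:
    def test_interior_optimum(self):
        np_ = make_natural_parameters(zeta_par=0.5, zeta_sp=1.0, n=50)
        assert bc.lambda_map_H0(np_) == pytest.approx(0.5)

    def test_negative_projection_clamps_to_zero(self):
        np_ = make_natural_parameters(zeta_par=-0.3, zeta_sp=1.0, n=50)
        assert bc.lambda_map_H0(np_) == 0.0

    def test_beyond_gradient_clamps_to_one(self):
        np_ = make_natural_parameters(zeta_par=2.5, zeta_sp=1.0, n=50)
        assert bc.lambda_map_H0(np_) == 1.0

    def test_no_gradient_is_undefined(self):
        np_ = make_natural_parameters(zeta_perp=0.5, zeta_sp=0.0, n=50)
        assert bc.lambda_map_H0(np_) is None
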
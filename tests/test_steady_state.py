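"""Closed-form single-odorant and mixture response algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ornmix.steady_state import (MixtureSpec, SteadyStateProfile,
                                 approximation_error_experiment,
                                 dominant_approximation,
                                 effective_mixture_params,
                                 mixture_params_arrays, mixture_rate,
                                 response_from_log_params, saturating_rate,
                                 single_odorant_rate)

PROFILE = SteadyStateProfile(kappa=1.0, eta=1.0)


class TestSingleOdorant:
    def test_zero_concentration_gives_zero(self):
        assert single_odorant_rate(0.0, PROFILE) == 0.0

    def test_saturation_limit_eta_one(self):
        # F(inf) = Fmax / (1 + eta^-n) = 1/2 for eta = 1
        assert single_odorant_rate(np.inf, PROFILE) == pytest.approx(0.5)

    def test_value_at_kappa(self):
        # C = kappa, eta = 1, n = 4: F = 1 / (1 + 2^4) = 1/17
        assert single_odorant_rate(1.0, PROFILE) == pytest.approx(1 / 17)

    def test_saturating_rate_matches_limit_to_machine_precision(self):
        for eta in (0.2, 1.0, 3.7, 25.0):
            prof = SteadyStateProfile(1.0, eta)
            assert single_odorant_rate(np.inf, prof) == pytest.approx(
                saturating_rate(eta), rel=1e-14)

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            SteadyStateProfile(kappa=-1.0, eta=1.0)
        with pytest.raises(ValueError):
            SteadyStateProfile(kappa=1.0, eta=0.0)


class TestEffectiveMixtureParams:
    def test_single_component_unchanged(self):
        prof = SteadyStateProfile(2.0, 3.0)
        eff = effective_mixture_params(MixtureSpec([prof], [5.0]))
        assert eff.kappa == pytest.approx(prof.kappa)
        assert eff.eta == pytest.approx(prof.eta)

    def test_equal_kappa_equal_fraction_averages_eta(self):
        mix = MixtureSpec([SteadyStateProfile(1.0, 1.0),
                           SteadyStateProfile(1.0, 5.0)], [1.0, 1.0])
        assert effective_mixture_params(mix).eta == pytest.approx(3.0)

    def test_zero_concentration_component_dropped(self):
        mix = MixtureSpec([SteadyStateProfile(1.0, 2.0),
                           SteadyStateProfile(9.0, 9.0)], [1.0, 0.0])
        eff = effective_mixture_params(mix)
        assert eff.eta == pytest.approx(2.0)

    def test_empty_mixture_raises(self):
        mix = MixtureSpec([SteadyStateProfile(1.0, 1.0)], [0.0])
        with pytest.raises(ValueError, match="empty mixture"):
            effective_mixture_params(mix)

    def test_merging_duplicate_components_invariant(self):
        prof = SteadyStateProfile(0.7, 2.5)
        other = SteadyStateProfile(3.0, 0.4)
        split = MixtureSpec([prof, prof, other], [1.0, 2.0, 4.0])
        merged = MixtureSpec([prof, other], [3.0, 4.0])
        a, b = effective_mixture_params(split), effective_mixture_params(merged)
        assert a.kappa == pytest.approx(b.kappa)
        assert a.eta == pytest.approx(b.eta)


class TestMixtureRate:
    def test_self_mixture_equals_single(self):
        prof = SteadyStateProfile(0.5, 2.0)
        C = 3.0
        mix = MixtureSpec([prof, prof], [C / 2, C / 2])
        assert mixture_rate(mix) == pytest.approx(single_odorant_rate(C, prof))

    def test_saturating_limit_with_eta_mix_three(self):
        # kappa_A = kappa_B = 1, eta = (1, 5), equal fractions: eta_mix = 3
        mix = MixtureSpec([SteadyStateProfile(1.0, 1.0),
                           SteadyStateProfile(1.0, 5.0)], [1.0, 1.0])
        eff = effective_mixture_params(mix)
        assert single_odorant_rate(np.inf, eff) == pytest.approx(1 / (1 + 3.0**-4))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_betweenness_of_component_envelopes(self, seed):
        """A competitive mixture at total C always lies between the
        component dose-response curves evaluated at the same total C."""
        rng = np.random.default_rng(seed)
        pa = SteadyStateProfile(*np.exp(rng.normal(0, 2, 2)))
        pb = SteadyStateProfile(*np.exp(rng.normal(0, 2, 2)))
        beta = rng.uniform(0.05, 0.95)
        for C in np.logspace(-3, 3, 13):
            fm = mixture_rate(MixtureSpec([pa, pb], [beta * C, (1 - beta) * C]))
            fa = single_odorant_rate(C, pa)
            fb = single_odorant_rate(C, pb)
            assert min(fa, fb) - 1e-12 <= fm <= max(fa, fb) + 1e-12

    def test_monotone_in_strongest_component_concentration(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            pa = SteadyStateProfile(*np.exp(rng.normal(0, 2, 2)))
            eta_b = pa.eta * rng.uniform(1.5, 10)  # B has the largest eta
            pb = SteadyStateProfile(float(np.exp(rng.normal(0, 2))), float(eta_b))
            ca = float(np.exp(rng.normal(0, 1)))
            rates = [mixture_rate(MixtureSpec([pa, pb], [ca, cb]))
                     for cb in np.logspace(-2, 3, 11)]
            assert np.all(np.diff(rates) >= -1e-12)


class TestDominantApproximation:
    def test_single_component_exact(self):
        prof = SteadyStateProfile(2.0, 0.3)
        mix = MixtureSpec([prof], [1.0])
        appr = dominant_approximation(mix)
        exact = effective_mixture_params(mix)
        assert appr.kappa == pytest.approx(exact.kappa)
        assert appr.eta == pytest.approx(exact.eta)

    def test_overwhelming_dominance_small_error(self):
        # one component with beta*kappa^-1 a million times the others
        profs = [SteadyStateProfile(1e-6, 2.0), SteadyStateProfile(1.0, 0.5),
                 SteadyStateProfile(1.0, 4.0)]
        mix = MixtureSpec(profs, [1.0, 1.0, 1.0])
        appr = dominant_approximation(mix)
        exact = effective_mixture_params(mix)
        assert abs(appr.kappa / exact.kappa - 1) < 1e-4
        assert abs(appr.eta / exact.eta - 1) < 1e-4

    def test_tie_broken_by_lowest_index(self):
        profs = [SteadyStateProfile(1.0, 7.0), SteadyStateProfile(1.0, 3.0)]
        appr = dominant_approximation(MixtureSpec(profs, [1.0, 1.0]))
        assert appr.eta == pytest.approx(7.0)


class TestApproximationErrorExperiment:
    def test_single_component_has_zero_error(self):
        df = approximation_error_experiment([1], n_receptors=50, trials=5, seed=0)
        assert np.allclose(df.err_kappa, 0.0, atol=1e-12)
        assert np.allclose(df.err_eta, 0.0, atol=1e-12)

    def test_error_grows_with_mixture_size(self):
        df = approximation_error_experiment([1, 8, 64], n_receptors=100,
                                            trials=20, seed=1)
        means = df.groupby("nmix").err_kappa.mean()
        assert means.loc[1] < means.loc[8] < means.loc[64]

    def test_variable_concentrations_reduce_error(self):
        eq = approximation_error_experiment([16], n_receptors=100, trials=30,
                                            seed=2)
        lu = approximation_error_experiment([16], n_receptors=100, trials=30,
                                            seed=2, concentration_mode="log-uniform")
        assert lu.err_kappa.mean() < eq.err_kappa.mean()
        assert lu.err_eta.mean() < eq.err_eta.mean()

    def test_rejects_unknown_mode(self):
        with pytest.raises(ValueError):
            approximation_error_experiment([2], concentration_mode="bogus")


class TestLogDomainHelpers:
    def test_matches_scalar_algebra_on_random_mixtures(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            K = rng.integers(1, 6)
            lk, le = rng.normal(0, 3, (2, K))
            conc = rng.uniform(0.1, 5, K)
            profs = [SteadyStateProfile(float(np.exp(-a)), float(np.exp(b)))
                     for a, b in zip(lk, le)]
            mix = MixtureSpec(profs, conc)
            eff = effective_mixture_params(mix)
            lb = np.log(conc / conc.sum())
            lkinv, leta = mixture_params_arrays(lk, le, log_beta=lb)
            assert np.exp(lkinv) == pytest.approx(1 / eff.kappa, rel=1e-10)
            assert np.exp(leta) == pytest.approx(eff.eta, rel=1e-10)
            C = float(conc.sum())
            got = response_from_log_params(np.log(C), lkinv, leta)
            assert got == pytest.approx(mixture_rate(mix), rel=1e-10)

    def test_saturating_log_concentration(self):
        got = response_from_log_params(np.inf, 0.3, np.log(3.0))
        assert got == pytest.approx(1 / (1 + 3.0**-4))
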
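"""Recruitment-based intensity inference, suppression, overshadowing."""

import numpy as np
import pytest

from ornmix._rng import substream
from ornmix.ensemble import EnsembleConfig, OdorantEnsembleProfile, sample_odorant
from ornmix.masking import MaskingProfile
from ornmix.psychophysics import (BELOW_FIRST, default_grid,
                                  infer_concentration,
                                  masking_intensity_experiment,
                                  mixture_intensity_experiment,
                                  overshadowing_curve, recruitment_table,
                                  suppression_fraction)

CFG = EnsembleConfig(rho=0.0, p=0.5)


class TestRecruitmentTable:
    def test_higher_sensitivity_recruited_earlier(self):
        cfg = EnsembleConfig(N=2, p=0.5)
        prof = OdorantEnsembleProfile(np.array([2.0, 0.0]), np.array([1.0, 1.0]))
        table = recruitment_table(prof, cfg)
        assert list(table.glomeruli) == [0, 1]
        assert table.concentrations[0] < table.concentrations[1]

    def test_active_set_at_cmax_equals_table(self, config_p05):
        prof = sample_odorant(config_p05, substream(0, "t"))
        grid = default_grid()
        table = recruitment_table(prof, config_p05, grid)
        from ornmix.ensemble import finite_concentration_response
        z = finite_concentration_response(prof, config_p05, [grid[-1]]).z
        assert set(np.flatnonzero(z)) == set(table.glomeruli)

    def test_expected_size_matches_sparsity(self, config_p05):
        sizes = [len(recruitment_table(sample_odorant(config_p05,
                                                      substream(1, "s", i)),
                                       config_p05)) for i in range(100)]
        want = config_p05.p * config_p05.N
        assert np.mean(sizes) == pytest.approx(want, rel=0.1)

    def test_empty_table_is_explicit(self):
        cfg = EnsembleConfig(N=3, p=0.5)
        prof = OdorantEnsembleProfile(np.zeros(3), np.full(3, -5.0))  # eta << 1
        table = recruitment_table(prof, cfg)
        assert len(table) == 0


class TestInference:
    def test_contiguous_prefix_telescopes(self, config_p05):
        prof = sample_odorant(config_p05, substream(2, "u"))
        table = recruitment_table(prof, config_p05)
        for k in (1, 3, len(table)):
            active = table.glomeruli[:k]
            got = infer_concentration(active, table)
            assert got == pytest.approx(np.log(table.concentrations[k - 1]))

    def test_empty_active_set_sentinel(self, config_p05):
        prof = sample_odorant(config_p05, substream(2, "u"))
        table = recruitment_table(prof, config_p05)
        assert infer_concentration(np.array([], int), table) == BELOW_FIRST

    def test_subset_monotonicity(self, config_p05):
        """Removing active glomeruli can only lower the inferred value."""
        prof = sample_odorant(config_p05, substream(3, "v"))
        table = recruitment_table(prof, config_p05)
        rng = substream(4, "w")
        full = table.glomeruli.copy()
        est_full = infer_concentration(full, table)
        for _ in range(10):
            sub = rng.choice(full, size=len(full) // 2, replace=False)
            assert infer_concentration(sub, table) <= est_full + 1e-12

    def test_single_odorant_inference_unbiased(self):
        """Mean inference bias over the central four decades stays within
        half a recruitment-grid step (the estimator's resolution)."""
        df = mixture_intensity_experiment(CFG, trials=25, seed=5,
                                          companion="none")
        mid = df[(df.log10_true > -2) & (df.log10_true < 2)]
        step = 6.0 / 120  # 121 grid points over six decades
        assert abs((mid.log10_alone - mid.log10_true).mean()) < step / 2


class TestMixtureIntensity:
    @pytest.fixture(scope="class")
    def mixture_df(self):
        return mixture_intensity_experiment(CFG, trials=25, seed=6,
                                            companion="equal")

    def test_high_concentration_inhibition(self, mixture_df):
        hi = mixture_df[mixture_df.log10_true > 1.5]
        assert (hi.log10_mixture - hi.log10_true).mean() < -0.2

    def test_low_concentration_synergy(self, mixture_df):
        lo = mixture_df[(mixture_df.log10_true > -2.5) &
                        (mixture_df.log10_true < -1.5)]
        assert (lo.log10_mixture - lo.log10_true).mean() > 0.0


class TestMaskingIntensity:
    def test_masker_lowers_inferred_concentration_monotonically(self):
        df = masking_intensity_experiment(CFG, trials=10, seed=7)
        floor = np.log10(default_grid()[0])
        g = df.groupby(["mu", "masker_concentration"]).log10_inferred.mean()
        for mu in (0.4, 0.7, 1.0):
            curve = np.maximum(g.loc[mu].to_numpy(), floor)
            assert np.all(np.diff(curve) <= 1e-9)
        # stronger masking coefficient suppresses faster
        at_high = g.unstack(0).iloc[-1].to_numpy()
        assert at_high[0] >= at_high[1] >= np.maximum(at_high[2], floor)


class TestSuppression:
    def test_reciprocal_suppression_requires_antagonism(self):
        sup0 = suppression_fraction(EnsembleConfig(rho=0.0, p=0.5), [1.0],
                                    trials=120, seed=8).iloc[0]
        sup1 = suppression_fraction(EnsembleConfig(rho=1.0, p=0.5), [1.0],
                                    trials=120, seed=8).iloc[0]
        assert sup1.suppressed_A < 0.05 and sup1.suppressed_B < 0.05
        assert sup0.suppressed_A > 0.3 and sup0.suppressed_B > 0.3

    def test_symmetry_between_equal_odorants(self):
        sup = suppression_fraction(EnsembleConfig(rho=0.0, p=0.5), [1.0],
                                   trials=200, seed=9).iloc[0]
        se = np.hypot(sup.stderr_A, sup.stderr_B)
        assert abs(sup.suppressed_A - sup.suppressed_B) < 3 * se + 0.01

    def test_masking_capacity_makes_suppression_asymmetric(self):
        sup = suppression_fraction(EnsembleConfig(rho=0.0, p=0.5), [1.0],
                                   trials=120, seed=10,
                                   masking_B=MaskingProfile(KM=1e-6, mu=1.0)).iloc[0]
        assert sup.suppressed_A > sup.suppressed_B + 0.15

    @pytest.mark.parametrize("p", [0.3, 0.7])
    def test_ordering_robust_to_sparsity(self, p):
        sup0 = suppression_fraction(EnsembleConfig(rho=0.0, p=p), [1.0],
                                    trials=80, seed=11).iloc[0]
        sup1 = suppression_fraction(EnsembleConfig(rho=1.0, p=p), [1.0],
                                    trials=80, seed=11).iloc[0]
        assert sup0.suppressed_A > sup1.suppressed_A + 0.1


class TestOvershadowing:
    @pytest.fixture(scope="class")
    def curves(self):
        ratios = np.logspace(0, 3, 7)
        return {rho: overshadowing_curve(EnsembleConfig(rho=rho, p=0.5),
                                         ratios, trials=8, seed=12)
                for rho in (0.0, 1.0)}

    def test_equal_ratio_both_detected(self, curves):
        for df in curves.values():
            first = df[df.ratio == 1.0]
            assert first.prob_B.mean() > 0.5
            assert first.prob_A.mean() > 0.5

    def test_antagonism_intensifies_overshadowing(self, curves):
        """P(B) falls below the detection threshold at a smaller A:B ratio
        under full antagonism than without antagonism."""
        def crossing(df):
            g = df.groupby("ratio").prob_B.mean()
            below = g[g < 0.5]
            return below.index.min() if len(below) else np.inf
        assert crossing(curves[0.0]) < crossing(curves[1.0])

    def test_strong_component_stays_detected(self, curves):
        g = curves[0.0].groupby("ratio").prob_A.mean()
        assert (g > 0.5).all()
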
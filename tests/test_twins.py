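"""Tests for twin analyses: ICC, Falconer/ML ACE, between-within decomposition."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from polyepi import TwinConfig, simulate_twins
from polyepi.twins import (
    between_within_decomposition,
    falconer_decomposition,
    intraclass_correlation,
    ml_ace_fit,
    pairs_wide,
)


def make_pairs(v1, v2, zygosity="MZ"):
    return pd.DataFrame(
        {
            "pair_id": [f"p{i}" for i in range(len(v1))],
            "zygosity": zygosity,
            "v1": v1,
            "v2": v2,
        }
    )


class TestIntraclassCorrelation:
    def test_identical_twins_give_one(self):
        pairs = make_pairs([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert intraclass_correlation(pairs, "MZ").r == pytest.approx(1.0)

    def test_independent_members_near_zero(self):
        rng = np.random.default_rng(7)
        n = 400
        pairs = make_pairs(rng.normal(size=n), rng.normal(size=n))
        res = intraclass_correlation(pairs, "MZ")
        assert abs(res.r) < 3 / np.sqrt(n)

    def test_double_entry_matches_hand_computation(self):
        # pairs (1,2), (2,1), (3,3) double-entered -> 6 rows
        pairs = make_pairs([1.0, 2.0, 3.0], [2.0, 1.0, 3.0])
        a = np.array([1, 2, 3, 2, 1, 3], dtype=float)
        b = np.array([2, 1, 3, 1, 2, 3], dtype=float)
        expected = np.corrcoef(a, b)[0, 1]
        assert intraclass_correlation(pairs, "MZ").r == pytest.approx(expected)

    def test_symmetric_under_twin_order_swap(self):
        rng = np.random.default_rng(8)
        v1, v2 = rng.normal(size=50), rng.normal(size=50)
        r1 = intraclass_correlation(make_pairs(v1, v2), "MZ").r
        r2 = intraclass_correlation(make_pairs(v2, v1), "MZ").r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            intraclass_correlation(make_pairs([1.0], [2.0]), "MZ")


class TestFalconer:
    def test_published_style_correlations(self):
        # rMZ = 0.87, rDZ = 0.52 -> a2 = 0.70, c2 = 0.17, e2 = 0.13
        res = falconer_decomposition(0.87, 0.52)
        assert (res.a2, res.c2, res.e2) == pytest.approx((0.70, 0.17, 0.13))
        assert not res.truncated

    def test_no_familial_resemblance(self):
        res = falconer_decomposition(0.0, 0.0)
        assert (res.a2, res.c2, res.e2) == (0.0, 0.0, 1.0)

    def test_purely_additive_limit(self):
        res = falconer_decomposition(1.0, 0.5)
        assert (res.a2, res.c2, res.e2) == pytest.approx((1.0, 0.0, 0.0))

    def test_components_sum_to_one_before_truncation(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            rmz, rdz = rng.uniform(-1, 1, 2)
            raw = np.array([2 * (rmz - rdz), 2 * rdz - rmz, 1 - rmz])
            assert raw.sum() == pytest.approx(1.0, abs=1e-12)
            res = falconer_decomposition(rmz, rdz)
            assert res.a2 + res.c2 + res.e2 == pytest.approx(1.0, abs=1e-12)
            assert min(res.a2, res.c2, res.e2) >= 0

    def test_negative_component_is_truncated_and_flagged(self):
        res = falconer_decomposition(0.4, 0.1)  # c2 raw = -0.2
        assert res.truncated and res.c2 == 0.0


class TestMlAce:
    def test_recovers_simulated_fractions(self):
        # average over seeds so Monte-Carlo error (SE ~ 0.027 per replicate)
        # does not dominate the unbiasedness check
        ests = []
        for seed in (10, 20, 30):
            c = simulate_twins(
                TwinConfig(seed=seed, a2=0.5, c2=0.2, n_mz_pairs=5000, n_dz_pairs=5000)
            )
            est = ml_ace_fit(pairs_wide(c.pheno, "latent_score"), ci_method=None)
            ests.append((est.a2, est.c2, est.e2))
        mean = np.mean(ests, axis=0)
        np.testing.assert_allclose(mean, (0.5, 0.2, 0.3), atol=0.03)

    def test_pure_noise_hits_zero_boundary(self):
        c = simulate_twins(
            TwinConfig(seed=11, a2=0.0, c2=0.0, n_mz_pairs=500, n_dz_pairs=500)
        )
        pairs = pairs_wide(c.pheno, "latent_score")
        est = ml_ace_fit(pairs, ci_method=None)
        assert est.a2 < 0.05 and est.c2 < 0.05

    def test_agrees_with_falconer_at_large_n(self):
        c = simulate_twins(
            TwinConfig(seed=12, a2=0.4, c2=0.3, n_mz_pairs=4000, n_dz_pairs=4000)
        )
        pairs = pairs_wide(c.pheno, "latent_score")
        est = ml_ace_fit(pairs, ci_method=None)
        rmz = intraclass_correlation(pairs, "MZ").r
        rdz = intraclass_correlation(pairs, "DZ").r
        fal = falconer_decomposition(rmz, rdz)
        assert est.a2 == pytest.approx(fal.a2, abs=0.02)
        assert est.c2 == pytest.approx(fal.c2, abs=0.02)

    def test_profile_ci_brackets_estimate_and_truth(self):
        c = simulate_twins(
            TwinConfig(seed=13, a2=0.5, c2=0.2, n_mz_pairs=1500, n_dz_pairs=1500)
        )
        est = ml_ace_fit(pairs_wide(c.pheno, "latent_score"), ci_method="profile")
        lo, hi = est.ci_a2
        assert lo < est.a2 < hi
        assert hi - lo < 0.25

    def test_too_few_pairs_rejected(self):
        pairs = make_pairs(np.arange(5.0), np.arange(5.0))
        with pytest.raises(ValueError, match="20"):
            ml_ace_fit(pairs)


class TestBetweenWithin:
    @staticmethod
    def _long(pair_ids, zyg, pred, outc):
        return pd.DataFrame(
            {
                "family_id": np.repeat(pair_ids, 2),
                "zygosity": np.repeat(zyg, 2),
                "predictor": np.concatenate(pred),
                "outcome": np.concatenate(outc),
            }
        )

    def test_constructed_within_effect_is_exact(self):
        # outcome = 0.18 * deviation from pair mean, exactly
        pred = [np.array([1.0, 3.0]), np.array([2.0, 6.0]), np.array([0.0, 4.0])]
        outc = [0.18 * (p - p.mean()) for p in pred]
        df = self._long(["a", "b", "c"], ["MZ"] * 3, pred, outc)
        res = between_within_decomposition(df, "outcome", "predictor")
        assert res.within == pytest.approx(0.18, abs=1e-10)
        assert res.between == pytest.approx(0.0, abs=1e-10)

    def test_identical_predictor_within_pairs_rejected(self):
        pred = [np.array([2.0, 2.0]), np.array([5.0, 5.0])]
        outc = [np.array([1.0, 2.0]), np.array([3.0, 1.0])]
        df = self._long(["a", "b"], ["MZ"] * 2, pred, outc)
        with pytest.raises(ValueError, match="identical within"):
            between_within_decomposition(df, "outcome", "predictor")

    def test_matches_explicit_design_matrix_ols(self):
        rng = np.random.default_rng(14)
        n_pairs = 40
        pred = [rng.normal(size=2) for _ in range(n_pairs)]
        outc = [0.5 * p.mean() + 0.2 * (p - p.mean()) + rng.normal(0, 0.1, 2) for p in pred]
        ids = [f"p{i}" for i in range(n_pairs)]
        df = self._long(ids, ["DZ"] * n_pairs, pred, outc)
        res = between_within_decomposition(df, "outcome", "predictor")
        # independent oracle: build the decomposed design by hand
        pm = df.groupby("family_id").predictor.transform("mean")
        X = np.column_stack([np.ones(len(df)), pm, df.predictor - pm])
        ref = sm.OLS(df.outcome.to_numpy(), X).fit()
        assert res.between == pytest.approx(ref.params[1], abs=1e-10)
        assert res.within == pytest.approx(ref.params[2], abs=1e-10)

    def test_mz_within_equals_pair_difference_regression(self):
        # for complete MZ pairs the within coefficient equals the regression
        # of outcome differences on predictor differences through the origin
        c = simulate_twins(
            TwinConfig(
                seed=15,
                n_mz_pairs=300,
                n_dz_pairs=300,
                packyear_effect=0.09,
                genetic_confounding=0.244,
            )
        )
        df = c.pheno
        res = between_within_decomposition(
            df, "latent_score", "pack_years_z", pair_col="family_id", subset="MZ"
        )
        mz = df[df.zygosity == "MZ"]
        wide_p = mz.pivot_table(index="family_id", columns="twin", values="pack_years_z")
        wide_y = mz.pivot_table(index="family_id", columns="twin", values="latent_score")
        dp = (wide_p[1] - wide_p[2]).to_numpy()
        dy = (wide_y[1] - wide_y[2]).to_numpy()
        slope = (dp @ dy) / (dp @ dp)
        assert res.within == pytest.approx(slope, abs=1e-10)

    def test_recovers_designed_within_effects(self):
        c = simulate_twins(
            TwinConfig(
                seed=16,
                n_mz_pairs=4000,
                n_dz_pairs=3142,
                packyear_effect=0.09,
                genetic_confounding=0.244,
            )
        )
        res_all = between_within_decomposition(c.pheno, "latent_score", "pack_years_z")
        res_mz = between_within_decomposition(
            c.pheno, "latent_score", "pack_years_z", subset="MZ"
        )
        assert res_all.within == pytest.approx(0.18, abs=0.03)
        assert res_mz.within == pytest.approx(0.09, abs=0.03)
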
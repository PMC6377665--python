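"""Tests for the methylation-expression screen, annotation and sensitivity analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polyepi.expression import (
    bonferroni_alpha,
    cis_trans_annotate,
    correlation_screen,
    screen_grid_size,
    sensitivity_partial,
    transcriptome_association,
)


def random_grid(rng, n_probes=40, n_probesets=10, n=60):
    samples = [f"S{i}" for i in range(n)]
    meth = pd.DataFrame(
        rng.uniform(0.1, 0.9, (n_probes, n)),
        index=[f"cg{i:05d}" for i in range(n_probes)],
        columns=samples,
    )
    expr = pd.DataFrame(
        rng.normal(size=(n_probesets, n)),
        index=[f"PS{i:04d}" for i in range(n_probesets)],
        columns=samples,
    )
    strata = pd.Series(
        np.where(np.arange(n) % 2 == 0, "never", "current"), index=samples
    )
    return meth, expr, strata


class TestGridArithmetic:
    def test_grid_size_is_exact_product(self):
        assert screen_grid_size(2623, 143) == 375_089

    def test_bonferroni_threshold_rounds_to_printed_value(self):
        alpha = bonferroni_alpha(0.05, 375_089)
        assert float(f"{float(alpha):.3g}") == 1.33e-07

    def test_screen_reports_full_grid(self, rng):
        meth, expr, strata = random_grid(rng)
        res = correlation_screen(meth, expr, strata)
        assert res.n_tests == 400
        assert len(res.table) == 400
        assert res.per_test_alpha == pytest.approx(0.05 / 400)


class TestCorrelationScreen:
    def test_perfect_linear_pair_is_flagged(self, rng):
        meth, expr, strata = random_grid(rng)
        expr.loc["PS0000"] = 3.0 - 2.0 * meth.loc["cg00000"]
        res = correlation_screen(meth, expr, strata)
        row = res.table.set_index(["probe_id", "probeset_id"]).loc[("cg00000", "PS0000")]
        assert bool(row.significant_both)
        assert row.r_never == pytest.approx(-1.0)

    def test_null_grid_rarely_hits_in_both_strata(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            meth, expr, strata = random_grid(rng, n_probes=100, n_probesets=20, n=80)
            res = correlation_screen(meth, expr, strata)
            hits += int(res.table.significant_both.sum())
        assert hits == 0  # expected joint-null hits << 1 over 10 seeds

    def test_lowering_alpha_never_adds_pairs(self, rng):
        meth, expr, strata = random_grid(rng)
        expr.loc["PS0001"] = 1.0 * meth.loc["cg00003"] + 0.01 * expr.loc["PS0001"]
        loose = correlation_screen(meth, expr, strata, alpha_family=0.5)
        strict = correlation_screen(meth, expr, strata, alpha_family=0.01)
        loose_pairs = set(map(tuple, loose.significant_pairs[["probe_id", "probeset_id"]].to_numpy()))
        strict_pairs = set(map(tuple, strict.significant_pairs[["probe_id", "probeset_id"]].to_numpy()))
        assert strict_pairs <= loose_pairs

    def test_correlations_invariant_to_affine_rescaling(self, rng):
        meth, expr, strata = random_grid(rng, n_probes=8, n_probesets=4)
        base = correlation_screen(meth, expr, strata)
        rescaled = correlation_screen(meth, expr * 3.5 + 1.0, strata)
        np.testing.assert_allclose(
            base.table.r_never, rescaled.table.r_never, atol=1e-12
        )

    def test_small_stratum_rejected(self, rng):
        meth, expr, strata = random_grid(rng, n=12)
        with pytest.raises(ValueError, match="need >="):
            correlation_screen(meth, expr, strata)

    def test_spearman_option_matches_scipy(self, rng):
        meth, expr, strata = random_grid(rng, n_probes=3, n_probesets=2)
        res = correlation_screen(meth, expr, strata, method="spearman")
        never = [s for s in meth.columns if strata[s] == "never"]
        expected = stats.spearmanr(
            meth.loc["cg00001", never], expr.loc["PS0001", never]
        ).statistic
        row = res.table.set_index(["probe_id", "probeset_id"]).loc[("cg00001", "PS0001")]
        assert row.r_never == pytest.approx(expected, abs=1e-12)


class TestCisTransAnnotate:
    @staticmethod
    def _fixtures():
        probe_ann = pd.DataFrame(
            {
                "probe_id": ["cgA", "cgB", "cgC", "cgD"],
                "chrom": ["chr1", "chr1", "chr2", "chr1"],
                "pos": [1_000_000, 1_250_001, 1_000_000, 999_876],
            }
        )
        ps_map = pd.DataFrame({"probeset_id": ["PS1"], "gene": ["IL32like"]})
        gene_ann = pd.DataFrame(
            {"gene": ["IL32like"], "chrom": ["chr1"], "start": [1_000_000]}
        )
        return probe_ann, ps_map, gene_ann

    def test_probe_at_gene_start_is_cis_distance_zero(self):
        probe_ann, ps_map, gene_ann = self._fixtures()
        pairs = pd.DataFrame({"probe_id": ["cgA"], "probeset_id": ["PS1"]})
        out = cis_trans_annotate(pairs, probe_ann, ps_map, gene_ann)
        assert out.relation[0] == "cis" and out.distance_bp[0] == 0

    def test_boundary_is_inclusive(self):
        probe_ann, ps_map, gene_ann = self._fixtures()
        pairs = pd.DataFrame({"probe_id": ["cgB"], "probeset_id": ["PS1"]})
        out = cis_trans_annotate(pairs, probe_ann, ps_map, gene_ann)
        assert out.relation[0] == "trans"  # 250,001 bp is outside the window
        out2 = cis_trans_annotate(pairs, probe_ann, ps_map, gene_ann, window=250_001)
        assert out2.relation[0] == "cis"

    def test_other_chromosome_is_trans(self):
        probe_ann, ps_map, gene_ann = self._fixtures()
        pairs = pd.DataFrame({"probe_id": ["cgC"], "probeset_id": ["PS1"]})
        out = cis_trans_annotate(pairs, probe_ann, ps_map, gene_ann)
        assert out.relation[0] == "trans"

    def test_upstream_probe_has_negative_distance(self):
        # 124 bp upstream of the gene start -> cis, distance -124
        probe_ann, ps_map, gene_ann = self._fixtures()
        pairs = pd.DataFrame({"probe_id": ["cgD"], "probeset_id": ["PS1"]})
        out = cis_trans_annotate(pairs, probe_ann, ps_map, gene_ann)
        assert out.relation[0] == "cis" and out.distance_bp[0] == -124

    def test_missing_coordinates_labelled_unknown(self):
        probe_ann, ps_map, gene_ann = self._fixtures()
        pairs = pd.DataFrame({"probe_id": ["cgZZ"], "probeset_id": ["PS1"]})
        out = cis_trans_annotate(pairs, probe_ann, ps_map, gene_ann)
        assert out.relation[0] == "unknown"


class TestSensitivityPartial:
    def test_zero_covariate_equals_marginal(self, rng):
        meth, expr, strata = random_grid(rng, n_probes=6, n_probesets=3)
        pairs = pd.DataFrame(
            {"probe_id": ["cg00000", "cg00002"], "probeset_id": ["PS0000", "PS0001"]}
        )
        cov = pd.Series(0.0, index=meth.columns)
        res = sensitivity_partial(meth, expr, pairs, list(meth.columns), cov)
        np.testing.assert_allclose(res.table.r_partial, res.table.r_marginal, atol=1e-12)

    def test_collinear_covariate_skips_pair(self, rng):
        meth, expr, strata = random_grid(rng, n_probes=4, n_probesets=2)
        pairs = pd.DataFrame({"probe_id": ["cg00001"], "probeset_id": ["PS0000"]})
        cov = meth.loc["cg00001"].copy()
        res = sensitivity_partial(meth, expr, pairs, list(meth.columns), cov)
        assert res.skipped == [("cg00001", "PS0000")]
        assert len(res.table) == 0

    def test_independent_covariate_preserves_coefficients(self):
        rhos = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            meth, expr, strata = random_grid(rng, n_probes=30, n_probesets=6, n=120)
            # give some pairs real signal so the rank correlation is informative
            for k in range(6):
                expr.iloc[k] = 0.6 * stats.zscore(meth.iloc[k]) + 0.8 * expr.iloc[k]
            pairs = pd.DataFrame(
                {
                    "probe_id": meth.index[:20],
                    "probeset_id": np.tile(expr.index[:5], 4),
                }
            )
            cov = pd.Series(rng.normal(size=120), index=meth.columns)
            res = sensitivity_partial(meth, expr, pairs, list(meth.columns), cov)
            rhos.append(res.spearman_rho)
        assert np.mean(rhos) > 0.95


class TestTranscriptomeAssociation:
    def test_global_null_yields_no_bh_discoveries(self, rng):
        _, expr, _ = random_grid(rng, n_probesets=500, n=100)
        scores = pd.Series(rng.normal(size=100), index=expr.columns)
        res = transcriptome_association(expr, scores)
        assert res.significant.sum() <= 1  # BH controls FWER under the global null

    def test_injected_associations_are_discovered_with_fdr_control(self):
        false_fracs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            _, expr, _ = random_grid(rng, n_probesets=400, n=150)
            scores = pd.Series(rng.normal(size=150), index=expr.columns)
            truth = set(expr.index[:40])
            for ps in truth:
                expr.loc[ps] = 0.5 * scores.to_numpy() + expr.loc[ps]
            res = transcriptome_association(expr, scores)
            hits = set(res.loc[res.significant, "probeset_id"])
            if hits:
                false_fracs.append(len(hits - truth) / len(hits))
        assert np.mean(false_fracs) <= 0.05 + 3 * np.std(false_fracs) / np.sqrt(5) + 0.02

    def test_constant_probeset_dropped(self, rng):
        _, expr, _ = random_grid(rng, n_probesets=5, n=40)
        expr.iloc[3] = 1.0
        scores = pd.Series(rng.normal(size=40), index=expr.columns)
        res = transcriptome_association(expr, scores)
        assert len(res) == 4

    def test_matches_single_regression(self, rng):
        import statsmodels.api as sm

        _, expr, _ = random_grid(rng, n_probesets=3, n=50)
        scores = pd.Series(rng.normal(size=50), index=expr.columns)
        res = transcriptome_association(expr, scores)
        ref = sm.OLS(
            expr.iloc[1].to_numpy(), sm.add_constant(scores.to_numpy())
        ).fit()
        assert res.estimate.iloc[1] == pytest.approx(ref.params[1], abs=1e-12)
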
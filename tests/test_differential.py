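import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from peptiq.simulate import SyntheticConfig, generate_dataset
from peptiq.stats import (EBayesPrior, adjust_bh, anova_f, differential_abundance,
                          fit_ebayes_prior, moderated_t, pooled_variance, welch_t)


class TestWelch:
    def test_hand_computed_example(self):
        # [1,2,3] vs [2,3,4]: s^2 = 1 each, diff -1, t = -1/sqrt(2/3), df = 4
        res = welch_t([1, 2, 3], [2, 3, 4])
        assert res.diff == pytest.approx(-1.0)
        assert res.statistic == pytest.approx(-1.2247448, abs=1e-6)
        assert res.df == pytest.approx(4.0)

    def test_identical_groups(self):
        res = welch_t([1, 2, 3], [1, 2, 3])
        assert res.diff == 0.0 and res.statistic == 0.0 and res.p_value == 1.0

    def test_single_value_group_reports_reason(self):
        res = welch_t([1, 2, 3], [2])
        assert math.isnan(res.statistic)
        assert res.reason == "insufficient replicates"

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            g1 = rng.normal(0, 1, rng.integers(2, 8))
            g2 = rng.normal(0.5, 2, rng.integers(2, 8))
            mine = welch_t(g1, g2)
            ref = sps.ttest_ind(g1, g2, equal_var=False)
            assert mine.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_nan_values_are_dropped(self):
        res = welch_t([1, 2, 3, np.nan], [2, 3, 4])
        assert res.n1 == 3


class TestEBayesPrior:
    def test_identical_variances_give_infinite_prior_df(self):
        prior = fit_ebayes_prior([2.5] * 20, 4.0)
        assert math.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(2.5, abs=1e-6)

    def test_fewer_than_ten_variances_refused(self):
        with pytest.raises(ValueError, match=">= 10"):
            fit_ebayes_prior([1.0] * 9, 4.0)

    def test_monte_carlo_recovery_of_known_hyperparameters(self):
        # s^2 ~ s0^2 * (chi2_d / d) / (chi2_d0 / d0) with d0=4, s0^2=1
        rng = np.random.default_rng(7)
        d0, s0_sq, d, n = 4.0, 1.0, 4.0, 5000
        sigma_sq = s0_sq * d0 / rng.chisquare(d0, size=n)
        variances = sigma_sq * rng.chisquare(d, size=n) / d
        prior = fit_ebayes_prior(variances, d)
        assert prior.d0 == pytest.approx(d0, rel=0.15)
        assert prior.s0_sq == pytest.approx(s0_sq, rel=0.10)

    def test_agrees_with_limma_reference_fit(self, tmp_path):
        """Cross-check the method-of-moments fit against limma::fitFDist."""
        import shutil, subprocess
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(11)
        # genuine variance heterogeneity (d0=6) so the finite-d0 branch runs
        sigma_sq = 1.3 * 6.0 / rng.chisquare(6.0, size=200)
        variances = sigma_sq * rng.chisquare(5, size=200) / 5
        df = 5
        var_file = tmp_path / "var.txt"
        np.savetxt(var_file, variances)
        script = tmp_path / "fit.R"
        script.write_text(
            f'suppressMessages(library(limma))\n'
            f'x <- scan("{var_file}", quiet=TRUE)\n'
            f'f <- fitFDist(x, df1={df})\n'
            f'cat(f$scale, f$df2, sep="\\n")\n'
        )
        proc = subprocess.run(["Rscript", "--vanilla", str(script)],
                              capture_output=True, text=True)
        if proc.returncode != 0:
            pytest.skip(f"limma unavailable: {proc.stderr[:200]}")
        scale, df2 = map(float, proc.stdout.split())
        prior = fit_ebayes_prior(variances, df)
        assert prior.s0_sq == pytest.approx(scale, rel=1e-4)
        assert prior.d0 == pytest.approx(df2, rel=1e-4)


class TestModeratedT:
    def test_hand_computed_example(self):
        # pooled s^2 = 1, d = 4; prior d0=4, s0^2=1 -> s~^2 = 1, t = -1.2247, df = 8
        res = moderated_t([1, 2, 3], [2, 3, 4], EBayesPrior(d0=4.0, s0_sq=1.0))
        assert res.statistic == pytest.approx(-1.2247448, abs=1e-6)
        assert res.df == pytest.approx(8.0)

    def test_zero_prior_df_is_the_pooled_t(self):
        rng = np.random.default_rng(2)
        g1, g2 = rng.normal(0, 1, 4), rng.normal(1, 1, 5)
        res0 = moderated_t(g1, g2, EBayesPrior(d0=0.0, s0_sq=5.0))
        ref = sps.ttest_ind(g1, g2, equal_var=True)
        assert res0.statistic == pytest.approx(ref.statistic, rel=1e-12)

    def test_tiny_prior_df_converges_to_pooled_t(self):
        g1, g2 = [1.0, 2.2, 2.9], [2.1, 3.3, 4.0]
        tiny = moderated_t(g1, g2, EBayesPrior(d0=1e-8, s0_sq=123.0))
        zero = moderated_t(g1, g2, EBayesPrior(d0=0.0, s0_sq=123.0))
        assert tiny.statistic == pytest.approx(zero.statistic, abs=1e-6)

    def test_infinite_prior_df_uses_only_the_prior_variance(self):
        res = moderated_t([1, 2, 3], [5, 6, 7], EBayesPrior(d0=math.inf, s0_sq=9.0))
        assert res.se == pytest.approx(math.sqrt(9.0 * (2 / 3)))
        assert math.isinf(res.df)

    def test_agrees_with_limma_squeezed_t(self, tmp_path):
        """Moderated statistics should match limma's squeezeVar-based t."""
        import shutil, subprocess
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(3)
        g1 = rng.normal(0, 1, (40, 3))
        g2 = rng.normal(0, 1, (40, 3))
        pooled = np.array([pooled_variance(a, b)[0] for a, b in zip(g1, g2)])
        var_file = tmp_path / "var.txt"
        np.savetxt(var_file, pooled)
        script = tmp_path / "sq.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'x <- scan("{var_file}", quiet=TRUE)\n'
            'sq <- squeezeVar(x, df=4)\n'
            'cat(sq$df.prior, sq$var.prior, sep="\\n")\n'
            'write(sq$var.post, stdout(), ncolumns=1)\n'
        )
        proc = subprocess.run(["Rscript", "--vanilla", str(script)],
                              capture_output=True, text=True)
        if proc.returncode != 0:
            pytest.skip(f"limma unavailable: {proc.stderr[:200]}")
        lines = proc.stdout.split()
        d0_r, s0_r = float(lines[0]), float(lines[1])
        var_post_r = np.array([float(v) for v in lines[2:]])
        prior = fit_ebayes_prior(pooled, 4.0)
        assert prior.d0 == pytest.approx(d0_r, rel=1e-4)
        assert prior.s0_sq == pytest.approx(s0_r, rel=1e-4)
        if math.isinf(prior.d0):
            mine = np.full_like(pooled, prior.s0_sq)
        else:
            mine = np.array([(prior.d0 * prior.s0_sq + 4 * v) / (prior.d0 + 4) for v in pooled])
        assert np.allclose(mine, var_post_r, rtol=1e-4)


class TestAnova:
    def test_hand_computed_example(self):
        # groups [1,2,3],[2,3,4],[3,4,5]: SSB=6, SSW=6, F=(6/2)/(6/6)=3, df (2,6)
        res = anova_f([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert res.statistic == pytest.approx(3.0)
        assert (res.df1, res.df2) == (2.0, 6.0)
        assert res.p_value == pytest.approx(float(sps.f.sf(3.0, 2, 6)))

    def test_identical_groups(self):
        res = anova_f([[2, 2], [2, 2]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_two_groups_f_is_squared_pooled_t(self):
        g1, g2 = [1.0, 2.5, 3.1], [2.0, 3.7, 4.2, 3.9]
        f = anova_f([g1, g2])
        t = sps.ttest_ind(g1, g2, equal_var=True)
        assert f.statistic == pytest.approx(t.statistic ** 2, rel=1e-10)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(i, 1, 5) for i in range(4)]
        mine = anova_f(groups)
        ref = sps.f_oneway(*groups)
        assert mine.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_degenerate_input_reports_reason(self):
        assert anova_f([[1.0], [2.0, 3.0]]).reason == "insufficient replicates"


class TestAdjustBH:
    def test_step_up_minima(self):
        assert np.allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert adjust_bh([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert np.allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)

    def test_nan_passthrough_and_m(self):
        out = adjust_bh([0.01, np.nan, 0.02])
        assert np.isnan(out[1])
        # m = 2: adjusted = min(2*0.01/1, ...) etc
        assert out[0] == pytest.approx(0.02)

    def test_monotone(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=100)
        adj = adjust_bh(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_is_an_error(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])


class TestDifferentialAbundance:
    def test_moderated_beats_welch_in_power_at_matched_threshold(self):
        cfg = SyntheticConfig(n_proteins=300, peptides_per_protein=1, n_replicates=3,
                              frac_differential=0.3, dropout_midpoint=None, seed=6)
        table, truth = generate_dataset(cfg)
        truth_diff = set(truth.proteins.loc[truth.proteins["differential"], "protein"])
        hits = {}
        for method in ("welch", "moderated"):
            res = differential_abundance(table, level="protein", method=method,
                                         ref_condition="C1")
            sig = set(res.loc[res["adj_p_value"] < 0.05, "feature"])
            hits[method] = len(sig & truth_diff)
        assert hits["moderated"] >= hits["welch"]

    def test_untestable_features_are_recorded_not_dropped(self):
        cfg = SyntheticConfig(n_proteins=60, peptides_per_protein=1,
                              dropout_midpoint=18.0, dropout_slope=2.0, seed=8)
        table, _ = generate_dataset(cfg)
        res = differential_abundance(table, level="protein", method="welch")
        assert len(res) == table["protein"].nunique()
        missing = res[res["reason"].notna()]
        assert missing["p_value"].isna().all()

    def test_effect_sizes_recovered_in_log2(self):
        cfg = SyntheticConfig(n_proteins=100, peptides_per_protein=1, n_replicates=20,
                              frac_differential=0.2, dropout_midpoint=None,
                              replicate_noise_sd=0.1, seed=9)
        table, truth = generate_dataset(cfg)
        res = differential_abundance(table, level="protein", method="welch",
                                     ref_condition="C1").set_index("feature")
        tr = truth.proteins.query("condition == 'C2'").set_index("protein")
        merged = res.join(tr)
        assert np.corrcoef(merged["diff"], merged["true_log2fc"])[0, 1] > 0.98

    def test_anova_runs_omnibus_per_feature(self):
        cfg = SyntheticConfig(n_proteins=20, peptides_per_protein=1, n_conditions=3,
                              dropout_midpoint=None, seed=10)
        table, _ = generate_dataset(cfg)
        res = differential_abundance(table, level="protein", method="anova")
        assert (res["comparison"] == "omnibus").all()
        assert len(res) == 20
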
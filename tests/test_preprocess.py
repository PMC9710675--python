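import numpy as np
import pandas as pd
import pytest

from peptiq.preprocess import filter_min_observations, impute_mnar, median_normalize

from conftest import make_table


def sample_records(sample, values, condition="c"):
    return [{"sample": sample, "condition": condition, "replicate": 1,
             "protein": f"P{i}", "intensity_log2": float(v)} for i, v in enumerate(values)]


class TestMedianNormalize:
    def test_hand_computed_shifts(self):
        # medians 12 and 13 -> reference 12.5 -> both samples land on [10.5, 12.5, 14.5]
        table = make_table(sample_records("A", [10, 12, 14]) + sample_records("B", [11, 13, 15]))
        res = median_normalize(table)
        assert res.reference_median == pytest.approx(12.5)
        assert res.shifts["A"] == pytest.approx(0.5)
        assert res.shifts["B"] == pytest.approx(-0.5)
        for s in ("A", "B"):
            vals = sorted(res.table.loc[res.table["sample"] == s, "intensity_log2"])
            assert vals == pytest.approx([10.5, 12.5, 14.5])

    def test_equal_medians_change_nothing(self):
        table = make_table(sample_records("A", [10, 12, 14]) + sample_records("B", [11, 12, 13]))
        res = median_normalize(table)
        assert np.allclose(res.shifts, 0.0)
        pd.testing.assert_frame_equal(res.table, table)

    def test_single_sample_unchanged(self):
        table = make_table(sample_records("A", [10, 12, 14]))
        res = median_normalize(table)
        assert res.shifts["A"] == pytest.approx(0.0)

    def test_idempotent(self, two_condition_table):
        once = median_normalize(two_condition_table)
        twice = median_normalize(once.table)
        assert np.allclose(twice.shifts, 0.0, atol=1e-9)
        assert np.allclose(once.table["intensity_log2"], twice.table["intensity_log2"], atol=1e-9)

    def test_all_sample_medians_hit_the_reference(self, two_condition_table):
        res = median_normalize(two_condition_table)
        medians = res.table.groupby("sample")["intensity_log2"].median()
        assert np.allclose(medians, res.reference_median, atol=1e-9)

    def test_within_sample_differences_preserved_exactly(self, two_condition_table):
        res = median_normalize(two_condition_table)
        for s, grp in two_condition_table.groupby("sample"):
            before = grp.sort_values("peptide")["intensity_log2"].to_numpy()
            after = res.table[res.table["sample"] == s].sort_values("peptide")["intensity_log2"].to_numpy()
            assert np.allclose(np.diff(before), np.diff(after), atol=0)

    def test_empty_sample_is_a_named_error(self):
        table = make_table(sample_records("A", [10]) + sample_records("B", [np.nan]))
        with pytest.raises(ValueError, match="'B'"):
            median_normalize(table)

    def test_missing_values_stay_missing(self):
        table = make_table(sample_records("A", [10, np.nan, 14]))
        res = median_normalize(table)
        assert res.table["intensity_log2"].isna().sum() == 1


class TestFilterMinObservations:
    def feature(self, protein, counts):
        rows = []
        for cond, n_obs in counts.items():
            for r in range(3):
                rows.append({"sample": f"{cond}_R{r+1}", "condition": cond, "replicate": r + 1,
                             "protein": protein,
                             "intensity_log2": 10.0 if r < n_obs else np.nan})
        return rows

    def test_any_mode_keeps_one_passing_condition(self):
        table = make_table(self.feature("P1", {"c1": 3, "c2": 0}))
        out = filter_min_observations(table, "protein", min_per_condition=2, mode="any")
        assert set(out["protein"]) == {"P1"}

    def test_all_mode_requires_every_condition(self):
        table = make_table(self.feature("P1", {"c1": 3, "c2": 0}))
        out = filter_min_observations(table, "protein", min_per_condition=2, mode="all")
        assert out.empty

    def test_min_one_any_drops_only_never_observed(self):
        table = make_table(self.feature("P1", {"c1": 1, "c2": 0}) + self.feature("P2", {"c1": 0, "c2": 0}))
        out = filter_min_observations(table, "protein", min_per_condition=1, mode="any")
        assert set(out["protein"]) == {"P1"}

    def test_monotone_in_threshold(self):
        table = make_table(self.feature("P1", {"c1": 3, "c2": 1})
                           + self.feature("P2", {"c1": 2, "c2": 2})
                           + self.feature("P3", {"c1": 1, "c2": 0}))
        kept = [set(filter_min_observations(table, "protein", m, "any")["protein"])
                for m in (1, 2, 3)]
        assert kept[0] >= kept[1] >= kept[2]

    def test_output_rows_are_a_subset(self, two_condition_table):
        out = filter_min_observations(two_condition_table, "peptide", 2, "any")
        merged = out.merge(two_condition_table, how="left", indicator=True)
        assert (merged["_merge"] == "both").all()


class TestImputeMnar:
    def big_matrix(self, missing_in_a=0):
        rng = np.random.default_rng(0)
        n = 20_000
        a = rng.normal(20, 2, size=n)
        a[:missing_in_a] = np.nan
        b = rng.normal(20, 2, size=n)
        return pd.DataFrame({"a": a, "b": b})

    def test_no_missing_is_identity(self):
        m = self.big_matrix(0).iloc[:50]
        res = impute_mnar(m, seed=1)
        pd.testing.assert_frame_equal(res.matrix, m)
        assert not res.imputed.any().any()

    def test_monte_carlo_moments_of_the_downshifted_normal(self):
        # sample mean ~20, sd ~2 -> imputed ~ Normal(20 - 1.8*2, (0.3*2)^2)
        m = self.big_matrix(missing_in_a=10_000)
        res = impute_mnar(m, shift_sd=1.8, width_sd=0.3, seed=2)
        obs = m["a"].dropna()
        mu_s, sd_s = obs.mean(), obs.std(ddof=1)
        drawn = res.matrix.loc[m["a"].isna(), "a"]
        n = len(drawn)
        target_mu = mu_s - 1.8 * sd_s
        target_sd = 0.3 * sd_s
        assert abs(drawn.mean() - target_mu) < 3 * target_sd / np.sqrt(n)
        assert abs(drawn.std(ddof=1) - target_sd) < 3 * target_sd * np.sqrt(2 / (n - 1))

    def test_zero_width_is_the_point_value(self):
        m = self.big_matrix(missing_in_a=100).iloc[:1000]
        res = impute_mnar(m, shift_sd=1.8, width_sd=0.0, seed=3)
        obs = m["a"].dropna()
        point = obs.mean() - 1.8 * obs.std(ddof=1)
        assert np.allclose(res.matrix.loc[m["a"].isna(), "a"], point)

    def test_deterministic_under_seed(self):
        m = self.big_matrix(missing_in_a=50).iloc[:500]
        r1 = impute_mnar(m, seed=4)
        r2 = impute_mnar(m, seed=4)
        pd.testing.assert_frame_equal(r1.matrix, r2.matrix)

    def test_too_few_observed_values_is_an_error(self):
        m = pd.DataFrame({"a": [1.0, np.nan, 2.0], "b": [np.nan] * 3})
        with pytest.raises(ValueError, match=">= 10"):
            impute_mnar(m)

    def test_sparse_sample_left_missing(self, caplog):
        rng = np.random.default_rng(5)
        m = pd.DataFrame({"a": rng.normal(20, 2, 30),
                          "b": [15.0] + [np.nan] * 29})
        with caplog.at_level("WARNING"):
            res = impute_mnar(m, seed=6)
        assert res.matrix["b"].isna().sum() == 29
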
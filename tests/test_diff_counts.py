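"""NB differential machinery: normalisation, dispersion recovery, Wald calibration."""

import numpy as np
import pandas as pd
import pytest

from gcregulome.diff_counts import (
    CountMatrix,
    classify_responsive,
    combined_degs,
    estimate_dispersion,
    nb_wald_test,
    run_contrast,
    size_factors,
)


def nb_matrix(rng, mu, alpha, n_samples, factors=None):
    factors = np.ones(n_samples) if factors is None else np.asarray(factors)
    shape = 1.0 / alpha
    cols = {}
    for j in range(n_samples):
        lam = rng.gamma(shape, mu * alpha * factors[j])
        cols[f"s{j}"] = rng.poisson(lam)
    return pd.DataFrame(cols, index=[f"f{i}" for i in range(len(mu))])


class TestSizeFactors:
    def test_identical_columns(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert size_factors(df).to_numpy() == pytest.approx([1.0, 1.0])

    def test_doubled_column_hand_computed(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        # geometric mean per feature = a * sqrt(2); ratios 1/sqrt2 and sqrt2
        assert size_factors(df).to_numpy() == pytest.approx(
            [1 / np.sqrt(2), np.sqrt(2)]
        )

    def test_scale_equivariance_of_factor_ratios(self):
        # scaling one column by c multiplies its factor relative to any
        # other column by c (the geometric-mean reference shifts too, so
        # the individual factor moves by c^(1-1/m))
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.poisson(100, size=(200, 4)) + 1, columns=list("abcd"))
        base = size_factors(df)
        scaled = df.copy()
        scaled["c"] = scaled["c"] * 3
        new = size_factors(scaled)
        assert new["c"] / new["a"] == pytest.approx(3 * base["c"] / base["a"], rel=1e-6)
        assert new["c"] == pytest.approx(3 ** (1 - 1 / 4) * base["c"], rel=1e-6)

    def test_feature_permutation_invariance(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.poisson(50, size=(100, 3)) + 1, columns=list("abc"))
        perm = df.sample(frac=1.0, random_state=2)
        pd.testing.assert_series_equal(size_factors(df), size_factors(perm))

    def test_no_allpositive_feature_rejected(self):
        df = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(df)


class TestDispersion:
    def test_poisson_data_shrinks_to_zero(self):
        rng = np.random.default_rng(2)
        mu = rng.uniform(100, 1000, size=400)
        counts = pd.DataFrame(
            {f"s{j}": rng.poisson(mu) for j in range(50)}, index=[f"f{i}" for i in range(400)]
        )
        alpha = estimate_dispersion(counts, size_factors(counts))
        assert alpha.median() <= 0.01

    def test_recovers_true_dispersion(self):
        rng = np.random.default_rng(3)
        mu = rng.uniform(200, 2000, size=500)
        counts = nb_matrix(rng, mu, alpha=0.05, n_samples=10)
        a = estimate_dispersion(counts, size_factors(counts))
        assert 0.025 <= a.median() <= 0.1

    def test_constant_feature_floored(self):
        counts = pd.DataFrame({"a": [100, 7], "b": [100, 9], "c": [100, 8]})
        a = estimate_dispersion(counts, pd.Series(1.0, index=counts.columns))
        assert a.iloc[0] <= 1e-6

    def test_single_replicate_everywhere_rejected(self):
        counts = pd.DataFrame({"a": [10], "b": [20]})
        groups = pd.Series(["x", "y"], index=["a", "b"])
        with pytest.raises(ValueError):
            estimate_dispersion(counts, pd.Series(1.0, index=counts.columns), groups)


class TestWald:
    @staticmethod
    def _fixture(rng, m=500, effect=1.0, alpha=0.05, depth_mu=500.0, reps=4, frac_planted=0.1):
        # plant the effect on a subset so normalisation cannot absorb it
        mu = np.full(m, depth_mu)
        eff = np.ones(m)
        planted = rng.choice(m, size=int(frac_planted * m), replace=False)
        eff[planted] = effect
        treated = nb_matrix(rng, mu * eff, alpha, reps)
        treated.columns = [f"t{j}" for j in range(reps)]
        ref = nb_matrix(rng, mu, alpha, reps)
        ref.columns = [f"r{j}" for j in range(reps)]
        counts = pd.concat([treated, ref], axis=1)
        groups = pd.Series(
            ["treated"] * reps + ["ref"] * reps, index=counts.columns
        )
        factors = size_factors(counts)
        disp = estimate_dispersion(counts, factors, groups)
        res = nb_wald_test(counts, factors, disp, groups, "treated", "ref")
        res["planted"] = np.isin(np.arange(m), planted)
        return res

    def test_null_gives_no_calls(self):
        res = self._fixture(np.random.default_rng(4), effect=1.0)
        assert res["log2fc"].abs().mean() < 0.2
        assert (res["q"] < 0.1).mean() <= 0.02

    def test_planted_effect_recovered(self):
        res = self._fixture(np.random.default_rng(5), effect=4.0)
        hits = res[res["planted"]]
        assert 1.6 <= hits["log2fc"].mean() <= 2.4
        assert (hits["q"] < 0.01).mean() >= 0.9

    def test_type_one_error_calibrated(self):
        res = self._fixture(np.random.default_rng(6), m=5000, effect=1.0)
        frac = (res["p"] < 0.01).mean()
        assert 0.005 <= frac <= 0.02

    def test_direction_matches_sign(self):
        res = self._fixture(np.random.default_rng(7), m=100, effect=0.25)
        assert (res.loc[res["log2fc"] > 0, "direction"] == "enhanced").all()
        assert (res.loc[res["log2fc"] < 0, "direction"] == "reduced").all()

    def test_empty_group_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [2, 3]})
        groups = pd.Series(["x", "x"], index=counts.columns)
        with pytest.raises(ValueError):
            nb_wald_test(
                counts,
                pd.Series(1.0, index=counts.columns),
                pd.Series(0.05, index=counts.index),
                groups,
                "treated",
                "x",
            )


class TestClassification:
    def _results(self, qs, fcs):
        return pd.DataFrame(
            {"q": qs, "log2fc": fcs, "direction": np.where(np.array(fcs) > 0, "enhanced", "reduced")},
            index=[f"g{i}" for i in range(len(qs))],
        )

    def test_threshold_rule(self):
        res = self._results([0.005, 0.02, 0.005], [np.log2(2.5), np.log2(10), 0.5])
        hits = classify_responsive(res, q_max=0.01, min_fold=2.0)
        # passes: q<0.01 AND |fc|>=2; the q=0.02 site fails despite fc=10
        assert list(hits.index) == ["g0"]

    def test_combined_deg_union(self):
        r6 = self._results([0.001, 0.5], [2.0, 0.1])
        r24 = self._results([0.9, 0.001], [0.1, -2.0])
        degs = combined_degs({6.0: r6, 24.0: r24}, q_max=0.01, min_fold=2.0)
        assert set(degs.index) == {"g0", "g1"}
        assert degs.at["g1", "timepoint"] == 24.0


def test_run_contrast_smoke():
    rng = np.random.default_rng(8)
    counts = pd.DataFrame(
        rng.poisson(200, size=(50, 6)), columns=[f"s{j}" for j in range(6)],
        index=[f"f{i}" for i in range(50)],
    )
    samples = pd.DataFrame({"cond": ["a"] * 3 + ["b"] * 3}, index=counts.columns)
    res = run_contrast(CountMatrix(counts, samples), "cond", "b", "a")
    assert set(res.columns) >= {"log2fc", "se", "wald_stat", "p", "q", "direction"}
    assert (res["q"] >= res["p"] - 1e-12).all()
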
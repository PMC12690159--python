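"""Mediation machinery: standardization, partial correlation, ANCOVA and
the bootstrap mediation model, each against an independent construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cogflex.mediation import (
    BootstrapConfig,
    MediationModel,
    ancova_group_difference,
    effect_decomposition,
    fit_mediation,
    partial_correlation,
    standardize,
)


class TestStandardize:
    def test_forced_example(self):
        assert standardize([1, 2, 3]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_idempotent(self):
        z = standardize(np.random.default_rng(0).normal(3, 5, 40))
        assert standardize(z) == pytest.approx(z)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 2**20), st.integers(5, 60))
    def test_mean_zero_unit_sd(self, seed, n):
        x = np.random.default_rng(seed).normal(2, 7, n)
        z = standardize(x)
        assert z.mean() == pytest.approx(0.0, abs=1e-10)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            standardize([2.0] * 10)


class TestPartialCorrelation:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        cov = rng.normal(size=30)
        assert partial_correlation(x, x, cov[:, None]).r == pytest.approx(1.0)

    def test_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {"x": rng.normal(size=50), "y": rng.normal(size=50),
             "c1": rng.normal(size=50), "c2": rng.normal(size=50)}
        )
        df["y"] += 0.5 * df["x"] + 0.3 * df["c1"]
        ours = partial_correlation(df["x"], df["y"], df[["c1", "c2"]].to_numpy())
        theirs = pg.partial_corr(data=df, x="x", y="y", covar=["c1", "c2"])
        assert ours.r == pytest.approx(float(theirs["r"].iloc[0]), abs=1e-9)
        assert ours.p == pytest.approx(float(theirs["p_val"].iloc[0]), abs=1e-9)
        assert ours.df == 50 - 2 - 2

    def test_large_sample_null(self):
        rng = np.random.default_rng(3)
        n = 10_000
        c = rng.normal(size=n)
        x, y = rng.normal(size=n), rng.normal(size=n)
        assert abs(partial_correlation(x, y, c[:, None]).r) < 0.05

    def test_equals_pearson_when_covariate_is_noise(self):
        rng = np.random.default_rng(4)
        n = 20_000
        x = rng.normal(size=n)
        y = 0.6 * x + rng.normal(size=n)
        noise = rng.normal(size=n)
        r_partial = partial_correlation(x, y, noise[:, None]).r
        r_pearson = np.corrcoef(x, y)[0, 1]
        assert r_partial == pytest.approx(r_pearson, abs=0.01)

    def test_degenerate_inputs_rejected(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        c = rng.normal(size=20)
        with pytest.raises(ValueError):  # collinear covariates
            partial_correlation(x, x + 1, np.column_stack([c, 2 * c]))
        with pytest.raises(ValueError):  # zero-variance input
            partial_correlation(np.zeros(20), x, c[:, None])
        with pytest.raises(ValueError):  # too few observations
            partial_correlation(x[:3], x[:3] + 1, c[:3, None])


class TestAncova:
    def _data(self, rng, n=40, group_effect=0.0):
        g = np.repeat(["a", "b"], n // 2)
        cov = rng.normal(size=n)
        y = 0.5 * cov + rng.normal(size=n) + np.where(g == "b", group_effect, 0.0)
        return pd.DataFrame({"group": g, "sdq_conduct": cov, "y": y})

    def test_identical_groups_f_near_zero(self):
        rng = np.random.default_rng(6)
        half = self._data(rng, n=20)[lambda d: d.group == "a"]
        data = pd.concat([half, half.assign(group="b")], ignore_index=True)
        res = ancova_group_difference(data, "y")
        assert res.F == pytest.approx(0.0, abs=1e-20)

    def test_outcome_equal_to_covariate_absorbed(self):
        rng = np.random.default_rng(7)
        data = self._data(rng)
        data["y"] = data["sdq_conduct"]
        res = ancova_group_difference(data, "y")
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_matches_explicit_rss_oracle(self):
        rng = np.random.default_rng(8)
        data = self._data(rng, n=40, group_effect=0.4)
        res = ancova_group_difference(data, "y")
        # oracle: F from residual sums of squares of nested OLS fits
        g = (data["group"] == "b").to_numpy(float)
        full = np.column_stack([np.ones(40), g, data["sdq_conduct"]])
        reduced = np.column_stack([np.ones(40), data["sdq_conduct"]])
        y = data["y"].to_numpy()

        def rss(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            return float(((y - X @ beta) ** 2).sum())

        f_oracle = (rss(reduced) - rss(full)) / (rss(full) / (40 - 3))
        assert res.F == pytest.approx(f_oracle, rel=1e-9)
        assert (res.df_num, res.df_den) == (1, 37)
        assert set(res.descriptives.index) == {"a", "b"}

    def test_small_groups_rejected(self):
        data = pd.DataFrame(
            {"group": ["a", "a", "b", "b"], "sdq_conduct": [0, 1, 0, 1], "y": [1, 2, 3, 4]}
        )
        with pytest.raises(ValueError):
            ancova_group_difference(data, "y")


def _dataset(rng, n=80, a=0.6, b=0.5, cp=0.2):
    c = rng.normal(size=n)
    x = rng.normal(size=n) + 0.3 * c
    m = a * x + 0.3 * c + rng.normal(size=n)
    y = cp * x + b * m + 0.3 * c + rng.normal(size=n)
    return x, m, y, c[:, None]


class TestMediationModel:
    def test_ols_identity_exact(self):
        """total = direct + a*b to machine precision on any dataset."""
        for seed in range(5):
            x, m, y, c = _dataset(np.random.default_rng(seed))
            res = fit_mediation(x, m, y, c, boot=BootstrapConfig(n_resamples=1000, seed=0))
            assert res.total == pytest.approx(res.direct + res.indirect, abs=1e-12)

    def test_null_a_path_ci_straddles_zero(self):
        rng = np.random.default_rng(11)
        n = 2000
        c = rng.normal(size=n)
        x = rng.normal(size=n)
        m = 0.3 * c + rng.normal(size=n)          # independent of x
        y = 0.5 * m + rng.normal(size=n)
        res = fit_mediation(x, m, y, c[:, None], boot=BootstrapConfig(n_resamples=2000, seed=1))
        lo, hi = res.indirect_boot_ci
        assert lo < 0 < hi
        assert abs(res.indirect) < 0.05
        assert not res.significant_indirect

    def test_seeded_ci_reproducible(self):
        x, m, y, c = _dataset(np.random.default_rng(12))
        boot = BootstrapConfig(n_resamples=1500, seed=99)
        r1 = fit_mediation(x, m, y, c, boot=boot)
        r2 = fit_mediation(x, m, y, c, boot=boot)
        assert r1.indirect_boot_ci == r2.indirect_boot_ci
        assert r1.paths["a"].boot_ci == r2.paths["a"].boot_ci

    def test_unstandardized_input_rejected_when_required(self):
        x, m, y, c = _dataset(np.random.default_rng(13))
        with pytest.raises(ValueError):
            MediationModel(x * 3 + 5, m, y, c, standardize_vars=False)

    def test_minimum_sample_size(self):
        x, m, y, c = _dataset(np.random.default_rng(14), n=8)
        with pytest.raises(ValueError):
            MediationModel(x, m, y, c)

    def test_analytic_paths_match_statsmodels_formula_route(self):
        import statsmodels.formula.api as smf

        x, m, y, c = _dataset(np.random.default_rng(15))
        df = pd.DataFrame({
            "x": standardize(x), "m": standardize(m),
            "y": standardize(y), "c": standardize(c[:, 0]),
        })
        res = fit_mediation(x, m, y, c, boot=BootstrapConfig(n_resamples=1000, seed=0))
        a_ref = smf.ols("m ~ x + c", df).fit().params["x"]
        full_ref = smf.ols("y ~ x + m + c", df).fit()
        assert res.paths["a"].coef == pytest.approx(a_ref, abs=1e-10)
        assert res.paths["b"].coef == pytest.approx(full_ref.params["m"], abs=1e-10)
        assert res.paths["direct"].coef == pytest.approx(full_ref.params["x"], abs=1e-10)

    def test_summary_and_effect_table(self):
        x, m, y, c = _dataset(np.random.default_rng(16))
        res = fit_mediation(x, m, y, c, boot=BootstrapConfig(n_resamples=1000, seed=2))
        table = res.effect_table()
        assert list(table["effect"]) == ["Total", "Direct", "Indirect"]
        assert table["relative_pct"].iloc[0] == pytest.approx(100.0)
        assert table["relative_pct"].iloc[1:].sum() == pytest.approx(100.0)
        text = res.summary()
        assert "indirect" in text and "R^2" in text

    def test_bootstrap_config_validation(self):
        with pytest.raises(ValueError):
            BootstrapConfig(n_resamples=500)
        with pytest.raises(ValueError):
            BootstrapConfig(ci_level=1.5)
        with pytest.raises(ValueError):
            BootstrapConfig(method="bca")


class TestEffectDecomposition:
    def test_zero_indirect_all_direct(self):
        dec = effect_decomposition(direct=0.4, indirect=0.0)
        assert dec["direct_pct"] == pytest.approx(100.0)

    def test_zero_total_undefined_percentages(self):
        dec = effect_decomposition(direct=0.4, indirect=-0.4)
        assert np.isnan(dec["direct_pct"])

    def test_percentages_sum_to_hundred(self):
        dec = effect_decomposition(direct=-0.373, indirect=-0.397)
        assert dec["direct_pct"] + dec["indirect_pct"] == pytest.approx(100.0)
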
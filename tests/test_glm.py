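"""Poisson log-linear RS models and analysis of deviance."""

import numpy as np
import pandas as pd
import pytest

from spawnrs.glm import (
    MODEL_1,
    MODEL_2,
    MODEL_3,
    ModelSpec,
    analysis_of_deviance,
    deviance_test,
    fit_poisson_loglinear,
    predict_mean_rs,
)


def _table(rs, **cols):
    n = len(rs)
    base = {
        "rs": rs,
        "year": cols.get("year", ["2002"] * n),
        "seawinter": cols.get("seawinter", ["MSW"] * n),
        "stockstage": cols.get("stockstage", ["fry"] * n),
        "sex": cols.get("sex", ["F"] * n),
    }
    return pd.DataFrame(base)


class TestFit:
    def test_intercept_only_closed_form(self):
        table = _table([0, 1, 2, 3])
        fit = fit_poisson_loglinear(table, ModelSpec(("year",)))
        assert fit.coefficients["Intercept"] == pytest.approx(np.log(1.5), abs=1e-8)

    def test_binary_factor_log_ratio(self):
        table = _table(
            [2, 2, 2, 4, 4, 4],
            seawinter=["MSW"] * 3 + ["SSW"] * 3,
        )
        fit = fit_poisson_loglinear(table, ModelSpec(("seawinter",)))
        assert fit.coefficients["C(seawinter)[T.SSW]"] == pytest.approx(
            np.log(2), abs=1e-8
        )

    def test_reference_levels_are_treatment_baseline(self):
        table = _table(
            [1, 2, 3, 4],
            year=["2002", "2003", "2002", "2003"],
            seawinter=["MSW", "MSW", "SSW", "SSW"],
        )
        fit = fit_poisson_loglinear(table, ModelSpec(("year", "seawinter")))
        names = list(fit.coefficients.index)
        assert "C(year)[T.2003]" in names and "C(seawinter)[T.SSW]" in names

    def test_unknown_sex_rows_excluded(self):
        table = _table([1, 2, 3, 4, 5], sex=["F", "M", "U", "F", "M"])
        fit = fit_poisson_loglinear(table, ModelSpec(("sex",)))
        assert fit.n == 4 and fit.n_excluded == 1

    def test_fitted_sum_equals_observed_sum(self, rng):
        """Poisson log-link score equation: sum of fitted means = sum of
        counts."""
        n = 300
        table = _table(
            rng.poisson(2.0, n),
            year=rng.choice(["2002", "2003", "2004"], n),
            seawinter=rng.choice(["MSW", "SSW"], n),
            stockstage=rng.choice(["fry", "smolt", "wild"], n),
            sex=rng.choice(["F", "M"], n),
        )
        fit = fit_poisson_loglinear(table, MODEL_2)
        assert fit.result.fittedvalues.sum() == pytest.approx(
            table["rs"].sum(), rel=1e-8
        )

    def test_residual_df_identity(self, rng):
        n = 200
        table = _table(
            rng.poisson(2.0, n),
            seawinter=rng.choice(["MSW", "SSW"], n),
            sex=rng.choice(["F", "M"], n),
        )
        fit = fit_poisson_loglinear(table, ModelSpec(("seawinter", "sex"), True))
        assert fit.df_resid == fit.n - len(fit.coefficients)


class TestDeviance:
    def test_identical_models(self):
        out = deviance_test(100.0, 50, 100.0, 50)
        assert out["delta_deviance"] == 0.0 and out["p"] == 1.0

    def test_printed_deviance_comparison(self):
        """Additive vs full-interaction model on the printed fit summaries:
        a drop of 29.21 deviance units on 5 df."""
        out = deviance_test(2009.9, 532, 1980.69, 527)
        assert out["delta_deviance"] == pytest.approx(29.21, abs=1e-9)
        assert out["delta_df"] == 5
        assert out["p"] < 0.001

    def test_nesting_enforced(self, rng):
        n = 120
        table = _table(
            rng.poisson(2.0, n),
            seawinter=rng.choice(["MSW", "SSW"], n),
            sex=rng.choice(["F", "M"], n),
            stockstage=rng.choice(["fry", "wild"], n),
        )
        full = fit_poisson_loglinear(table, ModelSpec(("seawinter", "sex")))
        other = fit_poisson_loglinear(table, ModelSpec(("stockstage",)))
        with pytest.raises(ValueError, match="nested"):
            analysis_of_deviance(full, other)

    def test_deviance_non_increasing_with_terms(self, rng):
        n = 250
        table = _table(
            rng.poisson(2.0, n),
            year=rng.choice(["2002", "2003"], n),
            seawinter=rng.choice(["MSW", "SSW"], n),
            stockstage=rng.choice(["fry", "smolt", "wild"], n),
            sex=rng.choice(["F", "M"], n),
        )
        specs = [
            ModelSpec(("year",)),
            ModelSpec(("year", "seawinter")),
            ModelSpec(("year", "seawinter", "stockstage", "sex")),
            MODEL_1,
        ]
        devs = [fit_poisson_loglinear(table, sp).deviance for sp in specs]
        assert all(devs[i] >= devs[i + 1] - 1e-8 for i in range(len(devs) - 1))

    def test_null_extra_factor_p_uniform(self, rng):
        """Adding a factor unrelated to the response gives uniform p."""
        from scipy import stats

        pvals = []
        for _ in range(120):
            n = 150
            table = _table(
                rng.poisson(2.0, n),
                seawinter=rng.choice(["MSW", "SSW"], n),
                sex=rng.choice(["F", "M"], n),
            )
            full = fit_poisson_loglinear(table, ModelSpec(("seawinter", "sex")))
            red = fit_poisson_loglinear(table, ModelSpec(("seawinter",)))
            pvals.append(analysis_of_deviance(full, red)["p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestPredict:
    def test_intercept_only_returns_overall_mean(self):
        table = _table([0, 1, 2, 3, 4])
        fit = fit_poisson_loglinear(table, ModelSpec(("year",)))
        assert predict_mean_rs(fit, {"year": "2002"}) == pytest.approx(2.0)

    def test_saturated_two_factor_recovers_cell_means(self, rng):
        levels = [("MSW", "F"), ("MSW", "M"), ("SSW", "F"), ("SSW", "M")]
        rows = []
        means = {c: m for c, m in zip(levels, (4.0, 2.0, 1.0, 0.5))}
        for (sw, sex), m in means.items():
            rows += [
                {"rs": v, "seawinter": sw, "sex": sex, "year": "2002",
                 "stockstage": "fry"}
                for v in rng.poisson(m, 200)
            ]
        table = pd.DataFrame(rows)
        fit = fit_poisson_loglinear(table, ModelSpec(("seawinter", "sex"), True))
        for (sw, sex), _ in means.items():
            cell = table[(table["seawinter"] == sw) & (table["sex"] == sex)]
            assert predict_mean_rs(
                fit, {"seawinter": sw, "sex": sex}
            ) == pytest.approx(cell["rs"].mean(), rel=1e-6)

    def test_unknown_level_rejected(self):
        table = _table([1, 2, 3])
        fit = fit_poisson_loglinear(table, ModelSpec(("seawinter",)))
        with pytest.raises(ValueError):
            predict_mean_rs(fit, {"seawinter": "4SW"})
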
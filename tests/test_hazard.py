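"""Hazard model estimation: oracles, nesting, selection, invariances."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from mvpatiming.effects import effect_table
from mvpatiming.hazard import (
    HazardFit,
    ModelSpec,
    Term,
    fit_hazard,
    fit_moderator_model,
    lrt,
    select_time_polynomial,
)
from mvpatiming.synthesize import TrueHazardModel, simulate_person_period


@pytest.fixture(scope="module")
def flat_table():
    model = TrueHazardModel(degree=1, beta_time=(-2.5, 0.08), sigma_u=0.0,
                            risk_window=(9, 16))
    tbl, _ = simulate_person_period(model, 200, 5, seed=31)
    return tbl


@pytest.fixture(scope="module")
def mixed_table():
    model = TrueHazardModel(degree=1, beta_time=(-3.5, 0.15), sigma_u=1.0,
                            risk_window=(9, 13))
    tbl, _ = simulate_person_period(model, 150, 6, seed=7)
    return tbl


class TestFixedEffectsPath:
    def test_matches_statsmodels_logit(self, flat_table):
        fit = fit_hazard(flat_table, ModelSpec(degree=2, random_intercept=False))
        X = np.column_stack(
            [np.ones(len(flat_table)), flat_table["t"], flat_table["t"] ** 2]
        )
        oracle = sm.Logit(flat_table["event"], X).fit(disp=0)
        np.testing.assert_allclose(fit.beta, oracle.params.values, atol=1e-4)
        np.testing.assert_allclose(fit.minus2LL, -2 * oracle.llf, rtol=1e-8)
        np.testing.assert_allclose(
            np.sqrt(np.diag(fit.vcov)), oracle.bse.values, rtol=1e-4
        )

    def test_degenerate_tables_rejected(self, flat_table):
        allcens = flat_table.copy()
        allcens["event"] = 0
        with pytest.raises(ValueError, match="separat"):
            fit_hazard(allcens, ModelSpec(degree=1))

    def test_constant_moderator_columns_dropped(self, flat_table):
        tbl = flat_table.copy()
        for c in ("male", "bmi_overweight", "bmi_obese", "sports", "school_day"):
            tbl[c] = 0
        with pytest.warns(UserWarning, match="rank-deficient"):
            fit = fit_hazard(
                tbl,
                ModelSpec(degree=1, moderator="sex", include_interactions=True,
                          random_intercept=False),
            )
        assert fit.converged
        assert "male" in fit.dropped and "male:t" in fit.dropped
        assert fit.names == ["const", "t"]


class TestMixedPath:
    def test_agrees_with_lme4_glmer(self, mixed_table, tmp_path):
        """Independent oracle: lme4 adaptive Gauss-Hermite (nAGQ=9)."""
        csv = tmp_path / "pp.csv"
        mixed_table.to_csv(csv, index=False)
        fit = fit_hazard(mixed_table, ModelSpec(degree=1, n_quad=9))
        rscript = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(event ~ t + (1|participant_id), data=d,
                       family=binomial, nAGQ=9)
            cat(fixef(m), sqrt(unlist(VarCorr(m))),
                as.vector(coef(summary(m))[, "Std. Error"]), sep="\\n")
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, check=True
        )
        vals = [float(x) for x in out.stdout.split()]
        b0, b1, sigma, se0, se1 = vals
        np.testing.assert_allclose(fit.beta, [b0, b1], atol=2e-3)
        np.testing.assert_allclose(fit.sigma_u, sigma, atol=2e-3)
        np.testing.assert_allclose(
            np.sqrt(np.diag(fit.vcov)), [se0, se1], rtol=0.02
        )

    def test_quadrature_converged_between_9_and_15_nodes(self, mixed_table):
        f9 = fit_hazard(mixed_table, ModelSpec(degree=1, n_quad=9))
        f15 = fit_hazard(mixed_table, ModelSpec(degree=1, n_quad=15))
        assert np.abs(f9.beta - f15.beta).max() < 1e-3
        assert abs(f9.sigma_u - f15.sigma_u) < 1e-3

    def test_minus2LL_non_increasing_in_nested_expansion(self, mixed_table):
        m2 = [
            fit_hazard(mixed_table, ModelSpec(degree=d)).minus2LL for d in (1, 2, 3)
        ]
        assert m2[1] <= m2[0] + 1e-6 and m2[2] <= m2[1] + 1e-6

    def test_or_table_invariant_to_time_scaling(self, mixed_table):
        fit_a = fit_hazard(mixed_table, ModelSpec(degree=2, time_center=8.0,
                                                  time_scale=10.0))
        fit_b = fit_hazard(mixed_table, ModelSpec(degree=2, time_center=0.0,
                                                  time_scale=1.0))
        ta = effect_table(fit_a, 9, None, np.arange(9, 14))
        tb = effect_table(fit_b, 9, None, np.arange(9, 14))
        np.testing.assert_allclose(
            ta["odds_ratio"], tb["odds_ratio"], rtol=1e-3
        )
        np.testing.assert_allclose(
            ta["hazard_prob"], tb["hazard_prob"], atol=1e-4
        )


class TestLRT:
    def _mk_fit(self, names, m2ll, n_rows=100):
        terms = [Term(power=k) for k in range(len(names))]
        return HazardFit(
            spec=ModelSpec(degree=max(1, len(names) - 1), random_intercept=False),
            terms=terms, beta=np.zeros(len(names)),
            vcov=np.eye(len(names)), sigma_u=0.0, minus2LL=m2ll,
            n_rows=n_rows, n_persons=10, n_events=20, converged=True,
        )

    def test_identical_fits_give_zero_statistic(self):
        a = self._mk_fit(["const", "t"], 1000.0)
        chi2, df, p = lrt(a, a)
        assert chi2 == 0 and p == 1

    def test_chi_square_quantile_identity(self):
        nested = self._mk_fit(["const", "t"], 1000.0)
        full = self._mk_fit(["const", "t", "t2"], 996.16)
        chi2, df, p = lrt(nested, full)
        assert df == 1
        assert chi2 == pytest.approx(3.84)
        assert p == pytest.approx(0.050, abs=5e-4)

    def test_non_nested_rejected(self):
        a = self._mk_fit(["const", "t", "t2"], 1000.0)
        b = self._mk_fit(["const", "t"], 990.0)
        with pytest.raises(ValueError, match="nested"):
            lrt(a, b)

    def test_different_tables_rejected(self):
        a = self._mk_fit(["const", "t"], 1000.0, n_rows=100)
        b = self._mk_fit(["const", "t", "t2"], 990.0, n_rows=120)
        with pytest.raises(ValueError, match="table"):
            lrt(a, b)


class TestSelection:
    def test_max_degree_one_returns_empty_trail(self, flat_table):
        degree, fits, trail = select_time_polynomial(
            flat_table, max_degree=1, random_intercept=False
        )
        assert degree == 1 and trail == [] and set(fits) == {1}

    def test_pronounced_cubic_is_selected(self):
        model = TrueHazardModel(
            degree=3,
            # rises through the afternoon, peaks in the evening, drops late
            beta_time=(-60.0, 9.30, -0.468, 0.00744),
            sigma_u=0.0,
            risk_window=(9, 23),
        )
        tbl, _ = simulate_person_period(model, 250, 8, seed=3)
        degree, _, _ = select_time_polynomial(tbl, random_intercept=False)
        assert degree == 3

    def test_moderator_design_expands_to_indicator_columns(self, flat_table):
        tbl = flat_table.copy()
        rng = np.random.default_rng(0)
        pids = tbl["participant_id"].unique()
        cat = dict(zip(pids, rng.choice([0, 1, 2], size=pids.size)))
        tbl["bmi_overweight"] = tbl["participant_id"].map(cat).eq(1).astype(int)
        tbl["bmi_obese"] = tbl["participant_id"].map(cat).eq(2).astype(int)
        fit = fit_moderator_model(tbl, "bmi_category", 2, random_intercept=False)
        # 3 time columns + 2 dummies + 2x2 interactions
        assert len(fit.names) == 3 + 2 + 4
        assert "bmi_obese:t^2" in fit.names
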
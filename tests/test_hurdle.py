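"""Hurdle regression: MLE correctness, oracles, LR test, transfer analyses."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import kstest
from statsmodels.discrete.truncated_model import TruncatedLFPoisson

from pollenflow.hurdle import (
    HurdleSpec,
    fit_hurdle,
    likelihood_ratio_test,
    quantile_residuals,
    run_transfer_analyses,
)
from pollenflow.synthetic import simulate_hurdle_counts

TRUTH_ZERO = np.array([-0.5, -0.01])
TRUTH_COUNT = np.array([2.0, -0.005])


def make_data(seed, n=500, nb_size=1.5, zero=TRUTH_ZERO, count=TRUTH_COUNT):
    rng = np.random.default_rng(seed)
    r = rng.uniform(0, 300, n)
    X = np.column_stack([np.ones(n), r])
    y = simulate_hurdle_counts(X, X, zero, count, nb_size=nb_size, seed=seed + 1)
    return pd.DataFrame({"sum_count": y, "r": r, "n_flowers_sampled": np.ones(n)})


SPEC = HurdleSpec(zero_formula="r", count_formula="r")


class TestFit:
    def test_single_replicate_estimates_dominate_truth(self):
        """MLE property: the fitted likelihood is at least the likelihood at
        the generating parameters, and decay signs are recovered."""
        from pollenflow.hurdle import _logit_loglik, _trunc_count_negll

        df = make_data(7)
        fit = fit_hurdle(df, SPEC, seed=0)
        assert fit.converged
        y = df["sum_count"].to_numpy()
        X = np.column_stack([np.ones(len(df)), df["r"].to_numpy()])
        ll_truth = _logit_loglik(TRUTH_ZERO, X, (y > 0).astype(float))
        pos = y > 0
        ll_truth += -_trunc_count_negll(np.r_[TRUTH_COUNT, np.log(1.5)],
                                        X[pos], y[pos], np.zeros(pos.sum()), "negbin")
        assert fit.loglik >= ll_truth - 1e-8
        assert fit.zero_coefs["r"] < 0
        assert fit.count_coefs["r"] < 0
        assert 0.5 < fit.nb_size < 5

    def test_zero_part_equals_logistic_oracle(self):
        df = make_data(11)
        fit = fit_hurdle(df, SPEC, seed=0)
        X = sm.add_constant(df["r"].to_numpy())
        oracle = sm.Logit((df["sum_count"] > 0).astype(float), X).fit(disp=0)
        assert np.allclose(fit.zero_coefs.to_numpy(), oracle.params, atol=1e-4)
        assert np.allclose(fit.zero_se.to_numpy(), oracle.bse, atol=1e-3)

    def test_count_part_matches_truncated_poisson_oracle(self):
        df = make_data(13, nb_size=None)
        fit = fit_hurdle(df, HurdleSpec("r", "r", family="poisson"), seed=0)
        pos = df["sum_count"] > 0
        X = sm.add_constant(df.loc[pos, "r"].to_numpy())
        oracle = TruncatedLFPoisson(df.loc[pos, "sum_count"].to_numpy(), X,
                                    truncation=0).fit(disp=0, maxiter=500,
                                                      method="newton")
        assert np.allclose(fit.count_coefs.to_numpy(), oracle.params, atol=1e-3)
        assert fit.loglik_count == pytest.approx(oracle.llf, abs=1e-4)

    def test_loglik_separates(self):
        fit = fit_hurdle(make_data(3), SPEC, seed=0)
        assert fit.loglik == pytest.approx(fit.loglik_zero + fit.loglik_count, abs=1e-8)

    def test_poisson_is_negbin_limit(self):
        # data generated without overdispersion: both families agree
        df = make_data(5, nb_size=None)
        fp = fit_hurdle(df, HurdleSpec("r", "r", family="poisson"), seed=0)
        fn = fit_hurdle(df, HurdleSpec("r", "r", family="negbin"), seed=0)
        assert np.allclose(fp.count_coefs.to_numpy(), fn.count_coefs.to_numpy(),
                           atol=0.02)

    def test_offset_shifts_intercept(self):
        df = make_data(9)
        df2 = df.assign(n_flowers_sampled=7.0)
        f1 = fit_hurdle(df, SPEC, seed=0)
        f2 = fit_hurdle(df2, SPEC, seed=0)
        assert f2.count_coefs["Intercept"] == pytest.approx(
            f1.count_coefs["Intercept"] - np.log(7.0), abs=0.02)

    def test_degenerate_inputs(self):
        df = make_data(1)
        with pytest.raises(ValueError, match="no zeros"):
            fit_hurdle(df.assign(sum_count=df["sum_count"] + 1), SPEC)
        with pytest.raises(ValueError, match="all counts zero"):
            fit_hurdle(df.assign(sum_count=0), SPEC)
        with pytest.raises(ValueError, match="at least 10"):
            fit_hurdle(df.head(5), SPEC)

    def test_complete_separation_flagged(self):
        rng = np.random.default_rng(0)
        n = 60
        r = np.linspace(1, 200, n)
        y = np.where(r < 100, 1 + rng.poisson(3.0, n), 0)
        df = pd.DataFrame({"sum_count": y, "r": r, "n_flowers_sampled": np.ones(n)})
        fit = fit_hurdle(df, SPEC, seed=0)
        assert not fit.converged
        assert "separation" in fit.message


class TestLikelihoodRatio:
    def test_identical_specs(self):
        fit = fit_hurdle(make_data(2), SPEC, seed=0)
        stat, df, p = likelihood_ratio_test(fit, fit)
        assert (stat, df, p) == (0.0, 0, 1.0)

    def test_non_nested_error(self):
        d = make_data(2).assign(x2=np.random.default_rng(0).normal(size=500))
        f1 = fit_hurdle(d, HurdleSpec("r", "r"), seed=0)
        f2 = fit_hurdle(d, HurdleSpec("x2", "x2"), seed=0)
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(f1, f2)

    def test_null_calibration_and_nonnegativity(self):
        ps = []
        for rep in range(120):
            rng = np.random.default_rng(5000 + rep)
            n = 150
            r = rng.uniform(0, 300, n)
            x2 = rng.normal(size=n)
            X = np.column_stack([np.ones(n), r])
            y = simulate_hurdle_counts(X, X, [0.3, -0.005], [1.5, -0.003],
                                       nb_size=2.0, seed=6000 + rep)
            d = pd.DataFrame({"sum_count": y, "r": r, "x2": x2,
                              "n_flowers_sampled": np.ones(n)})
            full = fit_hurdle(d, HurdleSpec("r + x2", "r + x2"), seed=rep)
            red = fit_hurdle(d, HurdleSpec("r", "r"), seed=rep)
            stat, df, p = likelihood_ratio_test(full, red)
            assert stat >= 0.0
            assert df == 2
            ps.append(p)
        assert kstest(ps, "uniform").pvalue > 0.01


class TestQuantileResiduals:
    def test_well_specified_fit_gives_normal_residuals(self):
        df = make_data(21, n=800)
        fit = fit_hurdle(df, SPEC, seed=0)
        resid = quantile_residuals(fit, df, seed=0)
        assert kstest(resid, "norm").pvalue > 0.01


class TestTransferAnalyses:
    def test_all_three_run_on_fat_tail_scenario(self, fat_tail_transfers):
        for which in ("intrapop_differences", "intra_vs_inter_ecotypic",
                      "directionality"):
            fit, tidy, moran = run_transfer_analyses(fat_tail_transfers, which,
                                                     seed=0)
            assert fit.n_obs >= 10
            assert {"term", "component", "estimate", "se", "z", "p"} <= set(tidy.columns)
            # interaction terms present in the design
            assert any(":" in t for t in fit.count_coefs.index)
            assert moran is not None

    def test_exclusion_changes_n_obs_by_list_length(self, fat_tail_transfers):
        tr = fat_tail_transfers
        which = "intra_vs_inter_ecotypic"
        base, _, _ = run_transfer_analyses(tr, which, seed=0, residual_check=False)
        sub = tr[tr["transfer_class"].isin(["intra_ecotypic", "inter_ecotypic"])]
        drop = sub["recipient_id"].unique()[:3].tolist()
        n_dropped = sub["recipient_id"].isin(drop).sum()
        excl, _, _ = run_transfer_analyses(tr, which, exclude=drop, seed=0,
                                           residual_check=False)
        assert base.n_obs - excl.n_obs == n_dropped

    def test_unknown_analysis_rejected(self, fat_tail_transfers):
        with pytest.raises(ValueError, match="unknown analysis"):
            run_transfer_analyses(fat_tail_transfers, "everything")

    def test_directionality_requires_both_directions(self, fat_tail_transfers):
        one_way = fat_tail_transfers[fat_tail_transfers["direction"] != "SiToCa"]
        with pytest.raises(ValueError, match="inter-ecotypic"):
            run_transfer_analyses(one_way, "directionality")

    def test_type_effect_null_and_power(self):
        null_ok = power = 0
        n_rep = 40
        for rep in range(n_rep):
            rng = np.random.default_rng(7000 + rep)
            n = 150
            r = rng.uniform(0, 300, n)
            typ = (rng.uniform(size=n) < 0.5).astype(float)
            X = np.column_stack([np.ones(n), r, typ])
            d = {"r": r, "typ": typ, "n_flowers_sampled": np.ones(n)}
            y0 = simulate_hurdle_counts(X, X, [0.5, -0.004, 0.0], [1.2, -0.002, 0.0],
                                        nb_size=1.5, seed=8000 + rep)
            f0 = fit_hurdle(pd.DataFrame({**d, "sum_count": y0}),
                            HurdleSpec("r + typ", "r + typ"), seed=rep)
            p0 = f0.tidy().query("term == 'typ' and component == 'count'")["p"].iloc[0]
            null_ok += p0 > 0.05
            y1 = simulate_hurdle_counts(X, X, [0.5, -0.004, 0.0], [1.2, -0.002, 0.7],
                                        nb_size=1.5, seed=9000 + rep)
            f1 = fit_hurdle(pd.DataFrame({**d, "sum_count": y1}),
                            HurdleSpec("r + typ", "r + typ"), seed=rep)
            p1 = f1.tidy().query("term == 'typ' and component == 'count'")["p"].iloc[0]
            power += p1 <= 0.05
        assert null_ok >= 0.9 * n_rep - 2
        assert power >= 0.8 * n_rep
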
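"""Single and multiple imputation: identity, bounds, donor and recovery
properties."""

import numpy as np
import pandas as pd
import pytest

from metamiss.datatypes import IncompleteDataset, MEAN_DIFFERENCE, MetaDataset
from metamiss.imputation import (
    ALL_METHODS,
    CHAINED_METHODS,
    DONOR_METHODS,
    ImputationConfig,
    ImputationError,
    em_mvnorm,
    impute,
    impute_single,
)
from metamiss.meta_analysis import rubin_pool
from metamiss.missingness import DeletionPlan, apply_deletion

MULTIPLE_METHODS = [m for m in ALL_METHODS if m not in ("mean", "median")]


def _incomplete(md_dataset, fraction=0.5, target="BOTH", seed=9):
    plan = DeletionPlan("MCAR", target, fraction)
    return apply_deletion(md_dataset, plan, np.random.default_rng(seed))


def _tiny_incomplete(sd_t_values):
    """Minimal dataset with missing sd_t cells for single-imputation checks."""
    n = len(sd_t_values)
    df = pd.DataFrame(
        {
            "mean_c": np.linspace(1.0, 1.2, n),
            "mean_t": np.linspace(2.0, 2.2, n),
            "sd_c": [0.3] * n,
            "sd_t": sd_t_values,
            "n_c": [10.0] * n,
            "n_t": [10.0] * n,
        }
    )
    base = MetaDataset(MEAN_DIFFERENCE, df.copy())
    mask = df["sd_t"].isna().to_numpy()
    return IncompleteDataset(base=base, data=df, sd_deleted=mask,
                             ss_deleted=np.zeros(n, bool))


class TestSingleImputation:
    def test_mean_of_two_observed(self):
        inc = _tiny_incomplete([0.2, 0.4, np.nan])
        out = impute_single(inc, "mean")
        assert out.datasets[0].loc[2, "sd_t"] == pytest.approx(0.3)

    def test_mean_vs_median_on_skewed_column(self):
        inc = _tiny_incomplete([0.1, 0.1, 0.9, np.nan])
        assert impute_single(inc, "mean").datasets[0].loc[3, "sd_t"] == pytest.approx(
            (0.1 + 0.1 + 0.9) / 3
        )
        assert impute_single(inc, "median").datasets[0].loc[3, "sd_t"] == pytest.approx(0.1)

    def test_identity_on_complete_data(self):
        inc = _tiny_incomplete([0.2, 0.3, 0.4])
        out = impute_single(inc, "mean")
        pd.testing.assert_frame_equal(out.datasets[0], inc.data)

    def test_fully_missing_column_rejected(self):
        inc = _tiny_incomplete([np.nan, np.nan, np.nan])
        with pytest.raises(ImputationError):
            impute_single(inc, "mean")


class TestAllMethods:
    @pytest.mark.parametrize("method", MULTIPLE_METHODS)
    def test_identity_on_complete_data(self, md_dataset, method):
        inc = _incomplete(md_dataset, fraction=0.0)
        out = impute(inc, ImputationConfig(method=method, m=3),
                     np.random.default_rng(0))
        assert out.status == "ok"
        assert len(out.datasets) == 3
        for d in out.datasets:
            pd.testing.assert_frame_equal(d, md_dataset.data)

    @pytest.mark.parametrize("method", MULTIPLE_METHODS)
    def test_bounds_and_integrality_of_imputed_values(self, md_dataset, method):
        # every imputed SD must lie in [0.01, 1]; every imputed SS must be an
        # integer >= 5; observed cells must never change
        inc = _incomplete(md_dataset, fraction=0.5)
        out = impute(inc, ImputationConfig(method=method, m=3),
                     np.random.default_rng(1))
        assert out.status == "ok"
        for d in out.datasets:
            assert not d.isna().any().any()
            sd_imp = d.loc[inc.sd_deleted, ["sd_c", "sd_t"]].to_numpy()
            assert ((sd_imp >= 0.01) & (sd_imp <= 1.0)).all()
            ss_imp = d.loc[inc.ss_deleted, ["n_c", "n_t"]].to_numpy()
            assert (ss_imp >= 5).all()
            assert np.allclose(ss_imp, np.rint(ss_imp))
            obs = ~inc.data.isna()
            pd.testing.assert_frame_equal(d.where(obs), inc.data.where(obs))

    @pytest.mark.parametrize(
        "method", [m for m in MULTIPLE_METHODS if m in DONOR_METHODS]
    )
    def test_donor_methods_impute_observed_values_only(self, md_dataset, method):
        inc = _incomplete(md_dataset, fraction=0.4)
        out = impute(inc, ImputationConfig(method=method, m=2),
                     np.random.default_rng(2))
        for col in ("sd_c", "sd_t", "n_c", "n_t"):
            mis = inc.data[col].isna()
            observed = set(inc.data.loc[~mis, col])
            for d in out.datasets:
                assert set(d.loc[mis, col]) <= observed

    @pytest.mark.parametrize("method", MULTIPLE_METHODS)
    def test_between_imputation_variance_positive(self, md_dataset, method):
        # stochasticity across imputations is what Rubin's rules pool
        inc = _incomplete(md_dataset, fraction=0.4)
        out = impute(inc, ImputationConfig(method=method, m=5),
                     np.random.default_rng(3))
        col = "sd_t"
        mis = inc.data[col].isna()
        stacks = np.array([d.loc[mis, col].to_numpy() for d in out.datasets])
        assert stacks.var(axis=0).sum() > 0

    def test_too_few_observed_rows_raise_naming_the_method(self):
        inc = _tiny_incomplete([0.2, 0.3, np.nan, np.nan, np.nan, np.nan])
        with pytest.raises(ImputationError, match="pmm"):
            impute(inc, ImputationConfig(method="pmm", m=2), np.random.default_rng(0))


class TestChainedEquations:
    def test_mcar_imputations_recover_observed_mean(self, md_dataset):
        # under MCAR the deleted and observed cells share one distribution,
        # so imputed means must track the observed mean (Monte-Carlo check)
        inc = _incomplete(md_dataset, fraction=0.3, target="SD")
        out = impute(
            inc,
            ImputationConfig(method="linear_regression", m=100),
            np.random.default_rng(4),
        )
        mis = inc.data["sd_t"].isna()
        imputed = np.concatenate([d.loc[mis, "sd_t"].to_numpy() for d in out.datasets])
        obs = inc.data.loc[~mis, "sd_t"]
        pooled_se = np.sqrt(
            obs.var(ddof=1) / len(obs) + imputed.var(ddof=1) / len(imputed)
        )
        assert abs(imputed.mean() - obs.mean()) < 3 * pooled_se

    def test_imputation_order_has_no_systematic_effect(self, md_dataset):
        # reversing the default sd_t, sd_c, n_t, n_c order shifts pooled grand
        # means only within their pooled uncertainty
        from metamiss.effect_sizes import compute_effect_sizes
        from metamiss.meta_analysis import random_effects_fit

        inc = _incomplete(md_dataset, fraction=0.5)

        def pooled(order, seed):
            cfg = ImputationConfig(method="pmm", m=30, order=order)
            out = impute(inc, cfg, np.random.default_rng(seed))
            fits = []
            for d in out.datasets:
                es = compute_effect_sizes(d, MEAN_DIFFERENCE, "lnrr")
                fits.append(random_effects_fit(es["yi"], es["vi"]))
            return rubin_pool(fits)

        a = pooled(("sd_t", "sd_c", "n_t", "n_c"), 5)
        b = pooled(("n_c", "n_t", "sd_c", "sd_t"), 6)
        assert abs(a.mu - b.mu) < 3 * np.sqrt(a.se**2 + b.se**2)


class TestBootstrapEM:
    def test_em_recovers_bivariate_normal_correlation(self):
        # parameter-recovery oracle: 20% MCAR in one column of a bivariate
        # normal; the EM correlation estimate must track the truth
        rho = 0.6
        rng = np.random.default_rng(12)
        estimates = []
        for _ in range(10):
            z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=400)
            z[rng.uniform(size=400) < 0.2, 1] = np.nan
            mu, sigma = em_mvnorm(z)
            estimates.append(sigma[0, 1] / np.sqrt(sigma[0, 0] * sigma[1, 1]))
        estimates = np.asarray(estimates)
        se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - rho) < 3 * max(se, 1e-3)

    def test_gate_skips_above_missingness_cutoff(self, md_dataset):
        inc = _incomplete(md_dataset, fraction=0.7)
        out = impute(inc, ImputationConfig(method="bootstrap_em", m=2),
                     np.random.default_rng(0))
        assert out.status == "skipped"
        assert out.datasets == []
        assert "60%" in out.reason

    def test_runs_below_cutoff(self, md_dataset):
        inc = _incomplete(md_dataset, fraction=0.6)
        out = impute(inc, ImputationConfig(method="bootstrap_em", m=2),
                     np.random.default_rng(1))
        assert out.status == "ok"
        assert len(out.datasets) + len(out.failures) == 2
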
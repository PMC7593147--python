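"""Random-effects REML estimation and Rubin's-rules pooling."""

import json
import subprocess

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from metamiss.datatypes import MetaEstimate
from metamiss.meta_analysis import Z_95, random_effects_fit, reml_tau2, rubin_pool


def brute_force_tau2(yi, vi):
    """Independent REML oracle: dense grid plus local refinement."""
    yi = np.asarray(yi, float)
    vi = np.asarray(vi, float)

    def rll(t):
        w = 1 / (vi + t)
        mu = (w * yi).sum() / w.sum()
        return -0.5 * (
            np.log(vi + t).sum() + np.log(w.sum()) + (w * (yi - mu) ** 2).sum()
        )

    hi = 10 * np.var(yi, ddof=1)
    ts = np.linspace(0, hi, 20_001)
    vals = np.array([rll(t) for t in ts])
    i = int(vals.argmax())
    lo, up = ts[max(i - 1, 0)], ts[min(i + 1, len(ts) - 1)]
    res = minimize_scalar(
        lambda t: -rll(t), bounds=(lo, up), method="bounded",
        options={"xatol": 1e-12},
    )
    best = float(res.x)
    return best if rll(best) > rll(0.0) else 0.0


class TestRemlTau2:
    def test_zero_heterogeneity_for_identical_effects(self):
        assert reml_tau2([0.7] * 5, [0.1, 0.2, 0.3, 0.4, 0.5]) == 0.0

    def test_three_point_instance_matches_brute_force(self):
        yi, vi = [-1.0, 0.0, 1.0], [0.01, 0.01, 0.01]
        assert reml_tau2(yi, vi) == pytest.approx(brute_force_tau2(yi, vi), abs=1e-6)

    def test_matches_brute_force_on_random_small_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            k = int(rng.integers(3, 11))
            yi = rng.normal(0, 1, k)
            vi = rng.uniform(0.01, 0.5, k)
            assert reml_tau2(yi, vi) == pytest.approx(
                brute_force_tau2(yi, vi), abs=1e-5
            )

    def test_parameter_recovery(self):
        # true tau2 = 0.1, k = 100: the mean estimate over 200 replicates
        # must sit within 3 Monte-Carlo SEs of the truth
        rng = np.random.default_rng(11)
        ests = []
        for _ in range(200):
            vi = rng.uniform(0.01, 0.05, 100)
            yi = rng.normal(0.3, np.sqrt(vi + 0.1))
            ests.append(reml_tau2(yi, vi))
        ests = np.asarray(ests)
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - 0.1) < 3 * se

    def test_input_validation(self):
        with pytest.raises(ValueError):
            reml_tau2([1.0], [0.1])
        with pytest.raises(ValueError):
            reml_tau2([1.0, 2.0], [0.1, -0.1])
        with pytest.raises(ValueError):
            reml_tau2([1.0, np.inf], [0.1, 0.1])

    def test_agrees_with_metafor_rma(self):
        # independent cross-check against the R reference implementation
        rng = np.random.default_rng(11)
        yi = rng.normal(0.5, 0.4, 20)
        vi = rng.uniform(0.01, 0.2, 20)
        code = (
            "suppressMessages(library(metafor));"
            f"yi <- c({','.join(map(str, yi))});"
            f"vi <- c({','.join(map(str, vi))});"
            'f <- rma(yi, vi, method="REML");'
            "cat(jsonlite::toJSON(list(mu=as.numeric(f$beta), se=f$se,"
            " tau2=f$tau2), digits=12))"
        )
        out = subprocess.run(
            ["Rscript", "-e", code], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        ref = json.loads(out.stdout)
        fit = random_effects_fit(yi, vi)
        assert fit.mu == pytest.approx(ref["mu"][0], abs=1e-5)
        assert fit.se == pytest.approx(ref["se"][0], abs=1e-5)
        assert fit.tau2 == pytest.approx(ref["tau2"][0], abs=1e-5)


class TestRandomEffectsFit:
    def test_identical_effects_recover_common_value(self):
        fit = random_effects_fit([0.7] * 4, [0.1, 0.2, 0.1, 0.2])
        assert fit.mu == pytest.approx(0.7)
        assert fit.tau2 == 0.0

    def test_two_point_symmetry_forces_midpoint(self):
        fit = random_effects_fit([0.5, 1.5], [0.1, 0.1])
        assert fit.mu == pytest.approx(1.0)
        assert fit.ci_low < fit.mu < fit.ci_high

    def test_ci_uses_normal_quantile(self):
        fit = random_effects_fit([0.2, 0.5, 0.9], [0.05, 0.04, 0.06])
        assert fit.ci_high - fit.mu == pytest.approx(Z_95 * fit.se)

    def test_mu_invariant_to_vi_rescaling_when_tau2_zero(self):
        yi = [0.7] * 5
        vi = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        a = random_effects_fit(yi, vi)
        b = random_effects_fit(yi, vi * 37.0)
        assert a.tau2 == b.tau2 == 0.0
        assert a.mu == pytest.approx(b.mu)

    def test_unweighted_variant_is_mean_with_sd_over_sqrt_k(self):
        yi = np.array([0.1, 0.4, 0.3, 0.9, 0.6])
        fit = random_effects_fit(yi, None)
        assert fit.mu == pytest.approx(yi.mean())
        assert fit.se == pytest.approx(yi.std(ddof=1) / np.sqrt(5))

    def test_ci_coverage_near_nominal(self):
        # 1000 replicates simulated under the model: the 95% CI must cover
        # the true grand mean at a rate within 3 binomial SEs of 95%
        rng = np.random.default_rng(0)
        cover = 0
        n = 1000
        for _ in range(n):
            vi = rng.uniform(0.01, 0.05, 50)
            yi = rng.normal(0.3, np.sqrt(vi + 0.1))
            fit = random_effects_fit(yi, vi)
            cover += fit.ci_low <= 0.3 <= fit.ci_high
        band = 3 * np.sqrt(0.95 * 0.05 / n)
        assert abs(cover / n - 0.95) <= band


class TestRubinPool:
    def test_degenerate_pooling_of_identical_estimates(self):
        est = MetaEstimate(1.0, 0.2, 0.6, 1.4, 0.0, 10)
        pooled = rubin_pool([est] * 5)
        assert pooled.mu == pytest.approx(1.0)
        assert pooled.between_var == pytest.approx(0.0)
        assert pooled.se == pytest.approx(0.2)

    def test_hand_computed_identity(self):
        ests = [
            MetaEstimate(mu, 0.2, np.nan, np.nan, 0.0, 10) for mu in (0.9, 1.0, 1.1)
        ]
        pooled = rubin_pool(ests)
        assert pooled.mu == pytest.approx(1.0)
        assert pooled.within_var == pytest.approx(0.04)
        assert pooled.between_var == pytest.approx(0.01)
        assert pooled.se == pytest.approx(np.sqrt(0.04 + (4 / 3) * 0.01))
        assert pooled.se == pytest.approx(0.23094010767585033)

    def test_single_estimate_passes_through(self):
        est = MetaEstimate(0.42, 0.07, 0.28, 0.56, 0.01, 30)
        pooled = rubin_pool([est])
        assert pooled.mu == est.mu
        assert pooled.se == pytest.approx(est.se)
        assert pooled.m_used == 1

    def test_identity_on_random_instances(self):
        # se_total^2 = mean(se^2) + (1 + 1/m) * var(mu) on 100 random cases
        rng = np.random.default_rng(3)
        for _ in range(100):
            m = int(rng.integers(2, 30))
            mus = rng.normal(0, 1, m)
            ses = rng.uniform(0.05, 0.5, m)
            pooled = rubin_pool(
                [MetaEstimate(mu, se, np.nan, np.nan, 0.0, 5) for mu, se in zip(mus, ses)]
            )
            expected = np.sqrt((ses**2).mean() + (1 + 1 / m) * mus.var(ddof=1))
            assert pooled.se == pytest.approx(expected, rel=1e-12)
            assert pooled.se >= np.sqrt(pooled.within_var)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rubin_pool([])
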
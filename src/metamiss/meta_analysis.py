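"""Random-effects meta-analysis and Rubin's-rules pooling.

The model is the intercept-only random-effects model

    yi ~ N(mu, vi + tau2),

with tau2 (between-study variance) estimated by restricted maximum
likelihood and the grand mean by inverse-variance weighting,
wi = 1/(vi + tau2).  Confidence intervals use the normal 1.96 quantile
(no Knapp–Hartung adjustment).

Estimates from multiply imputed data sets are combined by Rubin's rules:
the pooled mean is the average of the per-imputation means, and the total
variance is the mean within-imputation variance plus (1 + 1/m) times the
between-imputation variance of the means.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .datatypes import MetaEstimate, PooledEstimate

Z_95 = 1.959963984540054  # normal 97.5% quantile


def _restricted_loglik(tau2: float, yi: np.ndarray, vi: np.ndarray) -> float:
    w = 1.0 / (vi + tau2)
    sw = w.sum()
    mu = (w * yi).sum() / sw
    return -0.5 * (np.log(vi + tau2).sum() + np.log(sw) + (w * (yi - mu) ** 2).sum())


def reml_tau2(
    yi: Sequence[float], vi: Sequence[float], tol: float = 1e-10
) -> float:
    """REML estimate of the between-study variance tau2 (>= 0).

    The profile restricted log-likelihood is maximized over
    tau2 in [0, 10 * var(yi)] by bounded scalar optimization, with the
    boundary tau2 = 0 checked explicitly.
    """
    yi = np.asarray(yi, dtype=float)
    vi = np.asarray(vi, dtype=float)
    if yi.shape != vi.shape:
        raise ValueError("yi and vi must have the same length")
    if len(yi) < 2:
        raise ValueError(f"need at least 2 studies, got {len(yi)}")
    if not (np.isfinite(yi).all() and np.isfinite(vi).all()):
        raise ValueError("yi and vi must be finite")
    if (vi <= 0).any():
        raise ValueError("all sampling variances must be > 0")
    spread = float(np.var(yi, ddof=1))
    if spread == 0.0:
        return 0.0
    upper = 10.0 * spread
    res = optimize.minimize_scalar(
        lambda t: -_restricted_loglik(t, yi, vi),
        bounds=(0.0, upper),
        method="bounded",
        options={"xatol": tol},
    )
    best = float(res.x)
    if _restricted_loglik(0.0, yi, vi) >= _restricted_loglik(best, yi, vi):
        return 0.0
    return max(best, 0.0)


def random_effects_fit(
    yi: Sequence[float], vi: Optional[Sequence[float]] = None
) -> MetaEstimate:
    """Fit the random-effects model; ``vi=None`` runs the unweighted variant.

    The unweighted variant is the intercept-only mixed model with equal
    weights and no known sampling variances: the total per-study variance is
    estimated from the data, so mu is the arithmetic mean of the yi and
    se = sd(yi) / sqrt(k) (the REML solution of that model).  Fixing vi = 1
    instead would put the confidence interval on an arbitrary scale.
    """
    yi = np.asarray(yi, dtype=float)
    if vi is None:
        yi = yi[np.isfinite(yi)]
        k = len(yi)
        if k < 2:
            raise ValueError(f"need at least 2 studies, got {k}")
        tau2 = float(np.var(yi, ddof=1))
        mu = float(yi.mean())
        se = float(np.sqrt(tau2 / k))
        return MetaEstimate(
            mu=mu, se=se, ci_low=mu - Z_95 * se, ci_high=mu + Z_95 * se,
            tau2=tau2, k=k,
        )
    vi = np.asarray(vi, dtype=float)
    tau2 = reml_tau2(yi, vi)
    w = 1.0 / (vi + tau2)
    sw = w.sum()
    mu = float((w * yi).sum() / sw)
    se = float(np.sqrt(1.0 / sw))
    return MetaEstimate(
        mu=mu,
        se=se,
        ci_low=mu - Z_95 * se,
        ci_high=mu + Z_95 * se,
        tau2=float(tau2),
        k=len(yi),
    )


def rubin_pool(estimates: Sequence[MetaEstimate]) -> PooledEstimate:
    """Combine per-imputation estimates by Rubin's rules.

    se_total^2 = mean(se_j^2) + (1 + 1/m) * Var(mu_j); with m = 1 the pooled
    estimate equals the single input.
    """
    m = len(estimates)
    if m == 0:
        raise ValueError("no estimates to pool")
    mus = np.array([e.mu for e in estimates], dtype=float)
    ses = np.array([e.se for e in estimates], dtype=float)
    mu_bar = float(mus.mean())
    within = float((ses**2).mean())
    between = float(mus.var(ddof=1)) if m > 1 else 0.0
    se_total = float(np.sqrt(within + (1.0 + 1.0 / m) * between))
    return PooledEstimate(
        mu=mu_bar,
        se=se_total,
        ci_low=mu_bar - Z_95 * se_total,
        ci_high=mu_bar + Z_95 * se_total,
        m_used=m,
        within_var=within,
        between_var=between,
    )
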
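"""Single and multiple imputation of missing SDs and sample sizes.

Eleven imputers are exposed behind one entry point, :func:`impute`:

* single imputation — ``mean``, ``median`` (deterministic, m = 1);
* chained-equations plug-ins — ``random_sample``, ``linear_regression``,
  ``pmm`` (predictive mean matching), ``cart``, ``random_forest``,
  ``bayes_pmm``;
* whole-table algorithms — ``bootstrap_em`` (bootstrap + EM for the
  multivariate normal, with conditional-normal draws), ``missforest``
  (iterated random-forest regression with the increase-in-change stopping
  rule), ``addreg_boot_pmm`` (bootstrapped additive spline regression with
  donor matching).

Chained-equations imputation initializes missing cells with random draws
from the observed values, then cycles through the columns in the order
sd_t, sd_c, n_t, n_c, refitting the per-column model and redrawing the
missing cells each cycle.  Predictors are the group means (or r) plus any
SD/SS columns without missing values.

All imputed SDs are restricted to [0.01, 1] and imputed sample sizes are
rounded to integers and restricted to >= 5.  Donor-based methods satisfy the
restrictions automatically because donors are observed values; model-based
methods redraw out-of-bounds values up to 10 times, then clamp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import SplineTransformer
from sklearn.tree import DecisionTreeRegressor

from .datatypes import CORRELATION, IncompleteDataset, MEAN_DIFFERENCE

SINGLE_METHODS = ("mean", "median")
CHAINED_METHODS = (
    "random_sample",
    "linear_regression",
    "pmm",
    "cart",
    "random_forest",
    "bayes_pmm",
)
TABLE_METHODS = ("bootstrap_em", "missforest", "addreg_boot_pmm")
ALL_METHODS = SINGLE_METHODS + CHAINED_METHODS + TABLE_METHODS

DEFAULT_ORDER_MD = ("sd_t", "sd_c", "n_t", "n_c")


class ImputationError(RuntimeError):
    """Unrecoverable imputation failure (e.g., too few complete rows)."""


@dataclass
class ImputationConfig:
    method: str
    m: int = 100
    n_chain_iters: int = 5
    sd_bounds: Tuple[float, float] = (0.01, 1.0)
    ss_lower: int = 5
    order: Optional[Sequence[str]] = None
    pmm_donors: int = 5
    max_bound_redraws: int = 10
    em_missing_cutoff: float = 0.6
    em_max_iters: int = 1000
    em_tol: float = 1e-6
    rf_trees: int = 10
    missforest_trees: int = 100
    missforest_max_iters: int = 10

    def __post_init__(self) -> None:
        if self.method not in ALL_METHODS:
            raise ValueError(f"unknown imputation method {self.method!r}")
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")


@dataclass
class ImputationOutcome:
    """Result of an imputation run: completed tables plus failure bookkeeping."""

    status: str  # "ok", "skipped" or "failed"
    datasets: List[pd.DataFrame] = field(default_factory=list)
    failures: List[str] = field(default_factory=list)
    reason: str = ""
    method: str = ""


def _column_kind(col: str) -> str:
    return "sd" if col.startswith("sd") else "ss"


def _target_columns(inc: IncompleteDataset, cfg: ImputationConfig) -> List[str]:
    order = cfg.order
    if order is None:
        order = DEFAULT_ORDER_MD if inc.kind == MEAN_DIFFERENCE else ("n",)
    return [c for c in order if inc.data[c].isna().any()]


def _predictor_columns(inc: IncompleteDataset, target: str) -> List[str]:
    """Group means / r plus fully observed SD/SS columns, excluding the target."""
    if inc.kind == MEAN_DIFFERENCE:
        preds = ["mean_c", "mean_t"]
        for c in ("sd_c", "sd_t", "n_c", "n_t"):
            if c != target and not inc.data[c].isna().any():
                preds.append(c)
    else:
        preds = ["r"]
    return [c for c in preds if c != target]


def _finish_values(vals: np.ndarray, kind: str, cfg: ImputationConfig) -> np.ndarray:
    """Apply the plausibility restrictions to imputed values."""
    vals = np.asarray(vals, dtype=float)
    if kind == "sd":
        return np.clip(vals, cfg.sd_bounds[0], cfg.sd_bounds[1])
    return np.maximum(np.rint(vals), cfg.ss_lower)


def _in_bounds(vals: np.ndarray, kind: str, cfg: ImputationConfig) -> np.ndarray:
    if kind == "sd":
        return (vals >= cfg.sd_bounds[0]) & (vals <= cfg.sd_bounds[1])
    return vals >= cfg.ss_lower


def _draw_with_redraws(
    draw_full: Callable[[], np.ndarray], kind: str, cfg: ImputationConfig
) -> np.ndarray:
    """Redraw out-of-bounds cells a bounded number of times, then clamp."""
    vals = np.asarray(draw_full(), dtype=float)
    for _ in range(cfg.max_bound_redraws):
        bad = ~_in_bounds(vals, kind, cfg)
        if not bad.any():
            break
        vals[bad] = np.asarray(draw_full(), dtype=float)[bad]
    return _finish_values(vals, kind, cfg)


# ---------------------------------------------------------------------------
# Single imputation


def impute_single(
    inc: IncompleteDataset, stat: str, cfg: Optional[ImputationConfig] = None
) -> ImputationOutcome:
    """Fill every missing cell with the column's observed mean or median."""
    if stat not in SINGLE_METHODS:
        raise ValueError(f"stat must be 'mean' or 'median', got {stat!r}")
    cfg = cfg or ImputationConfig(method=stat, m=1)
    work = inc.data.copy()
    for col in work.columns:
        mis = work[col].isna()
        if not mis.any():
            continue
        obs = work.loc[~mis, col]
        if obs.empty:
            raise ImputationError(f"{stat} imputation: column {col!r} has no observed values")
        value = float(obs.mean() if stat == "mean" else obs.median())
        work.loc[mis, col] = _finish_values(np.array([value]), _column_kind(col), cfg)[0]
    return ImputationOutcome(status="ok", datasets=[work], method=stat)


# ---------------------------------------------------------------------------
# Chained-equations plug-ins.  Each maps
# (X_obs, y_obs, X_mis, rng, cfg) -> imputed values for the missing rows.


def _add_intercept(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def _bayes_lm(
    X_obs: np.ndarray,
    y_obs: np.ndarray,
    rng: np.random.Generator,
    ridge: float = 0.0,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Posterior draw (beta*, sigma2*) plus the point estimate beta_hat.

    Normal-inverse-gamma reference prior (optionally ridge-regularized):
    sigma2* ~ RSS / chi2(n - p), beta* ~ N(beta_hat, sigma2* (X'X)^-1).
    """
    X = _add_intercept(X_obs)
    n, p = X.shape
    XtX = X.T @ X + ridge * np.eye(p)
    XtX_inv = np.linalg.pinv(XtX)
    beta_hat = XtX_inv @ (X.T @ y_obs)
    resid = y_obs - X @ beta_hat
    dof = max(n - p, 1)
    rss = float(resid @ resid)
    sigma2 = (rss + 1e-12) / rng.chisquare(dof)
    cov = sigma2 * XtX_inv
    beta_star = rng.multivariate_normal(beta_hat, cov, method="svd")
    return beta_hat, beta_star, sigma2


def _plugin_random_sample(X_obs, y_obs, X_mis, rng, cfg):
    return rng.choice(y_obs, size=len(X_mis), replace=True)


def _plugin_linear_regression(X_obs, y_obs, X_mis, rng, cfg):
    _, beta_star, sigma2 = _bayes_lm(X_obs, y_obs, rng)
    mean_mis = _add_intercept(X_mis) @ beta_star
    return mean_mis + rng.normal(0.0, np.sqrt(sigma2), size=len(X_mis))


def _pmm_match(pred_obs, y_obs, pred_mis, rng, donors):
    k = min(donors, len(y_obs))
    out = np.empty(len(pred_mis))
    for i, pm in enumerate(pred_mis):
        idx = np.argsort(np.abs(pred_obs - pm), kind="stable")[:k]
        out[i] = y_obs[idx[rng.integers(k)]]
    return out


def _plugin_pmm(X_obs, y_obs, X_mis, rng, cfg):
    beta_hat, beta_star, _ = _bayes_lm(X_obs, y_obs, rng)
    pred_obs = _add_intercept(X_obs) @ beta_hat
    pred_mis = _add_intercept(X_mis) @ beta_star
    return _pmm_match(pred_obs, y_obs, pred_mis, rng, cfg.pmm_donors)


def _plugin_bayes_pmm(X_obs, y_obs, X_mis, rng, cfg):
    # Bayesian GLM with a weakly informative (ridge) prior, then donor matching.
    beta_hat, beta_star, _ = _bayes_lm(X_obs, y_obs, rng, ridge=1e-3)
    pred_obs = _add_intercept(X_obs) @ beta_hat
    pred_mis = _add_intercept(X_mis) @ beta_star
    return _pmm_match(pred_obs, y_obs, pred_mis, rng, cfg.pmm_donors)


def _plugin_cart(X_obs, y_obs, X_mis, rng, cfg):
    tree = DecisionTreeRegressor(
        min_samples_leaf=5, random_state=int(rng.integers(2**31))
    )
    tree.fit(X_obs, y_obs)
    leaf_obs = tree.apply(X_obs)
    leaf_mis = tree.apply(X_mis)
    out = np.empty(len(X_mis))
    for i, leaf in enumerate(leaf_mis):
        donors = y_obs[leaf_obs == leaf]
        out[i] = donors[rng.integers(len(donors))]
    return out


def _plugin_random_forest(X_obs, y_obs, X_mis, rng, cfg):
    """Forest of bootstrap trees; each cell drawn from a random tree's leaf."""
    trees = []
    for _ in range(cfg.rf_trees):
        idx = rng.integers(0, len(y_obs), size=len(y_obs))
        t = DecisionTreeRegressor(
            min_samples_leaf=5,
            max_features=None,
            random_state=int(rng.integers(2**31)),
        )
        t.fit(X_obs[idx], y_obs[idx])
        trees.append((t, idx))
    out = np.empty(len(X_mis))
    for i in range(len(X_mis)):
        t, idx = trees[rng.integers(len(trees))]
        leaf = t.apply(X_mis[i : i + 1])[0]
        leaves_boot = t.apply(X_obs[idx])
        donors = y_obs[idx][leaves_boot == leaf]
        out[i] = donors[rng.integers(len(donors))]
    return out


_CHAINED_PLUGINS: Dict[str, Callable] = {
    "random_sample": _plugin_random_sample,
    "linear_regression": _plugin_linear_regression,
    "pmm": _plugin_pmm,
    "cart": _plugin_cart,
    "random_forest": _plugin_random_forest,
    "bayes_pmm": _plugin_bayes_pmm,
}

DONOR_METHODS = ("random_sample", "pmm", "cart", "random_forest", "bayes_pmm",
                 "addreg_boot_pmm")


def mice_impute(
    inc: IncompleteDataset, cfg: ImputationConfig, rng: np.random.Generator
) -> ImputationOutcome:
    """m rounds of chained-equations imputation with one of the six plug-ins."""
    if cfg.method not in _CHAINED_PLUGINS:
        raise ValueError(f"{cfg.method!r} is not a chained-equations plug-in")
    plugin = _CHAINED_PLUGINS[cfg.method]
    targets = _target_columns(inc, cfg)
    if not targets:
        return ImputationOutcome(
            status="ok", datasets=[inc.data.copy() for _ in range(cfg.m)], method=cfg.method
        )
    for col in targets:
        if (~inc.data[col].isna()).sum() < 5:
            raise ImputationError(
                f"{cfg.method}: fewer than 5 observed values in column {col!r}"
            )
    datasets: List[pd.DataFrame] = []
    for _ in range(cfg.m):
        work = inc.data.copy()
        # initialize missing cells by random draws from the observed values
        for col in targets:
            mis = work[col].isna().to_numpy()
            obs_vals = inc.data.loc[~mis, col].to_numpy(float)
            work.loc[mis, col] = rng.choice(obs_vals, size=int(mis.sum()), replace=True)
        for _cycle in range(cfg.n_chain_iters):
            for col in targets:
                mis = inc.data[col].isna().to_numpy()
                preds = _predictor_columns(inc, col)
                X = work[preds].to_numpy(float) if preds else np.zeros((len(work), 0))
                y_obs = inc.data.loc[~mis, col].to_numpy(float)
                X_obs, X_mis = X[~mis], X[mis]
                kind = _column_kind(col)
                if cfg.method in DONOR_METHODS:
                    vals = plugin(X_obs, y_obs, X_mis, rng, cfg)
                    vals = _finish_values(vals, kind, cfg)
                else:
                    vals = _draw_with_redraws(
                        lambda Xo=X_obs, yo=y_obs, Xm=X_mis: plugin(Xo, yo, Xm, rng, cfg),
                        kind,
                        cfg,
                    )
                work.loc[mis, col] = vals
        datasets.append(work)
    return ImputationOutcome(status="ok", datasets=datasets, method=cfg.method)


# ---------------------------------------------------------------------------
# Bootstrap EM (multivariate-normal model)


class _EMNonConvergence(RuntimeError):
    pass


def em_mvnorm(
    Y: np.ndarray, max_iters: int = 1000, tol: float = 1e-6
) -> Tuple[np.ndarray, np.ndarray]:
    """EM estimate of the mean vector and covariance of a MVN with missing data."""
    Y = np.asarray(Y, dtype=float)
    n, p = Y.shape
    miss = np.isnan(Y)
    if miss.all(axis=0).any():
        raise _EMNonConvergence("a column is entirely missing")
    mu = np.nanmean(Y, axis=0)
    var = np.nanvar(Y, axis=0)
    var[~np.isfinite(var) | (var <= 0)] = 1.0
    Sigma = np.diag(var)
    for _ in range(max_iters):
        Ey = np.where(miss, 0.0, Y)
        C = np.zeros((p, p))
        for i in range(n):
            ms = miss[i]
            if not ms.any():
                continue
            o = ~ms
            Soo = Sigma[np.ix_(o, o)]
            Smo = Sigma[np.ix_(ms, o)]
            Smm = Sigma[np.ix_(ms, ms)]
            solve = np.linalg.solve(Soo, np.column_stack([(Y[i, o] - mu[o]), Smo.T]))
            Ey[i, ms] = mu[ms] + Smo @ solve[:, 0]
            C[np.ix_(ms, ms)] += Smm - Smo @ solve[:, 1:]
        mu_new = Ey.mean(axis=0)
        centered = Ey - mu_new
        Sigma_new = (centered.T @ centered + C) / n
        Sigma_new += 1e-10 * np.eye(p)
        delta = max(
            np.abs(mu_new - mu).max(), np.abs(Sigma_new - Sigma).max()
        )
        mu, Sigma = mu_new, Sigma_new
        if delta < tol:
            return mu, Sigma
    raise _EMNonConvergence(f"EM did not converge in {max_iters} iterations")


def impute_bootstrap_em(
    inc: IncompleteDataset, cfg: ImputationConfig, rng: np.random.Generator
) -> ImputationOutcome:
    """Bootstrap rows, fit the MVN by EM, draw missing cells conditionally.

    Refuses data sets with more than ``em_missing_cutoff`` (default 60%)
    missing values in any column, emitting a structured "skipped" outcome.
    """
    frac = inc.missing_fraction()
    if frac > cfg.em_missing_cutoff:
        return ImputationOutcome(
            status="skipped",
            reason=(
                f"missing fraction {frac:.0%} exceeds the "
                f"{cfg.em_missing_cutoff:.0%} operational cutoff"
            ),
            method="bootstrap_em",
        )
    if frac == 0.0:
        return ImputationOutcome(
            status="ok", datasets=[inc.data.copy() for _ in range(cfg.m)],
            method="bootstrap_em",
        )
    cols = list(inc.data.columns)
    Y = inc.data.to_numpy(float)
    miss = np.isnan(Y)
    n = len(Y)
    datasets: List[pd.DataFrame] = []
    failures: List[str] = []
    for j in range(cfg.m):
        boot = rng.integers(0, n, size=n)
        try:
            mu, Sigma = em_mvnorm(Y[boot], cfg.em_max_iters, cfg.em_tol)
        except (_EMNonConvergence, np.linalg.LinAlgError) as exc:
            failures.append(f"imputation {j + 1}: {exc}")
            continue
        work = inc.data.copy()
        for i in range(n):
            ms = miss[i]
            if not ms.any():
                continue
            o = ~ms
            Soo = Sigma[np.ix_(o, o)]
            Smo = Sigma[np.ix_(ms, o)]
            Smm = Sigma[np.ix_(ms, ms)]
            sol = np.linalg.solve(Soo, np.column_stack([(Y[i, o] - mu[o]), Smo.T]))
            cmu = mu[ms] + Smo @ sol[:, 0]
            ccov = Smm - Smo @ sol[:, 1:]
            ccov = (ccov + ccov.T) / 2 + 1e-10 * np.eye(int(ms.sum()))
            mis_cols = [cols[c] for c in np.where(ms)[0]]
            vals = rng.multivariate_normal(cmu, ccov, method="svd")
            for _ in range(cfg.max_bound_redraws):
                ok = all(
                    _in_bounds(np.array([v]), _column_kind(c), cfg)[0]
                    for v, c in zip(vals, mis_cols)
                )
                if ok:
                    break
                vals = rng.multivariate_normal(cmu, ccov, method="svd")
            for v, c in zip(vals, mis_cols):
                work.loc[i, c] = _finish_values(np.array([v]), _column_kind(c), cfg)[0]
        datasets.append(work)
    if not datasets:
        return ImputationOutcome(
            status="failed", failures=failures,
            reason="all bootstrap-EM imputations failed", method="bootstrap_em",
        )
    return ImputationOutcome(
        status="ok", datasets=datasets, failures=failures, method="bootstrap_em"
    )


# ---------------------------------------------------------------------------
# missForest-style iterative random forest


def impute_missforest(
    inc: IncompleteDataset, cfg: ImputationConfig, rng: np.random.Generator
) -> ImputationOutcome:
    """Iterated random-forest imputation with the increase-in-change stop rule.

    Unlike the chained-equations plug-ins, every other column (including
    currently imputed ones) serves as a predictor — the iteration is the
    point of the algorithm.  Between-imputation variability comes from the
    forests' bootstrap randomness.
    """
    targets = _target_columns(inc, cfg)
    if not targets:
        return ImputationOutcome(
            status="ok", datasets=[inc.data.copy() for _ in range(cfg.m)],
            method="missforest",
        )
    for col in targets:
        if (~inc.data[col].isna()).sum() < 5:
            raise ImputationError(
                f"missforest: fewer than 5 observed values in column {col!r}"
            )
    # impute columns with the least missingness first (missForest ordering)
    targets = sorted(targets, key=lambda c: inc.data[c].isna().sum())
    cols = list(inc.data.columns)
    datasets: List[pd.DataFrame] = []
    for _ in range(cfg.m):
        work = inc.data.copy()
        for col in targets:  # mean initialization
            mis = work[col].isna()
            work.loc[mis, col] = float(inc.data[col].mean())
        prev_diff = np.inf
        snapshot = work.copy()
        for _it in range(cfg.missforest_max_iters):
            snapshot = work.copy()
            for col in targets:
                mis = inc.data[col].isna().to_numpy()
                other = [c for c in cols if c != col]
                X = work[other].to_numpy(float)
                rf = RandomForestRegressor(
                    n_estimators=cfg.missforest_trees,
                    min_samples_leaf=5,
                    random_state=int(rng.integers(2**31)),
                )
                rf.fit(X[~mis], inc.data.loc[~mis, col].to_numpy(float))
                vals = _finish_values(rf.predict(X[mis]), _column_kind(col), cfg)
                work.loc[mis, col] = vals
            num = 0.0
            den = 0.0
            for col in targets:
                mis = inc.data[col].isna().to_numpy()
                new = work.loc[mis, col].to_numpy(float)
                old = snapshot.loc[mis, col].to_numpy(float)
                num += float(((new - old) ** 2).sum())
                den += float((new**2).sum())
            diff = num / den if den > 0 else 0.0
            if diff >= prev_diff:
                work = snapshot  # change increased: keep the previous iterate
                break
            prev_diff = diff
            if diff == 0.0:
                break
        datasets.append(work)
    return ImputationOutcome(status="ok", datasets=datasets, method="missforest")


# ---------------------------------------------------------------------------
# Additive regression + bootstrap + predictive mean matching


def impute_addreg_boot_pmm(
    inc: IncompleteDataset, cfg: ImputationConfig, rng: np.random.Generator
) -> ImputationOutcome:
    """Bootstrap rows, fit spline regressions, donor-match the predictions.

    Imputed values are always members of the observed set, so the
    plausibility restrictions hold automatically.
    """
    targets = _target_columns(inc, cfg)
    if not targets:
        return ImputationOutcome(
            status="ok", datasets=[inc.data.copy() for _ in range(cfg.m)],
            method="addreg_boot_pmm",
        )
    for col in targets:
        if (~inc.data[col].isna()).sum() < 5:
            raise ImputationError(
                f"addreg_boot_pmm: fewer than 5 observed values in column {col!r}"
            )
    n = len(inc.data)
    datasets: List[pd.DataFrame] = []
    for _ in range(cfg.m):
        work = inc.data.copy()
        boot = rng.integers(0, n, size=n)
        for col in targets:
            mis = inc.data[col].isna().to_numpy()
            preds = _predictor_columns(inc, col)
            X = inc.data[preds].to_numpy(float)
            y = inc.data[col].to_numpy(float)
            boot_obs = boot[~np.isnan(y[boot])]
            if len(boot_obs) < 5 or len(np.unique(boot_obs)) < 3:
                boot_obs = np.where(~mis)[0]  # degenerate resample: fall back
            model = make_pipeline(
                SplineTransformer(n_knots=4, degree=3), LinearRegression()
            )
            model.fit(X[boot_obs], y[boot_obs])
            pred_mis = model.predict(X[mis])
            pred_obs = model.predict(X[~mis])
            y_obs = y[~mis]
            vals = np.empty(len(pred_mis))
            for i, pm in enumerate(pred_mis):
                vals[i] = y_obs[np.argmin(np.abs(pred_obs - pm))]
            work.loc[mis, col] = vals
        datasets.append(work)
    return ImputationOutcome(status="ok", datasets=datasets, method="addreg_boot_pmm")


# ---------------------------------------------------------------------------


def impute(
    inc: IncompleteDataset, cfg: ImputationConfig, rng: np.random.Generator
) -> ImputationOutcome:
    """Dispatch to the configured imputation method."""
    if cfg.method in SINGLE_METHODS:
        return impute_single(inc, cfg.method, cfg)
    if cfg.method in CHAINED_METHODS:
        return mice_impute(inc, cfg, rng)
    if cfg.method == "bootstrap_em":
        return impute_bootstrap_em(inc, cfg, rng)
    if cfg.method == "missforest":
        return impute_missforest(inc, cfg, rng)
    return impute_addreg_boot_pmm(inc, cfg, rng)
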
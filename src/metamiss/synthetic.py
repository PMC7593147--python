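"""Synthetic meta-analysis data sets.

Generates the two study types used throughout the package:

* mean-difference data — per-study control/treatment means (truncated normal,
  strictly positive), standard deviations (truncated normal on [0.01, 1]) and
  group sample sizes (truncated Poisson, at least 5);
* correlation data — per-study correlation coefficient (truncated normal on
  [-1, 1]) and a single sample size (truncated Poisson, at least 5).

Also provides the "effect sizes paired with precision" rearrangement used for
the corMCAR scenario, where large effects are matched with small SDs and
large sample sizes.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    CORRELATION,
    MEAN_DIFFERENCE,
    MetaDataset,
    TruncNormalSpec,
    TruncPoissonSpec,
    ValidationError,
)

# Default generating distributions for the simulation study.
MD_DEFAULTS = {
    "mean_c": TruncNormalSpec(1.0, 0.25, lower=0.001),
    "mean_t": TruncNormalSpec(2.0, 0.5, lower=0.001),
    "sd_c": TruncNormalSpec(0.25, 0.125, lower=0.01, upper=1.0),
    "sd_t": TruncNormalSpec(0.5, 0.25, lower=0.01, upper=1.0),
    "n_c": TruncPoissonSpec(10.0, lower=5),
    "n_t": TruncPoissonSpec(10.0, lower=5),
}
CORR_DEFAULTS = {
    "r": TruncNormalSpec(0.5, 0.125, lower=-1.0, upper=1.0),
    "n": TruncPoissonSpec(10.0, lower=5),
}


def sample_trunc_normal(
    spec: TruncNormalSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` values from the truncated normal by inverse-CDF transform.

    Inverse-CDF sampling is exact and has deterministic cost, unlike
    rejection, which can stall under extreme truncation.
    """
    if n < 0:
        raise ValidationError(f"n must be >= 0, got {n}")
    if spec.sd == 0:
        if not (spec.lower <= spec.mean <= spec.upper):
            raise ValidationError("degenerate spec: mean outside truncation bounds")
        return np.full(n, float(spec.mean))
    a = (spec.lower - spec.mean) / spec.sd
    b = (spec.upper - spec.mean) / spec.sd
    u = rng.uniform(size=n)
    x = stats.truncnorm.ppf(u, a, b, loc=spec.mean, scale=spec.sd)
    # ppf can land exactly on a bound at u ~ 0 or 1; clip guards float fuzz.
    return np.clip(x, spec.lower, spec.upper)


def trunc_normal_mean(spec: TruncNormalSpec) -> float:
    """Analytic mean of the truncated normal (moment oracle for tests)."""
    if spec.sd == 0:
        return float(spec.mean)
    a = (spec.lower - spec.mean) / spec.sd
    b = (spec.upper - spec.mean) / spec.sd
    return float(stats.truncnorm.mean(a, b, loc=spec.mean, scale=spec.sd))


def trunc_poisson_mean(spec: TruncPoissonSpec) -> float:
    """Analytic mean of Poisson(lam) conditioned on X >= lower."""
    lam, lo = spec.lam, spec.lower
    if lo == 0:
        return float(lam)
    # E[X | X >= lo] = lam * P(X >= lo - 1) / P(X >= lo)
    tail_lo = stats.poisson.sf(lo - 1, lam)
    tail_lo_m1 = stats.poisson.sf(lo - 2, lam)
    return float(lam * tail_lo_m1 / tail_lo)


def sample_trunc_poisson(
    spec: TruncPoissonSpec, n: int, rng: np.random.Generator, max_rounds: int = 1000
) -> np.ndarray:
    """Draw ``n`` integers from Poisson(lam) conditioned on X >= lower.

    Rejection sampling with a bounded number of rounds; any draws still
    unresolved fall back to inverse-CDF over a tabulated pmf.  For the
    simulation defaults (lam=10, lower=5) acceptance is ~0.97 so the
    fallback is essentially never reached.
    """
    if n < 0:
        raise ValidationError(f"n must be >= 0, got {n}")
    out = np.empty(n, dtype=np.int64)
    pending = np.arange(n)
    for _ in range(max_rounds):
        if pending.size == 0:
            break
        draws = rng.poisson(spec.lam, size=pending.size)
        ok = draws >= spec.lower
        out[pending[ok]] = draws[ok]
        pending = pending[~ok]
    if pending.size:
        out[pending] = _trunc_poisson_inverse_cdf(spec, pending.size, rng)
    return out


def _trunc_poisson_inverse_cdf(
    spec: TruncPoissonSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    hi = int(spec.lam + 20 * np.sqrt(spec.lam) + 20)
    ks = np.arange(spec.lower, hi + 1)
    pmf = stats.poisson.pmf(ks, spec.lam)
    pmf = pmf / pmf.sum()
    return rng.choice(ks, size=n, p=pmf)


def generate_mean_difference_dataset(
    n_studies: int,
    rng: np.random.Generator,
    params: Optional[dict] = None,
    replicate_id: int = 0,
) -> MetaDataset:
    """Simulate a complete mean-difference data set (no missing cells)."""
    if n_studies < 0:
        raise ValidationError(f"n_studies must be >= 0, got {n_studies}")
    p = dict(MD_DEFAULTS)
    if params:
        p.update(params)
    data = pd.DataFrame(
        {
            "mean_c": sample_trunc_normal(p["mean_c"], n_studies, rng),
            "mean_t": sample_trunc_normal(p["mean_t"], n_studies, rng),
            "sd_c": sample_trunc_normal(p["sd_c"], n_studies, rng),
            "sd_t": sample_trunc_normal(p["sd_t"], n_studies, rng),
            "n_c": sample_trunc_poisson(p["n_c"], n_studies, rng).astype(float),
            "n_t": sample_trunc_poisson(p["n_t"], n_studies, rng).astype(float),
        }
    )
    return MetaDataset(MEAN_DIFFERENCE, data, replicate_id=replicate_id)


def generate_correlation_dataset(
    n_studies: int,
    rng: np.random.Generator,
    params: Optional[dict] = None,
    replicate_id: int = 0,
) -> MetaDataset:
    """Simulate a complete correlation-coefficient data set."""
    if n_studies < 0:
        raise ValidationError(f"n_studies must be >= 0, got {n_studies}")
    p = dict(CORR_DEFAULTS)
    if params:
        p.update(params)
    data = pd.DataFrame(
        {
            "r": sample_trunc_normal(p["r"], n_studies, rng),
            "n": sample_trunc_poisson(p["n"], n_studies, rng).astype(float),
        }
    )
    return MetaDataset(CORRELATION, data, replicate_id=replicate_id)


def raw_effect_size(ds: MetaDataset) -> np.ndarray:
    """Per-row effect size used for ranking: simple ln(mean_t/mean_c), or r.

    Deliberately uncorrected so that ordering studies never depends on the
    SD/SS columns being rearranged or deleted.
    """
    if ds.kind == MEAN_DIFFERENCE:
        return np.log(ds.data["mean_t"].to_numpy() / ds.data["mean_c"].to_numpy())
    return ds.data["r"].to_numpy()


def sort_for_cormcar(ds: MetaDataset) -> MetaDataset:
    """Re-pair rows so effect size and precision are perfectly correlated.

    Column families are sorted independently and zipped: the (mean_c, mean_t)
    pairs ordered by effect size descending, the (sd_c, sd_t) pairs by summed
    SD ascending, and the (n_c, n_t) pairs by summed SS descending — larger
    effects end up with smaller SDs and larger sample sizes.  Each column's
    multiset of values is preserved (the operation is a within-family
    permutation).  For correlation data, r descending is zipped with n
    descending.
    """
    if not ds.is_complete():
        raise ValidationError("corMCAR sorting requires a complete dataset")
    df = ds.data
    if ds.kind == MEAN_DIFFERENCE:
        es = np.log(df["mean_t"].to_numpy() / df["mean_c"].to_numpy())
        mean_order = np.argsort(-es, kind="stable")
        sd_order = np.argsort(
            (df["sd_c"] + df["sd_t"]).to_numpy(), kind="stable"
        )
        n_order = np.argsort(-(df["n_c"] + df["n_t"]).to_numpy(), kind="stable")
        out = pd.DataFrame(
            {
                "mean_c": df["mean_c"].to_numpy()[mean_order],
                "mean_t": df["mean_t"].to_numpy()[mean_order],
                "sd_c": df["sd_c"].to_numpy()[sd_order],
                "sd_t": df["sd_t"].to_numpy()[sd_order],
                "n_c": df["n_c"].to_numpy()[n_order],
                "n_t": df["n_t"].to_numpy()[n_order],
            }
        )
    else:
        r_sorted = np.sort(df["r"].to_numpy())[::-1]
        n_sorted = np.sort(df["n"].to_numpy())[::-1]
        out = pd.DataFrame({"r": r_sorted, "n": n_sorted})
    return MetaDataset(ds.kind, out, replicate_id=ds.replicate_id, rng_seed=ds.rng_seed)


def dataset_to_csv(ds, path) -> None:
    """Write a (possibly incomplete) dataset; missing values as empty cells."""
    df = ds.data if hasattr(ds, "data") else ds
    df.to_csv(path, index=False, na_rep="")


def dataset_from_csv(path, kind: Optional[str] = None) -> MetaDataset:
    """Read a dataset CSV, inferring the kind from its header when not given."""
    df = pd.read_csv(path)
    if kind is None:
        kind = CORRELATION if "r" in df.columns else MEAN_DIFFERENCE
    return MetaDataset(kind, df)
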
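"""Effect sizes and sampling variances.

Three metrics:

* small-sample bias-corrected log response ratio (lnRR) for two-group means,
* Hedges' d (standardized mean difference with the J correction),
* Fisher's z for correlation coefficients, vi = 1/(n-3).

Plus the sample-size variance approximation var = (n_t + n_c) / (n_t * n_c)
used by the SS-weighted analysis, and the simple (uncorrected) log response
ratio used by the unweighted and SS-weighted treatments, which is computable
without SDs.

Scalar functions return an :class:`EffectSize` or raise; functions raising
:class:`EffectSizeUnavailable` signal a study that a complete-case analysis
must drop.  Vectorized helpers operate on whole data frames and mark
unavailable studies with NaN.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .datatypes import CORRELATION, EffectSize, MEAN_DIFFERENCE

METRICS = ("lnrr", "hedges_d", "fishers_z")


class EffectSizeUnavailable(Exception):
    """The study lacks the fields needed for this effect size."""


def _require(*values) -> None:
    for v in values:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise EffectSizeUnavailable("missing field")


def lnrr_simple(mean_c: float, mean_t: float) -> EffectSize:
    """Uncorrected log response ratio ln(mean_t / mean_c); no variance."""
    _require(mean_c, mean_t)
    if mean_c <= 0 or mean_t <= 0:
        raise ValueError("log response ratio requires strictly positive means")
    return EffectSize(yi=math.log(mean_t / mean_c), vi=None, weight_kind="unavailable")


def lnrr_corrected(
    mean_c: float, mean_t: float, sd_c: float, sd_t: float, n_c: float, n_t: float
) -> EffectSize:
    """Small-sample bias-corrected log response ratio with its variance.

    yi = ln(mt/mc) + [sd_t^2/(n_t mt^2) - sd_c^2/(n_c mc^2)] / 2
    vi = sd_t^2/(n_t mt^2) + sd_c^2/(n_c mc^2)
         + [sd_t^4/(n_t^2 mt^4) + sd_c^4/(n_c^2 mc^4)] / 2
    """
    _require(mean_c, mean_t, sd_c, sd_t, n_c, n_t)
    if mean_c <= 0 or mean_t <= 0:
        raise ValueError("log response ratio requires strictly positive means")
    ct = sd_t**2 / (n_t * mean_t**2)
    cc = sd_c**2 / (n_c * mean_c**2)
    yi = math.log(mean_t / mean_c) + 0.5 * (ct - cc)
    vi = ct + cc + 0.5 * (ct**2 + cc**2)
    return EffectSize(yi=yi, vi=vi)


def hedges_d(
    mean_c: float, mean_t: float, sd_c: float, sd_t: float, n_c: float, n_t: float
) -> EffectSize:
    """Hedges' d: J-corrected standardized mean difference."""
    _require(mean_c, mean_t, sd_c, sd_t, n_c, n_t)
    df = n_c + n_t - 2
    sp2 = ((n_c - 1) * sd_c**2 + (n_t - 1) * sd_t**2) / df
    if sp2 <= 0:
        raise ValueError("pooled SD is zero; Hedges' d undefined")
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    d = j * (mean_t - mean_c) / math.sqrt(sp2)
    vi = (n_c + n_t) / (n_c * n_t) + d**2 / (2.0 * (n_c + n_t))
    return EffectSize(yi=d, vi=vi)


def fishers_z(r: float, n: float) -> EffectSize:
    """Fisher's variance-stabilizing transform artanh(r), vi = 1/(n-3)."""
    _require(n)
    if not abs(r) < 1:
        raise ValueError(f"|r| must be < 1 for Fisher's z, got {r}")
    if n <= 3:
        raise ValueError(f"Fisher's z variance needs n > 3, got {n}")
    return EffectSize(yi=math.atanh(r), vi=1.0 / (n - 3.0))


def ss_approx_variance(n_c: float, n_t: float) -> float:
    """Sample-size variance approximation (n_t + n_c) / (n_t * n_c)."""
    _require(n_c, n_t)
    if n_c < 1 or n_t < 1:
        raise ValueError("sample sizes must be >= 1")
    return (n_t + n_c) / (n_t * n_c)


# ---------------------------------------------------------------------------
# Vectorized computation on data frames (NaN marks unavailable studies).


def compute_effect_sizes(df: pd.DataFrame, kind: str, metric: str) -> pd.DataFrame:
    """Per-row (yi, vi) for a whole table; NaN where a row's fields are missing."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if kind == MEAN_DIFFERENCE:
        if metric == "fishers_z":
            raise ValueError("Fisher's z applies to correlation data only")
        mc = df["mean_c"].to_numpy(float)
        mt = df["mean_t"].to_numpy(float)
        sc = df["sd_c"].to_numpy(float)
        st = df["sd_t"].to_numpy(float)
        nc = df["n_c"].to_numpy(float)
        nt = df["n_t"].to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            if metric == "lnrr":
                ct = st**2 / (nt * mt**2)
                cc = sc**2 / (nc * mc**2)
                yi = np.log(mt / mc) + 0.5 * (ct - cc)
                vi = ct + cc + 0.5 * (ct**2 + cc**2)
            else:
                dfree = nc + nt - 2
                sp2 = ((nc - 1) * sc**2 + (nt - 1) * st**2) / dfree
                j = 1.0 - 3.0 / (4.0 * dfree - 1.0)
                yi = j * (mt - mc) / np.sqrt(sp2)
                vi = (nc + nt) / (nc * nt) + yi**2 / (2.0 * (nc + nt))
    else:
        if kind != CORRELATION or metric != "fishers_z":
            raise ValueError(f"metric {metric!r} does not apply to {kind!r} data")
        r = df["r"].to_numpy(float)
        n = df["n"].to_numpy(float)
        yi = np.arctanh(r)
        with np.errstate(invalid="ignore", divide="ignore"):
            vi = 1.0 / (n - 3.0)
    return pd.DataFrame({"yi": yi, "vi": vi})


def default_metrics(kind: str) -> tuple:
    """Metrics evaluated on a dataset kind: (lnrr, hedges_d) or (fishers_z,)."""
    return ("lnrr", "hedges_d") if kind == MEAN_DIFFERENCE else ("fishers_z",)
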
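"""Deletion of SDs and sample sizes under four missingness scenarios.

Scenarios:

* ``MCAR`` — rows deleted uniformly at random.
* ``MAR`` — deletion probability grows linearly with the rank position of the
  effect size when effects are ranked in decreasing order, so the smallest
  effects are the most likely to lose their SDs/SSs.
* ``MNAR`` — deletion probability grows with the rank of the summed SDs
  (increasing order) plus the rank of the summed sample sizes (decreasing
  order): low-precision, low-n studies are the most likely to be incomplete.
* ``corMCAR`` — deletion itself is uniform; the correlation between effect
  size and precision is built into the dataset beforehand
  (:func:`metamiss.synthetic.sort_for_cormcar`).

Deletion is always paired within a row: an SD deletion removes both sd_c and
sd_t, an SS deletion removes both n_c and n_t (or the single n).  SD and SS
deletions are sampled independently of one another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import (
    CORRELATION,
    MEAN_DIFFERENCE,
    IncompleteDataset,
    MetaDataset,
    ValidationError,
)
from .synthetic import raw_effect_size

SCENARIOS = ("MCAR", "MAR", "MNAR", "corMCAR")
TARGETS = ("SD", "SS", "BOTH")


@dataclass(frozen=True)
class DeletionPlan:
    scenario: str
    target: str
    fraction: float

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValidationError(f"unknown scenario {self.scenario!r}")
        if self.target not in TARGETS:
            raise ValidationError(f"unknown target {self.target!r}")
        if not 0.0 <= self.fraction <= 0.9:
            raise ValidationError(
                f"deletion fraction must be in [0, 0.9], got {self.fraction}"
            )


def _rank_positions(values: np.ndarray, descending: bool) -> np.ndarray:
    """1-based rank position in the requested ordering; ties broken by row order."""
    key = -values if descending else values
    order = np.argsort(key, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    ranks[order] = np.arange(1, len(values) + 1)
    return ranks


def deletion_weights(ds: MetaDataset, scenario: str) -> np.ndarray:
    """Per-row selection weights (sum to 1) for weighted deletion sampling."""
    if scenario not in SCENARIOS:
        raise ValidationError(f"unknown scenario {scenario!r}")
    n = ds.n_studies
    if n == 0:
        return np.empty(0)
    if scenario in ("MCAR", "corMCAR"):
        return np.full(n, 1.0 / n)
    if scenario == "MAR":
        # rank 1 = largest effect; chance of deletion grows with rank position,
        # so the smallest effect gets the largest weight.
        ranks = _rank_positions(raw_effect_size(ds), descending=True)
        return ranks / ranks.sum()
    # MNAR
    if ds.kind == MEAN_DIFFERENCE:
        for col in ("sd_c", "sd_t", "n_c", "n_t"):
            if ds.data[col].isna().any():
                raise ValidationError("MNAR weights need complete SD and SS columns")
        sd_sum = (ds.data["sd_c"] + ds.data["sd_t"]).to_numpy()
        n_sum = (ds.data["n_c"] + ds.data["n_t"]).to_numpy()
        ranks = _rank_positions(sd_sum, descending=False) + _rank_positions(
            n_sum, descending=True
        )
    else:
        if ds.data["n"].isna().any():
            raise ValidationError("MNAR weights need a complete SS column")
        ranks = _rank_positions(ds.data["n"].to_numpy(), descending=True)
    return ranks / ranks.sum()


def _n_deleted(fraction: float, n: int) -> int:
    return int(np.floor(fraction * n + 0.5))


def apply_deletion(
    ds: MetaDataset, plan: DeletionPlan, rng: np.random.Generator
) -> IncompleteDataset:
    """Mask SD and/or SS pairs in ``round(fraction * n)`` rows.

    Rows are chosen by weighted sampling without replacement using
    :func:`deletion_weights`; for target BOTH the SD rows and SS rows are
    drawn independently.  Surviving values are never altered.
    """
    if not ds.is_complete():
        raise ValidationError("deletion requires a complete dataset")
    if ds.kind == CORRELATION and plan.target != "SS":
        raise ValidationError("correlation datasets only support target='SS'")
    n = ds.n_studies
    k = _n_deleted(plan.fraction, n)
    if k > n:
        raise ValidationError(f"cannot delete {k} of {n} rows")
    weights = deletion_weights(ds, plan.scenario)

    def pick() -> np.ndarray:
        mask = np.zeros(n, dtype=bool)
        if k > 0:
            idx = rng.choice(n, size=k, replace=False, p=weights)
            mask[idx] = True
        return mask

    sd_mask = pick() if plan.target in ("SD", "BOTH") else np.zeros(n, dtype=bool)
    ss_mask = pick() if plan.target in ("SS", "BOTH") else np.zeros(n, dtype=bool)

    data = ds.data.copy()
    if ds.kind == MEAN_DIFFERENCE:
        data.loc[sd_mask, ["sd_c", "sd_t"]] = np.nan
        data.loc[ss_mask, ["n_c", "n_t"]] = np.nan
    else:
        data.loc[ss_mask, ["n"]] = np.nan
    return IncompleteDataset(base=ds, data=data, sd_deleted=sd_mask, ss_deleted=ss_mask)
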
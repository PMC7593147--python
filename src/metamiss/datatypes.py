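"""Core containers shared across the package.

A meta-analysis data set is held as a :class:`pandas.DataFrame` with one row
per study.  Mean-difference data carry the six columns
``mean_c, mean_t, sd_c, sd_t, n_c, n_t`` (control/treatment group means,
standard deviations and sample sizes); correlation data carry ``r, n``.
Missing cells are ``NaN``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MD_COLUMNS = ["mean_c", "mean_t", "sd_c", "sd_t", "n_c", "n_t"]
CORR_COLUMNS = ["r", "n"]

MEAN_DIFFERENCE = "mean_difference"
CORRELATION = "correlation"


class ValidationError(ValueError):
    """Raised when a distribution spec or dataset violates its invariants."""


@dataclass(frozen=True)
class TruncNormalSpec:
    """Normal distribution truncated to ``[lower, upper]``."""

    mean: float
    sd: float
    lower: float = -math.inf
    upper: float = math.inf

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError(f"sd must be >= 0, got {self.sd}")
        if not self.lower < self.upper:
            raise ValidationError(
                f"lower ({self.lower}) must be strictly below upper ({self.upper})"
            )


@dataclass(frozen=True)
class TruncPoissonSpec:
    """Poisson(lam) conditioned on X >= lower."""

    lam: float
    lower: int = 0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValidationError(f"lam must be > 0, got {self.lam}")
        if self.lower < 0:
            raise ValidationError(f"lower must be >= 0, got {self.lower}")


@dataclass
class MetaDataset:
    """An ordered collection of simulated (or user-supplied) studies."""

    kind: str
    data: pd.DataFrame
    replicate_id: int = 0
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        expected = MD_COLUMNS if self.kind == MEAN_DIFFERENCE else CORR_COLUMNS
        if self.kind not in (MEAN_DIFFERENCE, CORRELATION):
            raise ValidationError(f"unknown dataset kind {self.kind!r}")
        missing = [c for c in expected if c not in self.data.columns]
        if missing:
            raise ValidationError(f"{self.kind} dataset lacks columns {missing}")
        self.data = self.data[expected].reset_index(drop=True)

    @property
    def n_studies(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> Sequence[str]:
        return MD_COLUMNS if self.kind == MEAN_DIFFERENCE else CORR_COLUMNS

    def is_complete(self) -> bool:
        return not self.data.isna().any().any()

    def copy(self) -> "MetaDataset":
        return MetaDataset(self.kind, self.data.copy(), self.replicate_id, self.rng_seed)


@dataclass
class IncompleteDataset:
    """A dataset after deletion: values masked to NaN plus the row-level masks.

    ``sd_deleted[i]`` implies both sd_c and sd_t are missing in row i;
    ``ss_deleted[i]`` implies both n_c and n_t (or n, for correlation data).
    """

    base: MetaDataset
    data: pd.DataFrame
    sd_deleted: np.ndarray
    ss_deleted: np.ndarray

    @property
    def kind(self) -> str:
        return self.base.kind

    @property
    def n_studies(self) -> int:
        return len(self.data)

    def missing_fraction(self) -> float:
        """Largest per-column share of missing cells (0 when complete)."""
        frac = self.data.isna().mean()
        return float(frac.max()) if len(frac) else 0.0


@dataclass(frozen=True)
class EffectSize:
    """Point estimate and sampling variance for one study."""

    yi: float
    vi: Optional[float] = None
    weight_kind: str = "inverse_variance"

    def __post_init__(self) -> None:
        if not math.isfinite(self.yi):
            raise ValidationError(f"yi must be finite, got {self.yi}")
        if self.vi is not None and not self.vi > 0:
            raise ValidationError(f"vi must be > 0 when present, got {self.vi}")


@dataclass(frozen=True)
class MetaEstimate:
    """Grand mean and normal-approximation 95% CI from one random-effects fit."""

    mu: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    k: int


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules combination of estimates from multiply imputed data."""

    mu: float
    se: float
    ci_low: float
    ci_high: float
    m_used: int
    within_var: float
    between_var: float


@dataclass(frozen=True)
class TreatmentOption:
    """One of the 14 ways to handle missing SDs and/or sample sizes."""

    id: int
    name: str
    requires: str  # "none", "SS" or "SD+SS"
    is_multiple: bool


@dataclass
class DeviationRecord:
    """One factorial cell's outcome relative to the fully informed reference."""

    scenario: str
    deleted: str
    fraction: float
    effect_size: str
    option_id: int
    option_name: str
    replicate_id: int
    status: str
    dev_mu: float = math.nan
    dev_ci_width: float = math.nan
    mu: float = math.nan
    ci_width: float = math.nan
    k_used: int = 0
    m_used: int = 0
    reason: str = ""
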
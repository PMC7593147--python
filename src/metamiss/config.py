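"""Experiment configuration with the simulation study's design as defaults.

The default design: 4 missingness scenarios; SD, SS and BOTH deletion for 10
mean-difference replicates plus SS deletion for 10 correlation replicates;
16 deletion fractions spanning 10%-90%; 14 treatment options; 100 studies
per data set; 100 imputations per multiple-imputation method.

The fraction grid is ``linspace(0.10, 0.90, 16)``: sixteen equally spaced
steps that keep both printed endpoints (spacing ~5.3%).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import yaml

DEFAULT_FRACTIONS: Tuple[float, ...] = tuple(
    float(f) for f in np.round(np.linspace(0.10, 0.90, 16), 6)
)


@dataclass
class ExperimentConfig:
    n_studies: int = 100
    n_replicates: int = 10
    m: int = 100
    master_seed: int = 1
    scenarios: Tuple[str, ...] = ("MCAR", "MAR", "MNAR", "corMCAR")
    md_targets: Tuple[str, ...] = ("SD", "SS", "BOTH")
    include_mean_difference: bool = True
    include_correlation: bool = True
    fractions: Tuple[float, ...] = DEFAULT_FRACTIONS
    options: Tuple[int, ...] = tuple(range(1, 15))
    n_chain_iters: int = 5
    pmm_donors: int = 5
    em_missing_cutoff: float = 0.6

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f: raw[f] for f in cls.__dataclass_fields__ if f in raw}
        for key in ("scenarios", "md_targets", "fractions", "options"):
            if key in known:
                known[key] = tuple(known[key])
        return cls(**known)
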
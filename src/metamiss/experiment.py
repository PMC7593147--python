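"""Factorial evaluation of the 14 missing-data treatments.

For every cell of the design (scenario x deleted-data type x deletion
fraction x replicate), each applicable treatment is run on the incomplete
data set and its grand mean / CI width are compared with a fully informed
weighted meta-analysis of the same complete data set:

    dev_mu       = treatment grand mean - reference grand mean
    dev_ci_width = treatment CI width   - reference CI width

Treatment options (ids match the fixed registry):

 1 complete-case, 2 unweighted, 3 SS-weighted (sample-size variance
 approximation), 4 mean imputation, 5 median imputation, 6-11 chained
 equations (random sample, linear regression, PMM, CART, random forest,
 Bayes PMM), 12 bootstrap EM, 13 missForest-style, 14 additive regression +
 bootstrap PMM.

Options 2 and 3 evaluate the *simple* log response ratio (computable without
SDs); all other options evaluate the bias-corrected lnRR, Hedges' d or
Fisher's z.  Option 3 is not applicable to Hedges' d, whose own calculation
requires the SDs that the approximation is meant to replace.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import ExperimentConfig
from .datatypes import (
    CORRELATION,
    DeviationRecord,
    IncompleteDataset,
    MEAN_DIFFERENCE,
    MetaDataset,
    MetaEstimate,
    PooledEstimate,
    TreatmentOption,
    ValidationError,
)
from .effect_sizes import compute_effect_sizes, default_metrics
from .imputation import ImputationConfig, ImputationError, impute
from .meta_analysis import random_effects_fit, rubin_pool
from .missingness import DeletionPlan, apply_deletion
from .synthetic import (
    generate_correlation_dataset,
    generate_mean_difference_dataset,
    sort_for_cormcar,
)

TREATMENTS: Tuple[TreatmentOption, ...] = (
    TreatmentOption(1, "complete_case", "SD+SS", False),
    TreatmentOption(2, "unweighted", "none", False),
    TreatmentOption(3, "ss_weighted", "SS", False),
    TreatmentOption(4, "mean", "none", False),
    TreatmentOption(5, "median", "none", False),
    TreatmentOption(6, "random_sample", "none", True),
    TreatmentOption(7, "linear_regression", "none", True),
    TreatmentOption(8, "pmm", "none", True),
    TreatmentOption(9, "cart", "none", True),
    TreatmentOption(10, "random_forest", "none", True),
    TreatmentOption(11, "bayes_pmm", "none", True),
    TreatmentOption(12, "bootstrap_em", "none", True),
    TreatmentOption(13, "missforest", "none", True),
    TreatmentOption(14, "addreg_boot_pmm", "none", True),
)
TREATMENT_BY_ID: Dict[int, TreatmentOption] = {t.id: t for t in TREATMENTS}


@dataclasses.dataclass
class TreatmentResult:
    status: str  # "ok", "skipped" or "failed"
    pooled: Optional[PooledEstimate] = None
    k_used: int = 0
    m_used: int = 0
    reason: str = ""


def fully_informed_reference(ds: MetaDataset, metric: str) -> MetaEstimate:
    """Weighted random-effects fit of the complete data set (the benchmark)."""
    if not ds.is_complete():
        raise ValidationError("the fully informed reference needs complete data")
    es = compute_effect_sizes(ds.data, ds.kind, metric)
    return random_effects_fit(es["yi"].to_numpy(), es["vi"].to_numpy())


def _fit_weighted(es: pd.DataFrame) -> Tuple[Optional[MetaEstimate], int]:
    ok = es["yi"].notna() & es["vi"].notna() & (es["vi"] > 0)
    k = int(ok.sum())
    if k < 2:
        return None, k
    return random_effects_fit(es.loc[ok, "yi"].to_numpy(), es.loc[ok, "vi"].to_numpy()), k


def _simple_yi(df: pd.DataFrame, kind: str, metric: str) -> np.ndarray:
    """Per-row effect estimate computable without SDs (options 2 and 3)."""
    if metric == "lnrr":
        return np.log(df["mean_t"].to_numpy(float) / df["mean_c"].to_numpy(float))
    if metric == "fishers_z":
        return np.arctanh(df["r"].to_numpy(float))
    # Hedges' d has no SD-free form; rows lacking SDs/SSs are incomputable.
    return compute_effect_sizes(df, kind, metric)["yi"].to_numpy()


def run_treatment(
    inc: IncompleteDataset,
    option_id: int,
    metric: str,
    rng: np.random.Generator,
    m: int = 100,
    imputation_kwargs: Optional[dict] = None,
) -> TreatmentResult:
    """Apply one treatment option to an incomplete data set."""
    opt = TREATMENT_BY_ID[option_id]
    df = inc.data
    kind = inc.kind

    if opt.id == 1:  # complete-case: weighted fit on fully reported rows
        es = compute_effect_sizes(df, kind, metric)
        est, k = _fit_weighted(es)
        if est is None:
            return TreatmentResult("failed", reason=f"only {k} complete rows", k_used=k)
        return TreatmentResult("ok", pooled=rubin_pool([est]), k_used=k, m_used=1)

    if opt.id == 2:  # unweighted fit on all rows with a computable estimate
        yi = _simple_yi(df, kind, metric)
        yi = yi[np.isfinite(yi)]
        if len(yi) < 2:
            return TreatmentResult("failed", reason="fewer than 2 computable rows")
        est = random_effects_fit(yi, None)
        return TreatmentResult("ok", pooled=rubin_pool([est]), k_used=len(yi), m_used=1)

    if opt.id == 3:  # sample-size variance approximation
        if metric == "hedges_d":
            return TreatmentResult(
                "skipped",
                reason="SS-weighting is not applicable to Hedges' d, whose "
                "calculation itself requires the SDs",
            )
        yi = _simple_yi(df, kind, metric)
        if kind == MEAN_DIFFERENCE:
            nc = df["n_c"].to_numpy(float)
            nt = df["n_t"].to_numpy(float)
            vi = (nt + nc) / (nt * nc)
        else:
            vi = 1.0 / (df["n"].to_numpy(float) - 3.0)
        es = pd.DataFrame({"yi": yi, "vi": vi})
        est, k = _fit_weighted(es)
        if est is None:
            return TreatmentResult("failed", reason=f"only {k} rows with sample sizes")
        return TreatmentResult("ok", pooled=rubin_pool([est]), k_used=k, m_used=1)

    # options 4-14: impute, fit each completed data set, pool by Rubin's rules
    kwargs = dict(imputation_kwargs or {})
    cfg = ImputationConfig(method=opt.name, m=1 if opt.id in (4, 5) else m, **kwargs)
    try:
        outcome = impute(inc, cfg, rng)
    except ImputationError as exc:
        return TreatmentResult("failed", reason=str(exc))
    if outcome.status != "ok":
        return TreatmentResult(outcome.status, reason=outcome.reason)
    estimates = []
    for completed in outcome.datasets:
        es = compute_effect_sizes(completed, kind, metric)
        est, k = _fit_weighted(es)
        if est is not None:
            estimates.append(est)
    if not estimates:
        return TreatmentResult("failed", reason="no imputed data set could be fitted")
    pooled = rubin_pool(estimates)
    return TreatmentResult(
        "ok", pooled=pooled, k_used=len(outcome.datasets[0]), m_used=len(estimates)
    )


# ---------------------------------------------------------------------------
# Factorial sweep


def _dataset_types(cfg: ExperimentConfig) -> List[Tuple[str, str]]:
    types: List[Tuple[str, str]] = []
    if cfg.include_mean_difference:
        types += [(MEAN_DIFFERENCE, t) for t in cfg.md_targets]
    if cfg.include_correlation:
        types.append((CORRELATION, "SS"))
    return types


def plan_factorial(cfg: ExperimentConfig) -> pd.DataFrame:
    """Enumerate the incomplete data sets the design will create (no fitting).

    One row per scenario x deleted-data type x replicate x fraction; the
    default configuration enumerates 2,560 rows.
    """
    rows = []
    for scenario in cfg.scenarios:
        for kind, target in _dataset_types(cfg):
            for rep in range(cfg.n_replicates):
                for frac in cfg.fractions:
                    rows.append(
                        {
                            "scenario": scenario,
                            "kind": kind,
                            "deleted": target,
                            "replicate_id": rep,
                            "fraction": frac,
                        }
                    )
    return pd.DataFrame(rows)


def _base_dataset(
    kind: str, rep: int, cfg: ExperimentConfig
) -> MetaDataset:
    tag = 101 if kind == MEAN_DIFFERENCE else 102
    rng = np.random.default_rng(np.random.SeedSequence([cfg.master_seed, tag, rep]))
    if kind == MEAN_DIFFERENCE:
        return generate_mean_difference_dataset(cfg.n_studies, rng, replicate_id=rep)
    return generate_correlation_dataset(cfg.n_studies, rng, replicate_id=rep)


def run_factorial(cfg: ExperimentConfig, progress: bool = False) -> pd.DataFrame:
    """Run the full design and return one DeviationRecord row per cell x option.

    Per-cell randomness is derived from the master seed and the cell's
    coordinates, so cells are decoupled and the sweep is reproducible.
    Individual cell failures are recorded, never abort the sweep.
    """
    records: List[DeviationRecord] = []
    ref_cache: Dict[Tuple, MetaEstimate] = {}
    ds_cache: Dict[Tuple, MetaDataset] = {}
    for si, scenario in enumerate(cfg.scenarios):
        for ti, (kind, target) in enumerate(_dataset_types(cfg)):
            for rep in range(cfg.n_replicates):
                key = (scenario == "corMCAR", kind, rep)
                if key not in ds_cache:
                    base = _base_dataset(kind, rep, cfg)
                    ds_cache[key] = sort_for_cormcar(base) if key[0] else base
                ds = ds_cache[key]
                for fi, frac in enumerate(cfg.fractions):
                    del_rng = np.random.default_rng(
                        np.random.SeedSequence([cfg.master_seed, 7, si, ti, rep, fi])
                    )
                    inc = apply_deletion(
                        ds, DeletionPlan(scenario, target, frac), del_rng
                    )
                    for option_id in cfg.options:
                        opt = TREATMENT_BY_ID[option_id]
                        for metric in default_metrics(kind):
                            rkey = (key, metric)
                            if rkey not in ref_cache:
                                ref_cache[rkey] = fully_informed_reference(ds, metric)
                            ref = ref_cache[rkey]
                            t_rng = np.random.default_rng(
                                np.random.SeedSequence(
                                    [cfg.master_seed, 8, si, ti, rep, fi, option_id]
                                )
                            )
                            res = run_treatment(
                                inc,
                                option_id,
                                metric,
                                t_rng,
                                m=cfg.m,
                                imputation_kwargs={
                                    "n_chain_iters": cfg.n_chain_iters,
                                    "pmm_donors": cfg.pmm_donors,
                                    "em_missing_cutoff": cfg.em_missing_cutoff,
                                },
                            )
                            rec = DeviationRecord(
                                scenario=scenario,
                                deleted=target,
                                fraction=frac,
                                effect_size=metric,
                                option_id=option_id,
                                option_name=opt.name,
                                replicate_id=rep,
                                status=res.status,
                                k_used=res.k_used,
                                m_used=res.m_used,
                                reason=res.reason,
                            )
                            if res.status == "ok":
                                p = res.pooled
                                ref_width = ref.ci_high - ref.ci_low
                                rec.mu = p.mu
                                rec.ci_width = p.ci_high - p.ci_low
                                rec.dev_mu = p.mu - ref.mu
                                rec.dev_ci_width = rec.ci_width - ref_width
                            records.append(rec)
                    if progress:
                        print(
                            f"{scenario} {kind}/{target} rep={rep} frac={frac:.3f}",
                            flush=True,
                        )
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def summarize_deviation(records: pd.DataFrame) -> pd.DataFrame:
    """Average deviations over replicates for each design cell x option."""
    if records.empty:
        raise ValueError("no records to summarize")
    ok = records[records["status"] == "ok"]
    keys = ["scenario", "deleted", "effect_size", "option_id", "option_name", "fraction"]
    out = (
        ok.groupby(keys, as_index=False)
        .agg(
            dev_mu=("dev_mu", "mean"),
            dev_ci_width=("dev_ci_width", "mean"),
            n_replicates=("replicate_id", "nunique"),
        )
        .sort_values(keys)
        .reset_index(drop=True)
    )
    return out


def plot_deviation(summary: pd.DataFrame, path) -> None:
    """Deviation-versus-fraction panel plot (CI-width deviation halved for
    visibility, as in the reference figures; stored records keep full width)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cells = summary[["scenario", "deleted", "effect_size"]].drop_duplicates()
    ncells = len(cells)
    fig, axes = plt.subplots(
        ncells, 1, figsize=(7, 2.4 * ncells), squeeze=False, sharex=True
    )
    for ax, (_, cell) in zip(axes.ravel(), cells.iterrows()):
        sub = summary[
            (summary["scenario"] == cell["scenario"])
            & (summary["deleted"] == cell["deleted"])
            & (summary["effect_size"] == cell["effect_size"])
        ]
        for name, grp in sub.groupby("option_name"):
            ax.plot(grp["fraction"], grp["dev_mu"], label=name, lw=1)
            ax.plot(
                grp["fraction"], grp["dev_ci_width"] / 2.0, ls=":", lw=0.8,
                color=ax.lines[-1].get_color(),
            )
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set_title(
            f"{cell['scenario']} / deleted {cell['deleted']} / {cell['effect_size']}",
            fontsize=9,
        )
        ax.set_ylabel("deviation")
    axes.ravel()[-1].set_xlabel("fraction of values deleted")
    axes.ravel()[0].legend(fontsize=6, ncol=3)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def compare_on_user_data(
    ds: MetaDataset,
    metric: str,
    m: int = 100,
    seed: int = 0,
    options: Optional[Tuple[int, ...]] = None,
) -> pd.DataFrame:
    """Run every applicable treatment on a user-supplied meta-analysis table.

    The table's own missingness pattern is used; rows of the result report
    each option's pooled grand mean and CI.
    """
    data = ds.data
    if ds.kind == MEAN_DIFFERENCE:
        sd_mask = data[["sd_c", "sd_t"]].isna().any(axis=1).to_numpy()
        ss_mask = data[["n_c", "n_t"]].isna().any(axis=1).to_numpy()
    else:
        sd_mask = np.zeros(len(data), dtype=bool)
        ss_mask = data["n"].isna().to_numpy()
    inc = IncompleteDataset(base=ds, data=data.copy(), sd_deleted=sd_mask, ss_deleted=ss_mask)
    rows = []
    for opt in TREATMENTS:
        if options is not None and opt.id not in options:
            continue
        rng = np.random.default_rng(np.random.SeedSequence([seed, opt.id]))
        res = run_treatment(inc, opt.id, metric, rng, m=m)
        row = {
            "option_id": opt.id,
            "option_name": opt.name,
            "status": res.status,
            "k_used": res.k_used,
            "m_used": res.m_used,
            "reason": res.reason,
        }
        if res.status == "ok":
            p = res.pooled
            row.update(
                mu=p.mu, se=p.se, ci_low=p.ci_low, ci_high=p.ci_high,
                between_var=p.between_var,
            )
        rows.append(row)
    return pd.DataFrame(rows)
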
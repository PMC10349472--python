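"""Batch-to-batch variation and replicate-placement strategy analysis.

High-throughput screens run in consecutive batches (one microtiter plate
cultivation per batch). Run-level nuisance effects — a cryo-culture lot, a
reagent preparation, assay drift — shift every measurement of a batch
together. How biological replicates are placed relative to batches decides
whether that shift is visible:

- *same_plate*: all biological replicates of a strain x condition cell sit
  in one batch. Their spread reflects only within-batch noise; a batch
  shift moves the whole cell and masquerades as a condition effect (the
  "Golden Batch" trap, where one historically good run becomes an
  unrepresentative benchmark).
- *spread*: biological replicates are distributed over consecutive
  batches. Their spread then includes the between-batch component, so the
  reported error honestly covers batch-to-batch variation.

This module quantifies both: a balanced one-way random-effects
decomposition of activities into between-batch and within-batch variance
components (method of moments on mean squares), a head-to-head comparison
of the two placement strategies, and the weekly reporting used for
cryo-storage stability studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VarianceReport",
    "variance_components",
    "flag_outlier_batches",
    "compare_strategies",
    "weekly_report",
    "max_relative_deviation",
]


@dataclass(frozen=True)
class VarianceReport:
    """One-way random-effects decomposition over batches.

    total variance ~ between-batch + within-batch for balanced designs.
    ``truncated`` is True when the raw between-batch moment estimate was
    negative (sampling noise) and got reported as 0.
    """

    grand_mean: float
    pooled_sd: float
    var_between: float
    var_within: float
    n_batches: int
    n_per_batch: int
    truncated: bool


def variance_components(
    table: pd.DataFrame,
    value: str = "activity_U_per_mL",
    batch: str = "batch",
) -> VarianceReport:
    """Method-of-moments variance decomposition for a balanced batch design.

    With k batches of n observations each, the between-batch mean square
    has expectation ``var_within + n * var_between``, the within-batch
    mean square estimates ``var_within``; solving gives the components.
    A negative between-batch estimate is truncated at 0 and flagged.
    """
    if batch not in table.columns or value not in table.columns:
        raise ValueError(f"table needs columns {batch!r} and {value!r}")
    groups = table.groupby(batch)[value]
    sizes = groups.size()
    k = len(sizes)
    if k < 2:
        raise ValueError(f"need >= 2 batches, got {k}")
    if sizes.max() < 2:
        raise ValueError("need >= 2 replicates per batch in at least one batch")
    if sizes.nunique() != 1:
        raise ValueError("design is unbalanced; balance it before decomposing")
    n = int(sizes.iloc[0])
    means = groups.mean()
    grand = float(table[value].mean())
    msb = float(n * np.sum((means - grand) ** 2) / (k - 1))
    msw = float(
        sum(np.sum((g - g.mean()) ** 2) for _, g in groups) / (k * (n - 1))
    ) if n > 1 else 0.0
    raw_between = (msb - msw) / n
    truncated = raw_between < 0
    return VarianceReport(
        grand_mean=grand,
        pooled_sd=float(table[value].std(ddof=1)),
        var_between=max(raw_between, 0.0),
        var_within=msw,
        n_batches=k,
        n_per_batch=n,
        truncated=truncated,
    )


def flag_outlier_batches(
    table: pd.DataFrame,
    value: str = "activity_U_per_mL",
    batch: str = "batch",
    threshold_sds: float = 2.0,
) -> pd.DataFrame:
    """Flag batches whose mean deviates from the grand mean.

    A batch is flagged when |batch mean - grand mean| exceeds
    ``threshold_sds`` pooled within-batch SDs of the batch mean — a
    heuristic screen for a run that behaved unlike its peers (e.g. a
    "Golden Batch" that would bias a benchmark). Returns one row per
    batch with its mean, standardized deviation and flag.
    """
    rep = variance_components(table, value=value, batch=batch)
    sd_mean = np.sqrt(max(rep.var_within, 1e-300) / rep.n_per_batch)
    means = table.groupby(batch)[value].mean()
    z = (means - rep.grand_mean) / sd_mean
    out = pd.DataFrame({
        "batch": means.index,
        "mean": means.to_numpy(),
        "z_vs_grand": z.to_numpy(),
        "flagged": np.abs(z.to_numpy()) > threshold_sds,
    })
    return out.reset_index(drop=True)


def compare_strategies(
    same_plate: pd.DataFrame,
    spread: pd.DataFrame,
    value: str = "activity_U_per_mL",
    keys: tuple[str, ...] = ("strain", "iptg_uM"),
) -> pd.DataFrame:
    """Contrast replicate SDs under the two placement strategies.

    Both tables must cover the same strain x condition cells. For each
    cell the pooled SD over all replicates is computed per strategy, plus
    their ratio (spread / same_plate). Under a positive batch effect the
    spread-design SD exceeds the same-plate SD in expectation, since only
    the former samples the between-batch component.
    """
    for name, df in (("same_plate", same_plate), ("spread", spread)):
        missing = set(keys) | {value, "batch"}
        missing -= set(df.columns)
        if missing:
            raise ValueError(f"{name} table lacks columns {sorted(missing)}")
    if spread.groupby(list(keys))["batch"].nunique().min() < 2:
        raise ValueError("'spread' design has cells confined to one batch")
    a = same_plate.groupby(list(keys))[value].agg(["mean", "std", "size"])
    b = spread.groupby(list(keys))[value].agg(["mean", "std", "size"])
    if not a.index.equals(b.index):
        raise ValueError("strategy tables cover different strain x condition cells")
    out = pd.DataFrame({
        "mean_same_plate": a["mean"],
        "sd_same_plate": a["std"],
        "mean_spread": b["mean"],
        "sd_spread": b["std"],
        "n": a["size"].astype(int),
    })
    out["sd_ratio"] = out["sd_spread"] / out["sd_same_plate"]
    return out.reset_index()


def weekly_report(
    table: pd.DataFrame,
    error_floor_h: float = 4.0 / 60.0,
    reference: object | None = None,
) -> pd.DataFrame:
    """Weekly two-condition batch-time report.

    ``table`` is long-format with columns ``week, condition`` and either
    replicate values (``batch_time_h``, summarised here with the SD floored
    at ``error_floor_h``) or precomputed summaries (``mean_h, sd_h``).
    Exactly two conditions are required; ``reference`` picks which one the
    differences are taken against (default: first in sorted order).

    Returns one row per week with per-condition mean/SD, the mean
    difference (other - reference), the relative difference against the
    reference mean, and each condition's relative deviation (SD/mean).
    """
    if "condition" not in table.columns or "week" not in table.columns:
        raise ValueError("table needs 'week' and 'condition' columns")
    conds = sorted(table["condition"].unique())
    if len(conds) != 2:
        raise ValueError(f"expected exactly 2 conditions, got {conds}")
    if reference is None:
        reference = conds[0]
    if reference not in conds:
        raise ValueError(f"reference {reference!r} not among conditions {conds}")
    other = conds[0] if conds[1] == reference else conds[1]

    if "batch_time_h" in table.columns:
        summ = (
            table.groupby(["week", "condition"])["batch_time_h"]
            .agg(mean_h="mean", sd_h=lambda v: np.std(v, ddof=1) if len(v) > 1 else 0.0)
            .reset_index()
        )
        summ["sd_h"] = summ["sd_h"].clip(lower=error_floor_h)
    elif {"mean_h", "sd_h"} <= set(table.columns):
        summ = table[["week", "condition", "mean_h", "sd_h"]].copy()
        summ["sd_h"] = summ["sd_h"].clip(lower=error_floor_h)
    else:
        raise ValueError("table needs 'batch_time_h' or 'mean_h'+'sd_h' columns")

    wide = summ.pivot(index="week", columns="condition")
    rows = []
    for week in wide.index:
        m_ref = wide[("mean_h", reference)][week]
        m_oth = wide[("mean_h", other)][week]
        rows.append({
            "week": week,
            "mean_ref_h": m_ref,
            "sd_ref_h": wide[("sd_h", reference)][week],
            "mean_other_h": m_oth,
            "sd_other_h": wide[("sd_h", other)][week],
            "diff_h": m_oth - m_ref,
            "rel_diff": (m_oth - m_ref) / m_ref,
            "rel_dev_ref": wide[("sd_h", reference)][week] / m_ref,
            "rel_dev_other": wide[("sd_h", other)][week] / m_oth,
        })
    out = pd.DataFrame(rows)
    out.attrs["reference"] = reference
    out.attrs["other"] = other
    return out


def max_relative_deviation(report: pd.DataFrame) -> float:
    """Largest SD/mean over all weeks and both conditions of a weekly report."""
    return float(
        np.max(np.r_[report["rel_dev_ref"].to_numpy(),
                     report["rel_dev_other"].to_numpy()])
    )
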
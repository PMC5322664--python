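"""Percent-male summaries and a permutation interaction test.

The plate experiment records, per strain x temperature x replicate, the
exact male count and a hermaphrodite count rounded to the nearest 50.
Percent males is 100 * males / (males + hermaphrodites) per replicate (the
denominator choice is configurable); strain-level values are replicate
means.

Instead of a mixed-model F-test, the temperature x climate-group
interaction is tested by permutation: the observed statistic is the
between-cell variance of the double-centred cell means (cell mean minus
group and treatment means plus the grand mean) on strain-level percent
males, and the null distribution permutes temperature labels within each
strain -- which preserves strain identity and every strain-level (hence
group-level) main effect while breaking any temperature structure.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from andromix.genotypes_io import CLIMATE_GROUPS

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["strain", "locality", "climate_group", "temperature_C",
                    "replicate", "males", "hermaphrodites"]


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"count table lacks column(s) {missing}")
    if len(table) == 0:
        raise ValueError("empty count table")
    return table


def percent_males(table: pd.DataFrame,
                  include_males_in_denominator: bool = True) -> pd.DataFrame:
    """Per-replicate and per-strain x treatment percent males.

    Records with zero total offspring (failed plates) are excluded with a
    warning. Returns one row per strain x temperature with columns
    ``percent_by_rep`` (list) and ``percent_mean``.
    """
    table = _check_table(table).copy()
    denom = table["males"] + table["hermaphrodites"] \
        if include_males_in_denominator else table["hermaphrodites"]
    failed = denom == 0
    if failed.any():
        warnings.warn(f"excluding {int(failed.sum())} failed plate record(s) "
                      "with zero offspring", stacklevel=2)
        table = table[~failed]
        denom = denom[~failed]
    table["percent_males"] = 100.0 * table["males"] / denom
    grouped = (
        table.groupby(["strain", "locality", "climate_group", "temperature_C"],
                      sort=True)["percent_males"]
        .agg(percent_by_rep=list, percent_mean="mean")
        .reset_index()
    )
    return grouped


def climate_group_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Box-plot statistics (median, quartiles, whisker bounds) of percent
    males per climate group x treatment."""
    table = _check_table(table)
    unknown = set(table["climate_group"]) - set(CLIMATE_GROUPS.values())
    if unknown:
        raise ValueError(f"unknown climate group(s): {sorted(unknown)}")
    per_strain = percent_males(table)

    def box_stats(values):
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        iqr = q3 - q1
        lo = values[values >= q1 - 1.5 * iqr].min()
        hi = values[values <= q3 + 1.5 * iqr].max()
        return pd.Series({"median": med, "q1": q1, "q3": q3,
                          "whisker_low": lo, "whisker_high": hi,
                          "n_strains": len(values)})

    summary = (
        per_strain.groupby(["climate_group", "temperature_C"], sort=True)
        ["percent_mean"].apply(box_stats).unstack()
        .reset_index()
    )
    return summary


def _interaction_statistic(cells: np.ndarray, groups: np.ndarray) -> float:
    """Between-cell variance of double-centred strain x treatment means.

    ``cells``: strains x treatments matrix of percent males;
    ``groups``: climate-group index per strain. Cell means are taken per
    group x treatment, then centred by group and treatment margins.
    """
    n_groups = groups.max() + 1
    n_treat = cells.shape[1]
    means = np.empty((n_groups, n_treat))
    for g in range(n_groups):
        means[g] = cells[groups == g].mean(axis=0)
    resid = (means - means.mean(axis=1, keepdims=True)
             - means.mean(axis=0, keepdims=True) + means.mean())
    return float(resid.var())


def interaction_permutation_test(table: pd.DataFrame, n_perm: int = 10_000,
                                 seed: int = 0) -> dict:
    """Permutation test of the temperature x climate-group interaction.

    Null: temperature labels are exchangeable within strain. The p-value is
    (1 + #{permuted statistic >= observed}) / (1 + n_perm), so n_perm = 0
    gives p = 1. Deterministic given ``seed``.
    """
    table = _check_table(table)
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse p-value", stacklevel=2)
    per_strain = percent_males(table)
    wide = per_strain.pivot_table(index=["strain", "climate_group"],
                                  columns="temperature_C",
                                  values="percent_mean")
    wide = wide.dropna()  # strains observed under every treatment
    groups_lab = wide.index.get_level_values("climate_group")
    labels = sorted(set(groups_lab))
    if len(labels) < 2 or wide.shape[1] < 2:
        raise ValueError("need >= 2 climate groups and >= 2 treatments")
    groups = np.array([labels.index(g) for g in groups_lab])
    cells = wide.to_numpy()

    observed = _interaction_statistic(cells, groups)
    rng = np.random.default_rng(seed)
    n_ge = 0
    n_strains, n_treat = cells.shape
    for _ in range(n_perm):
        perm = cells[np.arange(n_strains)[:, None],
                     rng.permuted(np.tile(np.arange(n_treat), (n_strains, 1)),
                                  axis=1)]
        if _interaction_statistic(perm, groups) >= observed:
            n_ge += 1
    p_value = (1 + n_ge) / (1 + n_perm)
    return {"statistic": observed, "p_value": p_value, "n_perm": n_perm,
            "n_strains": n_strains}
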
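"""Population-level statistics: outlier removal, rank tests, heterogeneity.

Conventions: Tukey-fence outlier removal (outside Q1 - 1.5*IQR or
Q3 + 1.5*IQR, quartiles by linear interpolation), non-parametric group
comparisons (two groups: Wilcoxon rank-sum / Mann-Whitney; k groups:
Kruskal-Wallis), and a per-cell cross-zone heterogeneity score: moduli are
standardised to unit variance within each zone across the population, and
the variance of each cell's standardised values across zones is reported.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError

__all__ = [
    "iqr_filter",
    "rank_sum_test",
    "signed_rank_test",
    "kruskal_test",
    "rank_tests",
    "to_population_table",
    "cross_zone_variance",
    "group_summary",
    "plot_heatmap",
]

ALPHA = 0.05


def iqr_filter(values) -> tuple[np.ndarray, np.ndarray]:
    """Remove Tukey-fence outliers; returns ``(kept, removed_indices)``.

    Quartiles use linear interpolation.  With fewer than 4 values the data
    pass through unchanged with a warning (quartiles are meaningless).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ConfigError("iqr_filter expects a 1-d array")
    if len(x) < 4:
        warnings.warn("fewer than 4 values: IQR filter passes data through", stacklevel=2)
        return x.copy(), np.array([], dtype=int)
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    removed = np.flatnonzero((x < lo) | (x > hi))
    kept = np.delete(x, removed)
    return kept, removed


def rank_sum_test(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) for unpaired groups.

    Uses the exact null distribution when both groups are small and free
    of ties.  Returns ``(statistic, p_value)`` with the statistic being
    the rank sum of the first group.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ConfigError("groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    # rank-sum statistic W = U + n_a*(n_a+1)/2
    w = float(res.statistic) + len(a) * (len(a) + 1) / 2.0
    return w, float(res.pvalue)


def signed_rank_test(a, b) -> tuple[float, float]:
    """Wilcoxon signed-rank test for *paired* samples.

    Provided for completeness; it applies to paired designs only and is
    not a substitute for the rank-sum test on independent groups.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) == 0:
        raise ConfigError("signed-rank test needs paired, equal-length samples")
    res = stats.wilcoxon(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def kruskal_test(*groups) -> tuple[float, float]:
    """Kruskal-Wallis rank test across k independent groups."""
    if any(len(g) == 0 for g in groups) or len(groups) < 2:
        raise ConfigError("need >= 2 non-empty groups")
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def rank_tests(*groups) -> tuple[float, float]:
    """Dispatch: two groups -> rank-sum test, more -> Kruskal-Wallis."""
    if len(groups) < 2:
        raise ConfigError("need at least two groups")
    if len(groups) == 2:
        return rank_sum_test(*groups)
    return kruskal_test(*groups)


def to_population_table(
    results: pd.DataFrame,
    group: str | Sequence[str] = "all",
    n_zones: int | None = None,
) -> pd.DataFrame:
    """Long-format population table from a wide per-cell results frame.

    One record per (cell, zone) with columns ``cell_id, group, zone, f_Hz,
    Gp, Gpp, eta, D_cell``.  ``group`` is a single label or one label per
    cell.
    """
    if n_zones is None:
        n_zones = sum(c.startswith("zone") and c.endswith("_Gp_Pa") for c in results.columns)
    if isinstance(group, str):
        labels = [group] * len(results)
    else:
        labels = list(group)
        if len(labels) != len(results):
            raise ConfigError("need one group label per cell")
    records = []
    for (_, row), label in zip(results.iterrows(), labels):
        for j in range(1, n_zones + 1):
            records.append(
                {
                    "cell_id": row["cell_id"],
                    "group": label,
                    "zone": j,
                    "f_Hz": row.get(f"zone{j}_f_Hz", np.nan),
                    "Gp": row.get(f"zone{j}_Gp_Pa", np.nan),
                    "Gpp": row.get(f"zone{j}_Gpp_Pa", np.nan),
                    "eta": row.get(f"zone{j}_eta", np.nan),
                    "D_cell": row["D_cell_um"],
                }
            )
    return pd.DataFrame(records)


def cross_zone_variance(table: pd.DataFrame, modulus: str = "Gp") -> pd.Series:
    """Per-cell heterogeneity score across zones.

    Each zone's modulus values are z-scored across the population (unit
    variance per zone), then the variance of each cell's standardised
    values across its zones is returned (NaN for cells with < 2 zones).
    """
    if modulus not in ("Gp", "Gpp"):
        raise ConfigError("modulus must be 'Gp' or 'Gpp'")
    wide = table.pivot_table(index="cell_id", columns="zone", values=modulus)
    std = wide.std(axis=0, ddof=1)
    z = (wide - wide.mean(axis=0)) / std.replace(0.0, np.nan)
    n_zones = z.notna().sum(axis=1)
    score = z.var(axis=1, ddof=1)
    score[n_zones < 2] = np.nan
    score.name = f"{modulus}_cross_zone_variance"
    return score


def group_summary(table: pd.DataFrame, apply_iqr: bool = True) -> pd.DataFrame:
    """Median/IQR summary of Gp, Gpp, eta per (group, zone).

    With ``apply_iqr`` the Tukey-fence filter is applied within each
    (group, zone, quantity) before summarising, mirroring the reporting
    convention of the platform.
    """
    rows = []
    for (g, z), sub in table.groupby(["group", "zone"]):
        row = {"group": g, "zone": z, "n_cells": sub["cell_id"].nunique()}
        for col in ("Gp", "Gpp", "eta"):
            vals = sub[col].dropna().to_numpy()
            if apply_iqr and len(vals) >= 4:
                vals, _ = iqr_filter(vals)
            if len(vals):
                row[f"{col}_median"] = float(np.median(vals))
                row[f"{col}_q1"], row[f"{col}_q3"] = map(float, np.percentile(vals, [25, 75]))
            else:
                row[f"{col}_median"] = row[f"{col}_q1"] = row[f"{col}_q3"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def plot_heatmap(table: pd.DataFrame, modulus: str, path: str, log_scale: bool = True) -> None:
    """Zones-by-cells heatmap of a modulus, cells grouped and sorted by group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    wide = table.pivot_table(index="zone", columns=["group", "cell_id"], values=modulus)
    wide = wide.sort_index(axis=1)
    data = wide.to_numpy()
    if log_scale:
        with np.errstate(invalid="ignore", divide="ignore"):
            data = np.log10(np.where(data > 0, data, np.nan))
    fig, ax = plt.subplots(figsize=(max(4, data.shape[1] / 8), 3))
    im = ax.imshow(data, aspect="auto", cmap="viridis", interpolation="nearest")
    ax.set_xlabel("cell (grouped)")
    ax.set_ylabel("zone")
    ax.set_yticks(range(data.shape[0]), [str(z) for z in wide.index])
    label = f"log10 {modulus} (Pa)" if log_scale else f"{modulus} (Pa)"
    fig.colorbar(im, ax=ax, label=label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
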
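"""Young-vs-aged group tests, differential calls and derived summaries.

The default test is the two-sided equal-variance Student t-test; Welch and
the exact Wilcoxon rank-sum test are selectable.  Calls default to raw
p < alpha combined with a 1.5-fold change cutoff (BH q selectable), both
explicit artifact decisions since the source analysis prints no cutoffs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import AGED, YOUNG, AnalysisConfig, FeatureMatrix, log_stage
from .stats import bh_adjust

METHODS = ("student", "welch", "wilcoxon")


def group_test(matrix: FeatureMatrix, meta: pd.DataFrame,
               method: str = "student", tissue: str | None = None) -> pd.DataFrame:
    """Per-feature two-sided young-vs-aged test with BH adjustment.

    Features with zero variance in both groups and equal means get stat 0,
    p 1; zero variance with unequal means gets the method's limiting value
    (p -> 0) and a ``degenerate`` flag.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    samples = [s for s in matrix.sample_ids if s in meta.index
               and meta.loc[s, "role"] == "biological"]
    grp = meta.loc[samples, "age_group"]
    young = [s for s in samples if grp[s] == YOUNG]
    aged = [s for s in samples if grp[s] == AGED]
    if not young or not aged:
        raise ValueError("both age groups must be present")
    if tissue is None:
        tis = meta.loc[samples, "tissue"].unique()
        tissue = tis[0] if len(tis) == 1 else "pooled"

    Y = matrix.values[young].to_numpy(dtype=float)
    A = matrix.values[aged].to_numpy(dtype=float)
    n_y = (~np.isnan(Y)).sum(axis=1)
    n_a = (~np.isnan(A)).sum(axis=1)
    import warnings as _warnings
    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean_y = np.nanmean(np.where(n_y[:, None] > 0, Y, np.nan), axis=1)
        mean_a = np.nanmean(np.where(n_a[:, None] > 0, A, np.nan), axis=1)
        var_y = np.nanvar(Y, axis=1, ddof=1)
        var_a = np.nanvar(A, axis=1, ddof=1)
    log2fc = mean_a - mean_y
    valid = (n_y >= 2) & (n_a >= 2)
    stat = np.full(len(Y), np.nan)
    p = np.full(len(Y), np.nan)
    degenerate = np.zeros(len(Y), dtype=bool)
    if method == "wilcoxon":
        for i in np.where(valid)[0]:
            a = A[i][~np.isnan(A[i])]
            y = Y[i][~np.isnan(Y[i])]
            if np.ptp(a) == 0 and np.ptp(y) == 0 and mean_a[i] == mean_y[i]:
                stat[i], p[i] = 0.0, 1.0
                continue
            res = sps.mannwhitneyu(a, y, alternative="two-sided",
                                   method="exact" if (a.size + y.size) <= 25
                                   else "asymptotic")
            stat[i], p[i] = float(res.statistic), float(res.pvalue)
    else:
        with np.errstate(invalid="ignore", divide="ignore"), \
                _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            res = sps.ttest_ind(A, Y, axis=1, equal_var=(method == "student"),
                                nan_policy="omit")
        stat[valid] = np.asarray(res.statistic)[valid]
        p[valid] = np.asarray(res.pvalue)[valid]
    zero_both = valid & (var_y == 0) & (var_a == 0)
    eq = zero_both & (mean_y == mean_a)
    stat[eq], p[eq] = 0.0, 1.0
    neq = zero_both & ~eq
    stat[neq] = np.where(mean_a[neq] > mean_y[neq], np.inf, -np.inf)
    p[neq] = 0.0
    degenerate[neq] = True
    table = pd.DataFrame({
        "feature_id": matrix.feature_ids, "tissue": tissue,
        "mean_young": mean_y, "mean_aged": mean_a, "log2fc": log2fc,
        "stat": stat, "p": p, "degenerate": degenerate})
    table["q"] = bh_adjust(table["p"])
    log_stage("group_test", tissue=tissue, method=method, n=len(table))
    return table


def call_features(table: pd.DataFrame, cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Assign up/down/ns calls from significance and fold-change cutoffs."""
    cfg = cfg or AnalysisConfig()
    pcol = "q" if cfg.use_q else "p"
    lfc = np.log2(cfg.fc_cutoff)
    out = table.copy()
    sig = out[pcol] < cfg.alpha
    call = np.where(sig & (out["log2fc"] >= lfc), "up",
                    np.where(sig & (out["log2fc"] <= -lfc), "down", "ns"))
    call[out[pcol].isna().to_numpy()] = "ns"
    out["call"] = call
    return out


def updown_summary(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-tissue up/down counts and the up ratio n_up/(n_up+n_down)."""
    rows = []
    for tissue, tab in tables.items():
        n_up = int((tab["call"] == "up").sum())
        n_down = int((tab["call"] == "down").sum())
        ratio = n_up / (n_up + n_down) if (n_up + n_down) else np.nan
        rows.append((tissue, n_up, n_down, ratio))
    return pd.DataFrame(rows, columns=["tissue", "n_up", "n_down", "up_ratio"])


def high_frequency(tables: dict[str, pd.DataFrame], min_tissues: int,
                   direction: str) -> pd.DataFrame:
    """Features with the given call in >= min_tissues tissues.

    Sorted by descending tissue count, ties broken lexicographically by id.
    Directions are not pooled.
    """
    if min_tissues < 1:
        raise ValueError("min_tissues must be >= 1")
    if direction not in ("up", "down"):
        raise ValueError("direction must be up or down")
    hits: dict[str, list[str]] = {}
    for tissue, tab in tables.items():
        for f in tab.loc[tab["call"] == direction, "feature_id"]:
            hits.setdefault(f, []).append(tissue)
    rows = [(f, direction, len(ts), ",".join(sorted(ts)))
            for f, ts in hits.items() if len(ts) >= min_tissues]
    rows.sort(key=lambda r: (-r[2], r[0]))
    return pd.DataFrame(rows, columns=["feature_id", "direction",
                                       "n_tissues_significant", "tissues"])


def change_score(table: pd.DataFrame, class_map: pd.Series | dict,
                 detected: set[str] | None = None) -> pd.DataFrame:
    """Aging-related change score per feature class for one tissue.

    score = (N_increase - N_decrease) / N_total, where increase/decrease are
    the up/down calls and N_total counts detected classed features.  Classes
    with no detected features are omitted.
    """
    cmap = pd.Series(class_map)
    if detected is None:
        detected = set(table["feature_id"])
    unknown = [f for f in cmap.index if f not in detected]
    if unknown:
        raise ValueError(f"class map references undetected features: {unknown[:5]}")
    tissue = table["tissue"].iloc[0] if len(table) else ""
    calls = table.set_index("feature_id")["call"]
    rows = []
    for cls in sorted(cmap.unique()):
        members = [f for f in cmap.index[cmap == cls] if f in detected]
        if not members:
            continue
        sub = calls.reindex(members)
        n_inc = int((sub == "up").sum())
        n_dec = int((sub == "down").sum())
        n_tot = len(members)
        rows.append((tissue, cls, n_inc, n_dec, n_tot,
                     (n_inc - n_dec) / n_tot))
    return pd.DataFrame(rows, columns=["tissue", "class_label", "n_increase",
                                       "n_decrease", "n_total", "score"])
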
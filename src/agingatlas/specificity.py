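"""Tissue-specificity (TS) scores and organ-specific / organ-enriched labels.

The TS score is a robust z-like statistic of a protein's mean log2 abundance
in one tissue against its cross-tissue background: centred on the median of
tissue means and scaled by 1.4826 x MAD, with the scale floored so that flat
proteins score near zero rather than blowing up.  The scale is floored at
max(0.1, 5% of the cross-tissue range), and each tissue's denominator is
additionally floored at ``ts_sem_mult`` times that tissue's standard error
of the mean (within-tissue sample scatter / sqrt(n)).  The adaptive term
keeps flat-but-noisy proteins near zero (the MAD over a handful of tissues
is unstable) and stops strong within-tissue heterogeneity -- e.g. an
age-driven bimodal tissue -- from masquerading as tissue specificity.  With
a single sample per tissue the SEM term vanishes and the score reduces to
the plain robust z.

Classification follows the printed rules: organ-specific needs TS >= 4 in
exactly one tissue plus a margin of 1.5 over the runner-up (additive by
default; a fold-margin mode exists but TS scores can be non-positive, which
makes ratios ill-defined); organ-enriched covers TS inside the open interval
(2.5, 4) for proteins that are not specific anywhere.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import AnalysisConfig, FeatureMatrix, log_stage


def ts_scores(matrices: dict[str, FeatureMatrix], *,
              sem_mult: float | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-feature, per-tissue TS scores from per-tissue matrices.

    Returns ``(ts, flags)`` where ``flags`` carries ``sigma_floor_used`` and
    ``sparse`` (feature observed in fewer than half of the tissues).
    """
    if len(matrices) < 3:
        raise ValueError("need at least 3 tissues")
    if sem_mult is None:
        sem_mult = AnalysisConfig().ts_sem_mult
    tissues = list(matrices)
    features = sorted({f for m in matrices.values() for f in m.feature_ids})
    means = pd.DataFrame(np.nan, index=features, columns=tissues)
    sems = pd.DataFrame(np.nan, index=features, columns=tissues)
    for t, m in matrices.items():
        vals = m.values
        n_obs = vals.notna().sum(axis=1)
        means.loc[vals.index, t] = vals.mean(axis=1)
        if vals.shape[1] > 1:
            sem = vals.std(axis=1, ddof=1) / np.sqrt(n_obs.clip(lower=1))
            sems.loc[vals.index, t] = sem.where(n_obs > 1)
    X = means.to_numpy()
    med = np.nanmedian(X, axis=1, keepdims=True)
    mad = np.nanmedian(np.abs(X - med), axis=1)
    span = np.nanmax(X, axis=1) - np.nanmin(X, axis=1)
    floor = np.maximum(np.full_like(span, 0.1), 0.05 * span)
    sigma = np.maximum(1.4826 * mad, floor)
    # per-tissue denominator: never below sem_mult x that tissue's SEM, so a
    # tissue mean cannot claim specificity on a deviation comparable to its
    # own within-tissue measurement error; the per-tissue SEM is shrunk
    # toward the feature's median SEM because an 8-sample variance estimate
    # is unreliable downward
    import warnings as _warnings
    sem_arr = sems.to_numpy()
    with np.errstate(all="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        med_sem = np.nanmedian(sem_arr, axis=1)
    med_sem = np.nan_to_num(med_sem, nan=0.0)
    sem_eff = np.maximum(np.nan_to_num(sem_arr, nan=0.0), med_sem[:, None])
    denom = np.maximum(sigma[:, None], sem_mult * sem_eff)
    ts = pd.DataFrame((X - med) / denom, index=features, columns=tissues)
    flags = pd.DataFrame({
        "sigma_floor_used": (1.4826 * mad < floor)
        | (sigma[:, None] < denom).any(axis=1),
        "sparse": np.isnan(X).sum(axis=1) >= len(tissues) / 2,
    }, index=features)
    log_stage("ts_scores", n_features=len(features), n_tissues=len(tissues))
    return ts, flags


def classify_ts(ts: pd.DataFrame, cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Label every feature specific / enriched / none per the printed rules.

    Returns one row per feature: ``label``, ``home_tissues`` (comma-joined;
    the single home tissue for specific, every qualifying tissue for
    enriched) and the realised margin for the top tissue.
    """
    cfg = cfg or AnalysisConfig()
    lo, hi = cfg.ts_enriched_interval
    rows = []
    arr = ts.to_numpy()
    tissues = np.array(ts.columns)
    for i, f in enumerate(ts.index):
        scores = arr[i]
        finite = np.isfinite(scores)
        if not finite.any():
            rows.append((f, "none", "", np.nan))
            continue
        order = np.argsort(np.where(finite, scores, -np.inf))
        top, second = order[-1], order[-2] if len(order) > 1 else None
        top_score = scores[top]
        second_score = scores[second] if second is not None and finite[second] else -np.inf
        if cfg.ts_margin_mode == "additive":
            margin = top_score - second_score
            margin_ok = margin >= cfg.ts_margin
        else:
            margin = (top_score / second_score if second_score > 0 else np.inf)
            margin_ok = second_score <= 0 or top_score >= cfg.ts_margin * second_score
        if top_score >= cfg.ts_specific_min and margin_ok:
            rows.append((f, "specific", str(tissues[top]), float(margin)))
            continue
        enr = [str(tissues[j]) for j in range(len(tissues))
               if finite[j] and lo < scores[j] < hi]
        if cfg.ts_inclusive_enriched and top_score >= cfg.ts_specific_min:
            enr = sorted(set(enr) | {str(tissues[top])})
        if enr:
            rows.append((f, "enriched", ",".join(sorted(enr)), float(margin)))
        else:
            rows.append((f, "none", "", float(margin)))
    out = pd.DataFrame(rows, columns=["feature_id", "label", "home_tissues",
                                      "margin"]).set_index("feature_id")
    log_stage("classify_ts", n_specific=int((out["label"] == "specific").sum()),
              n_enriched=int((out["label"] == "enriched").sum()))
    return out


def resolved_features(classification: pd.DataFrame, tissue: str) -> set[str]:
    """Organ-resolved (specific or enriched) features for one tissue."""
    hit = classification["label"].isin(["specific", "enriched"])
    homes = classification.loc[hit, "home_tissues"].str.split(",")
    return {f for f, hs in homes.items() if tissue in hs}


def shared_resolved(classification: pd.DataFrame,
                    tissue_pair: tuple[str, str],
                    known_tissues: list[str] | None = None) -> list[str]:
    """Features organ-resolved in both tissues of the pair."""
    a, b = tissue_pair
    if known_tissues is not None:
        for t in (a, b):
            if t not in known_tissues:
                raise ValueError(f"unknown tissue {t!r}")
    return sorted(resolved_features(classification, a)
                  & resolved_features(classification, b))


def aging_resolved_overlap(classification: pd.DataFrame,
                           dep_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per tissue: organ-resolved features intersected with up/down calls."""
    rows = []
    for tissue, tab in dep_tables.items():
        resolved = resolved_features(classification, tissue)
        calls = tab.set_index("feature_id")["call"]
        up = sum(1 for f in resolved if calls.get(f) == "up")
        down = sum(1 for f in resolved if calls.get(f) == "down")
        total = len(resolved)
        rows.append((tissue, total, up, down,
                     up / total if total else 0.0,
                     down / total if total else 0.0))
    return pd.DataFrame(rows, columns=["tissue", "n_resolved", "n_up", "n_down",
                                       "frac_up", "frac_down"])
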
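"""Plasma-tissue pair screening and longitudinal window selection.

The screen is a four-criterion cascade: (1) the protein is measured in both
plasma and the tissue; (2) it changes significantly with age in plasma;
(3) plasma and tissue profiles across subject-matched samples (young and
aged pooled) correlate with |Spearman rho| >= the cutoff at p < alpha;
(4) the protein is also differential in that tissue.  Correlation magnitude
is used because negative plasma-tissue couplings are biologically real; the
sign is kept in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AnalysisConfig, FeatureMatrix, log_stage
from .stats import spearman


@dataclass
class CascadeAudit:
    """Stage-by-stage protein/pair counts of the screen."""

    n_stage1: int = 0          # proteins in plasma and >= 1 tissue
    n_stage2: int = 0          # of those, plasma-differential
    n_stage3_pairs: int = 0    # pairs passing the correlation rule
    n_final_proteins: int = 0
    n_final_pairs: int = 0
    n_skipped_pairs: int = 0   # < 4 matched samples
    stage3_proteins: int = 0

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def _matched_columns(plasma: FeatureMatrix, tissue_m: FeatureMatrix,
                     meta: pd.DataFrame) -> list[tuple[str, str]]:
    """Pair plasma/tissue sample ids by subject_id."""
    subj_p = {meta.loc[s, "subject_id"]: s for s in plasma.sample_ids
              if s in meta.index}
    out = []
    for s in tissue_m.sample_ids:
        if s not in meta.index:
            continue
        subj = meta.loc[s, "subject_id"]
        if subj in subj_p:
            out.append((subj_p[subj], s))
    return out


def screen_pairs(plasma: FeatureMatrix, tissues: dict[str, FeatureMatrix],
                 plasma_dep: pd.DataFrame, tissue_deps: dict[str, pd.DataFrame],
                 meta: pd.DataFrame,
                 cfg: AnalysisConfig | None = None
                 ) -> tuple[pd.DataFrame, CascadeAudit]:
    """Run the four-criterion plasma-tissue screening cascade.

    Returns the PairRecord table (protein, tissue, rho, p, sign,
    stage_passed) for every pair reaching at least stage 3 evaluation with a
    passing record, plus the audit of counts per stage.  Pairs with fewer
    than 4 matched samples are skipped and counted.
    """
    cfg = cfg or AnalysisConfig()
    audit = CascadeAudit()

    plasma_feats = set(plasma.feature_ids)
    stage1: set[str] = set()
    for m in tissues.values():
        stage1 |= plasma_feats & set(m.feature_ids)
    audit.n_stage1 = len(stage1)

    calls = plasma_dep.set_index("feature_id")["call"]
    stage2 = {f for f in stage1 if calls.get(f) in ("up", "down")}
    audit.n_stage2 = len(stage2)

    records = []
    stage3_prot = set()
    for t, m in tissues.items():
        pairs_cols = _matched_columns(plasma, m, meta)
        if not pairs_cols:
            continue
        tissue_feats = set(m.feature_ids)
        tcalls = tissue_deps[t].set_index("feature_id")["call"] if t in tissue_deps else pd.Series(dtype=object)
        for f in sorted(stage2 & tissue_feats):
            x = plasma.values.loc[f, [p for p, _ in pairs_cols]].to_numpy(dtype=float)
            y = m.values.loc[f, [s for _, s in pairs_cols]].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 4:
                audit.n_skipped_pairs += 1
                continue
            rho, p = spearman(x[ok], y[ok])
            if not np.isfinite(rho):
                continue
            if abs(rho) >= cfg.rho_cutoff and p < cfg.alpha:
                stage3_prot.add(f)
                passed4 = tcalls.get(f) in ("up", "down")
                records.append((f, t, rho, p,
                                "positive" if rho > 0 else "negative",
                                4 if passed4 else 3))
    audit.n_stage3_pairs = len(records)
    audit.stage3_proteins = len(stage3_prot)
    final = [r for r in records if r[5] == 4]
    audit.n_final_pairs = len(final)
    audit.n_final_proteins = len({r[0] for r in final})
    table = pd.DataFrame(final, columns=["protein_id", "tissue", "rho", "p",
                                         "sign", "stage_passed"])
    log_stage("screen_pairs", **audit.as_dict())
    return table, audit


def longitudinal_window(visits: FeatureMatrix, visit_meta: pd.DataFrame,
                        cfg: AnalysisConfig | None = None, *,
                        min_visits: int = 5,
                        span_days: tuple[int, int] = (700, 731)) -> pd.DataFrame:
    """Actionable-time-window selection plus per-subject trend correlations.

    Keeps subjects with >= ``min_visits`` healthy visits whose first-to-last
    span lies in ``span_days`` (inclusive; the upper bound reads "2 years"
    as <= 731 days), then reports Spearman rho/p of protein level against
    visit day for each kept subject and protein.
    """
    cfg = cfg or AnalysisConfig()
    if "healthy" not in visit_meta.columns:
        visit_meta = visit_meta.assign(healthy=True)
    rows = []
    for subj, sub in visit_meta.groupby("subject_id"):
        healthy = sub[sub["healthy"].astype(bool)]
        if len(healthy) < min_visits:
            continue
        days = healthy["visit_day"].astype(int)
        span = int(days.max() - days.min())
        if not span_days[0] <= span <= span_days[1]:
            continue
        ordered = healthy.loc[days.sort_values(kind="stable").index]
        cols = [s for s in ordered.index if s in visits.sample_ids]
        dvec = ordered.loc[cols, "visit_day"].astype(float).to_numpy()
        for f in visits.feature_ids:
            lev = visits.values.loc[f, cols].to_numpy(dtype=float)
            ok = ~np.isnan(lev)
            if ok.sum() < 3:
                continue
            rho, p = spearman(lev[ok], dvec[ok])
            rows.append((subj, f, len(cols), span, rho, p))
    return pd.DataFrame(rows, columns=["subject_id", "protein_id", "n_visits",
                                       "span_days", "rho", "p"])
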
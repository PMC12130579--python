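"""Acceptance filters, QC, imputation, normalisation and PCA.

Filter bounds follow the printed rules exactly: peptides are kept when
FDR <= 1%, length >= 7, |mass error| <= 20 ppm and score >= 40 (all
inclusive); a protein needs >= 2 distinct kept unique peptides; metabolite
features are removed when present in < 80% of biological samples (strict)
or when the QC coefficient of variation is >= 0.3 (inclusive removal).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA

from .core import FeatureMatrix, log_stage

EVIDENCE_COLUMNS = ("peptide_id", "protein_id", "length", "fdr",
                    "mass_error_ppm", "score", "unique")


def filter_peptides(table: pd.DataFrame, *, fdr_max: float = 0.01,
                    min_length: int = 7, ppm_max: float = 20.0,
                    min_score: float = 40.0,
                    min_unique_peptides: int = 2) -> tuple[pd.DataFrame, list[str]]:
    """Apply the four peptide acceptance filters and derive the protein list.

    Returns the kept rows and the proteins supported by at least
    ``min_unique_peptides`` distinct kept unique peptides.
    """
    if table.empty:
        raise ValueError("peptide table is empty")
    missing = [c for c in EVIDENCE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"peptide table missing columns: {missing}")
    keep = ((table["fdr"] <= fdr_max)
            & (table["length"] >= min_length)
            & (table["mass_error_ppm"].abs() <= ppm_max)
            & (table["score"] >= min_score))
    kept = table[keep].copy()
    uniq = kept[kept["unique"].astype(bool)]
    counts = uniq.groupby("protein_id")["peptide_id"].nunique()
    proteins = sorted(counts.index[counts >= min_unique_peptides])
    log_stage("filter_peptides", n_in=len(table), n_kept=len(kept),
              n_proteins=len(proteins))
    return kept, proteins


def qc_filter(matrix: FeatureMatrix, meta: pd.DataFrame, *,
              presence_min: float = 0.80,
              cv_max: float = 0.30) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Presence/CV feature filter with a per-feature QC report.

    Presence is the fraction of biological samples with a non-missing value
    (drop when < ``presence_min``).  CV = sd/mean over QC samples on the
    linear scale (drop when >= ``cv_max``); a zero QC mean flags the feature
    as removed with reason ``undefined CV``.
    """
    samples = [s for s in matrix.sample_ids if s in meta.index]
    roles = meta.loc[samples, "role"]
    bio = [s for s in samples if roles[s] == "biological"]
    qc = [s for s in samples if roles[s] == "qc"]
    if not bio:
        raise ValueError("no biological samples in matrix")
    vals = matrix.values
    presence = vals[bio].notna().mean(axis=1)

    qc_cv = pd.Series(np.nan, index=vals.index)
    undefined = pd.Series(False, index=vals.index)
    if len(qc) >= 2:
        qvals = vals[qc]
        mean = qvals.mean(axis=1)
        sd = qvals.std(axis=1, ddof=1)
        zero = mean == 0
        undefined = zero & qvals.notna().any(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            qc_cv = sd / mean
        qc_cv[zero] = np.nan

    reasons = []
    kept = []
    for f in vals.index:
        reason = ""
        ok = True
        if presence[f] < presence_min:
            ok, reason = False, f"presence {presence[f]:.3f} < {presence_min}"
        elif undefined[f]:
            ok, reason = False, "undefined CV"
        elif np.isfinite(qc_cv[f]) and qc_cv[f] >= cv_max:
            ok, reason = False, f"qc CV {qc_cv[f]:.3f} >= {cv_max}"
        kept.append(ok)
        reasons.append(reason)
    report = pd.DataFrame({
        "feature_id": vals.index, "qc_cv": qc_cv.to_numpy(),
        "presence_frac": presence.to_numpy(), "kept": kept, "reason": reasons})
    out = matrix.copy(values=vals.loc[np.array(kept)])
    log_stage("qc_filter", n_in=len(vals), n_kept=int(np.sum(kept)))
    return out, report.reset_index(drop=True)


def knn_impute(matrix: FeatureMatrix, k: int = 10) -> FeatureMatrix:
    """Impute missing cells from the k nearest features (rows).

    Distances are Euclidean over mutually observed, per-feature standardised
    columns; the imputed value is the 1/distance-weighted mean of the
    neighbours' observed values at the missing sample.  ``k`` is clamped to
    the available neighbour count with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    vals = matrix.values.to_numpy(dtype=float)
    n_feat, n_samp = vals.shape
    fully_missing = np.isnan(vals).all(axis=1)
    if fully_missing.any():
        bad = matrix.values.index[fully_missing][0]
        raise ValueError(f"feature {bad!r} has no observed values")
    if k > n_feat - 1:
        warnings.warn(f"k={k} exceeds available neighbours; clamped to {n_feat - 1}")
        k = n_feat - 1

    mu = np.nanmean(vals, axis=1, keepdims=True)
    sd = np.nanstd(vals, axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (vals - mu) / sd
    obs = ~np.isnan(vals)
    out = vals.copy()
    missing_rows = np.where(~obs.all(axis=1))[0]
    for i in missing_rows:
        shared = obs & obs[i]                      # mutually observed columns
        n_shared = shared.sum(axis=1)
        diff = np.where(shared, z - z[i], 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.sqrt((diff ** 2).sum(axis=1) / n_shared)
        dist[i] = np.inf
        dist[n_shared == 0] = np.inf
        for j in np.where(~obs[i])[0]:
            cand = np.where(obs[:, j] & np.isfinite(dist))[0]
            if cand.size == 0:
                continue
            nearest = cand[np.argsort(dist[cand], kind="stable")[:k]]
            w = 1.0 / np.maximum(dist[nearest], 1e-12)
            out[i, j] = float(np.average(vals[nearest, j], weights=w))
    frame = pd.DataFrame(out, index=matrix.values.index,
                         columns=matrix.values.columns)
    log_stage("knn_impute", k=k, n_missing=int((~obs).sum()))
    return matrix.copy(values=frame)


def normalize_log(matrix: FeatureMatrix) -> FeatureMatrix:
    """log2 transform then per-sample median centring (linear input)."""
    vals = matrix.values
    bad = (vals <= 0)
    if bad.any().any():
        cells = [(f, s) for f, s in zip(*np.where(bad.to_numpy()))][:5]
        named = [(vals.index[f], vals.columns[s]) for f, s in cells]
        raise ValueError(f"non-positive values, e.g. {named}")
    logged = np.log2(vals)
    centred = logged - logged.median(axis=0)
    return matrix.copy(values=centred, scale_tag="log_intensity")


def pca(matrix: FeatureMatrix, n_components: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature-centred PCA of samples; deterministic sign convention.

    Returns per-sample scores and explained-variance fractions.  The sign of
    each component is fixed so its largest-magnitude feature loading is
    positive.
    """
    vals = matrix.values
    if vals.isna().any().any():
        raise ValueError("matrix has missing values; impute first")
    X = vals.to_numpy(dtype=float).T          # samples x features
    rank = min(X.shape[0] - 1 if X.shape[0] > 1 else 1, X.shape[1])
    if n_components > rank:
        raise ValueError(f"n_components {n_components} exceeds rank {rank}")
    model = _SKPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    for c in range(n_components):
        load = model.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, c] *= -1
    frame = pd.DataFrame(scores, index=vals.columns,
                         columns=[f"PC{i + 1}" for i in range(n_components)])
    return frame, model.explained_variance_ratio_[:n_components]
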
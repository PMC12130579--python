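"""Read-quality filtering, diversity, ordination, LDA effect size, KO/pathway
aggregation and Procrustes concordance for the metagenomic stage.

The LDA effect-size stage mirrors the LEfSe recipe for a two-class design:
per-sample abundances scaled to 1e6, a Kruskal-Wallis screen at p < 0.05,
then 30 bootstrap rounds of a regularised Fisher discriminant whose
per-feature effect combines the discriminant loading and the raw class-mean
difference; the reported score is log10 of the mean effect, thresholded at
3.0.  The two-group design makes the subclass (Wilcoxon) stage degenerate,
so it is omitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial import procrustes as _sp_procrustes
from scipy.spatial.distance import pdist, squareform
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .core import AGED, YOUNG, AnalysisConfig, FeatureMatrix, log_stage


# ---------------------------------------------------------------------------
# Read filtering


@dataclass
class ReadRecord:
    id: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"read {self.id!r}: sequence/quality length mismatch")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Parse a 4-line Phred+33 FASTQ file into ReadRecords."""
    from Bio import SeqIO
    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        records.append(ReadRecord(rec.id, str(rec.seq),
                                  list(rec.letter_annotations["phred_quality"])))
    return records


def filter_reads(reads, *, window: int = 4, q_min: int = 20,
                 min_length: int = 100, max_n_frac: float = 0.05
                 ) -> tuple[list[ReadRecord], dict]:
    """Sliding-window quality trim plus length and N-content filters.

    Reads are truncated at the first window (default size 4) whose mean
    quality falls below ``q_min``; reads shorter than ``min_length`` after
    trimming, or with an N fraction strictly above ``max_n_frac``, are
    dropped.  Returns the kept reads and kept/trimmed/dropped counts.
    """
    kept, stats = [], {"input": 0, "kept": 0, "trimmed": 0, "dropped": 0}
    for rec in reads:
        stats["input"] += 1
        q = rec.qualities
        cut = len(q)
        for start in range(0, max(len(q) - window + 1, 1)):
            win = q[start:start + window]
            if win and sum(win) / len(win) < q_min:
                cut = start
                break
        seq = rec.sequence[:cut]
        trimmed = cut < len(rec.sequence)
        if len(seq) < min_length:
            stats["dropped"] += 1
            continue
        n_frac = seq.upper().count("N") / len(seq)
        if n_frac > max_n_frac:
            stats["dropped"] += 1
            continue
        if trimmed:
            stats["trimmed"] += 1
        stats["kept"] += 1
        kept.append(ReadRecord(rec.id, seq, q[:cut]))
    log_stage("filter_reads", **stats)
    return kept, stats


# ---------------------------------------------------------------------------
# Diversity


def diversity(counts: FeatureMatrix) -> pd.DataFrame:
    """Shannon H' (nats) and bias-corrected Chao1 per sample.

    Chao1 = S_obs + F1(F1-1)/(2(F2+1)) with F1/F2 the singleton/doubleton
    counts; the bias-corrected form is used unconditionally so F2 = 0 is
    well defined.
    """
    if counts.scale_tag != "count":
        raise ValueError("diversity expects a count matrix")
    rows = []
    for s in counts.sample_ids:
        c = counts.values[s].to_numpy(dtype=float)
        c = np.nan_to_num(c)
        total = c.sum()
        if total <= 0:
            raise ValueError(f"sample {s!r} has no counts")
        p = c[c > 0] / total
        h = float(-(p * np.log(p)).sum())
        ci = np.round(c[c > 0]).astype(int)
        s_obs = int(ci.size)
        f1 = int((ci == 1).sum())
        f2 = int((ci == 2).sum())
        rows.append((s, h, float(_skbio_chao1(np.round(c).astype(int),
                                              bias_corrected=True)),
                     s_obs, f1, f2))
    return pd.DataFrame(rows, columns=["sample_id", "shannon", "chao1",
                                       "s_obs", "f1", "f2"])


def to_relative(counts: FeatureMatrix) -> FeatureMatrix:
    """Close a count matrix to per-sample relative abundances."""
    vals = counts.values
    rel = vals / vals.sum(axis=0)
    return FeatureMatrix(rel, "relative_abundance")


def bray_curtis(matrix: FeatureMatrix) -> pd.DataFrame:
    """Sample x sample Bray-Curtis dissimilarity on relative abundances."""
    m = to_relative(matrix) if matrix.scale_tag == "count" else matrix
    X = m.values.to_numpy(dtype=float).T
    D = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(D, index=m.sample_ids, columns=m.sample_ids)


def pcoa(d: pd.DataFrame, k: int) -> tuple[pd.DataFrame, np.ndarray, float]:
    """Principal coordinates of a dissimilarity matrix (Gower centring).

    Returns (coordinates for the first k positive axes, positive
    eigenvalues, negative-inertia fraction).  ``k`` beyond the positive
    eigenvalue count is an error.
    """
    if not np.allclose(d.to_numpy(), d.to_numpy().T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    res = _skbio_pcoa(DistanceMatrix(d.to_numpy(), ids=list(d.index)),
                      method="eigh")
    eig = res.eigvals.to_numpy()
    pos = eig[eig > 1e-10]
    if k > pos.size:
        raise ValueError(f"k={k} exceeds {pos.size} positive eigenvalues")
    neg_frac = float(-eig[eig < 0].sum() / np.abs(eig).sum()) if (eig < 0).any() else 0.0
    coords = res.samples.iloc[:, :k]
    coords.index = d.index
    return coords, pos[:k], neg_frac


# ---------------------------------------------------------------------------
# LDA effect size


def lda_effect_size(counts: FeatureMatrix, meta: pd.DataFrame,
                    cfg: AnalysisConfig | None = None, seed: int = 0, *,
                    n_boot: int = 30) -> pd.DataFrame:
    """LEfSe-style per-feature effect sizes between young and aged samples."""
    cfg = cfg or AnalysisConfig()
    rng = np.random.default_rng(seed)
    samples = [s for s in counts.sample_ids if s in meta.index]
    grp = meta.loc[samples, "age_group"]
    young = [s for s in samples if grp[s] == YOUNG]
    aged = [s for s in samples if grp[s] == AGED]
    if len(young) < 3 or len(aged) < 3:
        raise ValueError("each class needs at least 3 samples")
    vals = counts.values[samples].to_numpy(dtype=float)
    vals = vals / vals.sum(axis=0) * 1e6          # per-sample scaling to 1e6
    frame = pd.DataFrame(vals, index=counts.feature_ids, columns=samples)

    yi = [samples.index(s) for s in young]
    ai = [samples.index(s) for s in aged]
    kw_p = np.ones(len(frame))
    for i in range(len(frame)):
        y, a = vals[i, yi], vals[i, ai]
        if np.ptp(np.concatenate([y, a])) == 0:
            kw_p[i] = 1.0
        else:
            kw_p[i] = sps.kruskal(y, a).pvalue
    surviving = np.where(kw_p < 0.05)[0]
    scores = np.zeros(len(frame))
    if surviving.size:
        X = vals[surviving]
        effects = np.zeros((n_boot, surviving.size))
        n_y = math.ceil(2 * len(yi) / 3)
        n_a = math.ceil(2 * len(ai) / 3)
        for b in range(n_boot):
            sy = rng.choice(yi, size=n_y, replace=False)
            sa = rng.choice(ai, size=n_a, replace=False)
            mu_y = X[:, sy].mean(axis=1)
            mu_a = X[:, sa].mean(axis=1)
            delta = mu_a - mu_y
            centred = np.concatenate([X[:, sy] - mu_y[:, None],
                                      X[:, sa] - mu_a[:, None]], axis=1)
            Sw = centred @ centred.T / max(centred.shape[1] - 2, 1)
            lam = 0.1 * np.trace(Sw) / Sw.shape[0] + 1e-12
            w = np.linalg.solve(Sw + lam * np.eye(Sw.shape[0]), delta)
            w = w / (np.linalg.norm(w) + 1e-30)
            d_proj = float(w @ delta)
            effects[b] = 0.5 * (np.abs(w * d_proj) + np.abs(delta))
        mean_eff = effects.mean(axis=0)
        scores[surviving] = np.log10(np.maximum(mean_eff, 1.0))

    mu_y_all = vals[:, yi].mean(axis=1)
    mu_a_all = vals[:, ai].mean(axis=1)
    out = pd.DataFrame({
        "feature_id": frame.index,
        "class_enriched": np.where(mu_a_all >= mu_y_all, AGED, YOUNG),
        "kw_p": kw_p,
        "lda_score": scores,
    })
    out["passed"] = (out["kw_p"] < cfg.alpha) & (out["lda_score"] > cfg.lda_cutoff)
    log_stage("lda_effect_size", n_pass=int(out["passed"].sum()))
    return out


# ---------------------------------------------------------------------------
# KO / pathway aggregation


def ko_aggregate(gene_counts: FeatureMatrix, gene_lengths: pd.Series,
                 gene2ko: pd.Series, ko2pathway: pd.Series | None = None
                 ) -> tuple[FeatureMatrix, FeatureMatrix | None]:
    """TPM per gene, summed into KO abundances and optionally pathways.

    TPM_g = 1e6 * (c_g/l_g) / sum_h(c_h/l_h) per sample; genes without a KO
    contribute to the denominator only.
    """
    lengths = gene_lengths.reindex(gene_counts.feature_ids)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    rate = gene_counts.values.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    if (denom <= 0).any():
        bad = denom.index[denom <= 0][0]
        raise ValueError(f"sample {bad!r} has zero total rate")
    tpm = rate / denom * 1e6
    mapping = gene2ko.reindex(gene_counts.feature_ids).fillna("")
    ko_tpm = tpm[mapping != ""].groupby(mapping[mapping != ""]).sum()
    ko_m = FeatureMatrix(ko_tpm, "tpm")
    path_m = None
    if ko2pathway is not None:
        pmap = ko2pathway.reindex(ko_tpm.index).fillna("")
        path = ko_tpm[pmap != ""].groupby(pmap[pmap != ""]).sum()
        path_m = FeatureMatrix(path, "tpm")
    return ko_m, path_m


# ---------------------------------------------------------------------------
# Procrustes


@dataclass
class ProcrustesResult:
    m2: float
    p: float
    n_perm: int


def procrustes(x: pd.DataFrame | np.ndarray, y: pd.DataFrame | np.ndarray,
               n_perm: int = 999, seed: int = 0) -> ProcrustesResult:
    """Procrustes m2 between two ordinations plus a permutation p-value.

    Both configurations are centred and unit-normed; the optimal
    rotation/scaling comes from the SVD of the cross-product, giving
    m2 = 1 - (sum of singular values)^2 in [0, 1].  p is the plus-one
    corrected fraction of row permutations of y with m2 <= observed.
    """
    X = np.asarray(x, dtype=float)
    Y = np.asarray(y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("configurations must share samples in the same order")
    _, _, m2 = _sp_procrustes(X, Y)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(Y.shape[0])
        _, _, m2p = _sp_procrustes(X, Y[perm])
        if m2p <= m2 + 1e-15:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return ProcrustesResult(m2=float(m2), p=float(p), n_perm=n_perm)
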
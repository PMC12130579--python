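"""Organ communities, k-means expression modules, weighted co-expression
modules with eigenfeatures, cross-omics module correlation and thresholded
correlation networks.

The co-expression core follows the weighted-network recipe: unsigned
adjacency a_ij = |cor_ij|^beta with beta chosen as the smallest power whose
scale-free topology fit R^2 reaches the target (0.90); topological overlap
smooths the adjacency by shared neighbours; modules come from average-linkage
clustering of 1 - TOM with a static cut that descends from 99% of the tallest
merge until at least two modules of the minimum size (30) emerge.  Module
eigenfeatures (MEs) are the first principal component of the standardised
module submatrix, oriented to correlate positively with the module mean
profile, and module labels (PM1..., MM1...) descend by size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .core import AGED, YOUNG, AnalysisConfig, FeatureMatrix, log_stage
from .stats import (bh_adjust, correlation_t_pvalue, fisher_z_pvalue, spearman,
                    spearman_matrix)

# ---------------------------------------------------------------------------
# Organ communities


def tissue_mean_profiles(matrices: dict[str, FeatureMatrix],
                         samples: list[str] | None = None) -> pd.DataFrame:
    """Features x tissues frame of per-tissue mean profiles."""
    cols = {}
    for t, m in matrices.items():
        vals = m.values if samples is None else m.values[
            [s for s in m.sample_ids if s in samples]]
        cols[t] = vals.mean(axis=1)
    return pd.DataFrame(cols)


def organ_communities(matrices: dict[str, FeatureMatrix],
                      cfg: AnalysisConfig | None = None
                      ) -> tuple[list[list[str]], dict[int, list[str]], pd.DataFrame]:
    """Connected components of the tissue graph with Spearman > community_rho.

    Edges require rho strictly greater than the cutoff ("greater than 0.60").
    Returns the communities (size >= 2, sorted), each community's co-expressed
    feature set (features detected in all member tissues) and the tissue
    correlation matrix.
    """
    if len(matrices) < 3:
        raise ValueError("need at least 3 tissues")
    cfg = cfg or AnalysisConfig()
    tissues = sorted(matrices)
    profiles = tissue_mean_profiles({t: matrices[t] for t in tissues})
    corr = pd.DataFrame(np.eye(len(tissues)), index=tissues, columns=tissues)
    for i, a in enumerate(tissues):
        for b in tissues[i + 1:]:
            both = profiles[[a, b]].dropna()
            rho, _ = spearman(both[a].to_numpy(), both[b].to_numpy())
            corr.loc[a, b] = corr.loc[b, a] = rho

    adj = {t: set() for t in tissues}
    for i, a in enumerate(tissues):
        for b in tissues[i + 1:]:
            # strict "greater than": guard against float noise at the cutoff
            if corr.loc[a, b] > cfg.community_rho + 1e-12:
                adj[a].add(b)
                adj[b].add(a)
    seen: set[str] = set()
    communities: list[list[str]] = []
    for t in tissues:
        if t in seen:
            continue
        stack, comp = [t], []
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            comp.append(u)
            stack.extend(adj[u] - seen)
        if len(comp) >= 2:
            communities.append(sorted(comp))
    communities.sort()
    coexpr = {}
    for ci, comp in enumerate(communities):
        detected = None
        for t in comp:
            feats = set(matrices[t].values.dropna(how="all").index)
            detected = feats if detected is None else detected & feats
        coexpr[ci] = sorted(detected or [])
    log_stage("organ_communities", n_communities=len(communities))
    return communities, coexpr, corr


def kmeans_modules(matrix: pd.DataFrame, k: int, seed: int,
                   aged_cols: list[str] | None = None,
                   young_cols: list[str] | None = None) -> pd.Series:
    """k-means modules of row-z-scored features; labels ordered by age delta.

    Modules are relabelled 1..k so that modules whose mean aged-minus-young
    delta is most negative (reduced with age) come first.  Same seed, same
    assignment.
    """
    if k > len(matrix):
        raise ValueError("k exceeds feature count")
    X = matrix.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    km = KMeans(n_clusters=k, init="k-means++", n_init=50, random_state=seed)
    raw = km.fit_predict(Z)
    if aged_cols and young_cols:
        zf = pd.DataFrame(Z, index=matrix.index, columns=matrix.columns)
        delta = zf[aged_cols].mean(axis=1) - zf[young_cols].mean(axis=1)
        order = sorted(range(k), key=lambda c: float(delta[raw == c].mean()))
    else:
        order = sorted(range(k))
    remap = {old: new + 1 for new, old in enumerate(order)}
    return pd.Series([remap[c] for c in raw], index=matrix.index, name="module")


# ---------------------------------------------------------------------------
# Soft threshold and module detection


@dataclass
class SoftThresholdScan:
    powers: list[int]
    fit_index: list[float]
    mean_connectivity: list[float]
    chosen_beta: int
    reached_target: bool


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Scale-free topology fit: R^2 of log10 p(k) on log10 mean k, 10 bins.

    Connectivities are discretised into equal-width bins (equal-count bins
    would make the frequency response constant by construction); empty bins
    are dropped.  Returns 0 when the fitted slope is non-negative.
    """
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    xs, ys = np.array(xs), np.array(ys)
    if np.unique(xs).size < 2:
        return 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * xs + intercept
    ss_res = ((ys - pred) ** 2).sum()
    ss_tot = ((ys - ys.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(r2) if slope < 0 else 0.0


def adjacency(matrix: FeatureMatrix | pd.DataFrame, beta: float,
              method: str = "pearson") -> np.ndarray:
    """Unsigned weighted adjacency |cor|^beta with zero diagonal."""
    vals = matrix.values if isinstance(matrix, FeatureMatrix) else matrix
    X = vals.to_numpy(dtype=float)
    if method == "spearman":
        from scipy.stats import rankdata
        X = np.apply_along_axis(rankdata, 1, X)
    C = np.corrcoef(X)
    A = np.abs(np.clip(C, -1, 1)) ** beta
    np.fill_diagonal(A, 0.0)
    return A


def pick_soft_threshold(matrix: FeatureMatrix | pd.DataFrame,
                        powers=None,
                        cfg: AnalysisConfig | None = None) -> SoftThresholdScan:
    """Scan candidate powers and choose the smallest with fit R^2 >= target.

    Constant features are excluded with a warning before correlation.
    """
    cfg = cfg or AnalysisConfig()
    powers = list(powers if powers is not None else cfg.wgcna_powers)
    vals = matrix.values if isinstance(matrix, FeatureMatrix) else matrix
    sd = vals.std(axis=1)
    const = sd <= 1e-12 * vals.abs().mean(axis=1).clip(lower=1.0)
    if const.any():
        import warnings
        warnings.warn(f"excluding {int(const.sum())} constant features")
        vals = vals.loc[~const]
    C = np.corrcoef(vals.to_numpy(dtype=float))
    C = np.abs(np.clip(C, -1, 1))
    np.fill_diagonal(C, 0.0)
    fits, ks = [], []
    for b in powers:
        A = C ** b
        k = A.sum(axis=1)
        fits.append(_scale_free_fit(k))
        ks.append(float(k.mean()))
    reached = [b for b, f in zip(powers, fits) if f >= cfg.wgcna_r2_target]
    if reached:
        chosen, ok = reached[0], True
    else:
        chosen, ok = powers[int(np.argmax(fits))], False
    return SoftThresholdScan(powers=powers, fit_index=fits,
                             mean_connectivity=ks, chosen_beta=chosen,
                             reached_target=ok)


def topological_overlap(A: np.ndarray) -> np.ndarray:
    """Unsigned TOM: w_ij = (sum_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1-a_ij)."""
    k = A.sum(axis=1)
    L = A @ A
    kmin = np.minimum.outer(k, k)
    W = (L + A) / (kmin + 1.0 - A)
    np.fill_diagonal(W, 1.0)
    return W


@dataclass
class ModuleSet:
    """Feature -> module assignment (0 = unassigned) with MEs and labels."""

    omics_tag: str                      # "PM" or "MM"
    assignment: pd.Series               # feature -> module index
    labels: dict = field(default_factory=dict)   # index -> "PM1"...
    eigenfeatures: pd.DataFrame | None = None    # samples x modules (ME)
    tom: np.ndarray | None = None

    @property
    def module_sizes(self) -> pd.Series:
        counts = self.assignment[self.assignment > 0].value_counts()
        return counts.sort_index()


def module_eigenfeature(sub: pd.DataFrame) -> pd.Series:
    """First PC of the standardised module submatrix, oriented positively.

    Returned with unit variance; its correlation with the module mean
    profile is positive by convention.
    """
    X = sub.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    me = vt[0]
    mean_profile = Z.mean(axis=0)
    if np.corrcoef(me, mean_profile)[0, 1] < 0:
        me = -me
    me = me / me.std()
    return pd.Series(me, index=sub.columns)


def detect_modules(matrix: FeatureMatrix | pd.DataFrame, beta: float,
                   cfg: AnalysisConfig | None = None, omics_tag: str = "PM",
                   keep_tom: bool = False) -> ModuleSet:
    """TOM-based average-linkage modules with a static descending cut.

    The dendrogram of 1 - TOM is cut at a height fraction h of the tallest
    merge, starting at 0.99 and descending by 0.01 (floor 0.90) until at
    least two clusters of size >= wgcna_min_module exist.  Sub-minimum
    clusters go to module 0; surviving modules are labelled by descending
    size.
    """
    cfg = cfg or AnalysisConfig()
    vals = matrix.values if isinstance(matrix, FeatureMatrix) else matrix
    features = list(vals.index)
    if len(features) < cfg.wgcna_min_module:
        import warnings
        warnings.warn("fewer features than the minimum module size; all unassigned")
        assignment = pd.Series(0, index=features, name="module")
        return ModuleSet(omics_tag=omics_tag, assignment=assignment)
    A = adjacency(vals, beta)
    W = topological_overlap(A)
    D = 1.0 - W
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2
    Z = linkage(squareform(D, checks=False), method="average")
    hmax = Z[:, 2].max()
    chosen_labels = None
    h = 0.99
    best = (None, -1)
    while h >= 0.90 - 1e-9:
        lab = fcluster(Z, t=h * hmax, criterion="distance")
        sizes = pd.Series(lab).value_counts()
        n_mod = int((sizes >= cfg.wgcna_min_module).sum())
        if n_mod > best[1]:
            best = (lab, n_mod)
        if n_mod >= 2:
            chosen_labels = lab
            break
        h -= 0.01
    if chosen_labels is None:
        chosen_labels = best[0]
    lab = pd.Series(chosen_labels, index=features)
    sizes = lab.value_counts()
    keepers = sizes.index[sizes >= cfg.wgcna_min_module]
    ordered = sorted(keepers, key=lambda c: (-sizes[c], c))
    remap = {c: i + 1 for i, c in enumerate(ordered)}
    assignment = lab.map(lambda c: remap.get(c, 0)).rename("module")

    labels = {idx: f"{omics_tag}{idx}" for idx in sorted(set(remap.values()))}
    mes = {}
    frame = vals if isinstance(vals, pd.DataFrame) else pd.DataFrame(vals)
    for idx in sorted(set(remap.values())):
        sub = frame.loc[assignment.index[assignment == idx]]
        mes[labels[idx]] = module_eigenfeature(sub)
    eig = pd.DataFrame(mes) if mes else None
    log_stage("detect_modules", omics=omics_tag, beta=beta,
              n_modules=len(labels),
              sizes=[int(sizes[c]) for c in ordered])
    return ModuleSet(omics_tag=omics_tag, assignment=assignment, labels=labels,
                     eigenfeatures=eig, tom=W if keep_tom else None)


# ---------------------------------------------------------------------------
# Cross-omics module correlation and correlation networks


def me_cross_correlate(pm: ModuleSet, mm: ModuleSet, meta: pd.DataFrame,
                       p_method: str = "t") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman correlation of every PM ME with every MM ME on shared samples.

    p-values come from the t transform of the correlation (Fisher z mode
    selectable); q is BH over all pairs.  Also returns per-module young/aged
    ME differences (two-sided t-test) for modules of both omics.
    """
    from scipy import stats as sps
    if pm.eigenfeatures is None or mm.eigenfeatures is None:
        raise ValueError("both module sets need eigenfeatures")
    shared = [s for s in pm.eigenfeatures.index if s in mm.eigenfeatures.index]
    if len(shared) < 4:
        raise ValueError("fewer than 4 shared samples")
    rows = []
    n = len(shared)
    pfun = correlation_t_pvalue if p_method == "t" else fisher_z_pvalue
    for a in pm.eigenfeatures.columns:
        for b in mm.eigenfeatures.columns:
            x = pm.eigenfeatures.loc[shared, a].to_numpy()
            y = mm.eigenfeatures.loc[shared, b].to_numpy()
            rho, _ = spearman(x, y)
            p = pfun(rho, n) if np.isfinite(rho) else np.nan
            rows.append((a, b, rho, p))
    edges = pd.DataFrame(rows, columns=["a_id", "b_id", "rho", "p"])
    edges["q"] = bh_adjust(edges["p"])
    edges["context"] = "me_cross_omics"

    diff_rows = []
    for mset in (pm, mm):
        eig = mset.eigenfeatures
        grp = meta.loc[[s for s in eig.index if s in meta.index], "age_group"]
        young = [s for s in grp.index if grp[s] == YOUNG]
        aged = [s for s in grp.index if grp[s] == AGED]
        for mod in eig.columns:
            if len(young) >= 2 and len(aged) >= 2:
                res = sps.ttest_ind(eig.loc[aged, mod], eig.loc[young, mod])
                diff_rows.append((mod, float(eig.loc[aged, mod].mean()
                                             - eig.loc[young, mod].mean()),
                                  float(res.statistic), float(res.pvalue)))
    diffs = pd.DataFrame(diff_rows, columns=["module", "delta", "stat", "p"])
    return edges, diffs


def tissue_coupling(metabolome: dict[str, FeatureMatrix], meta: pd.DataFrame
                    ) -> dict[str, pd.DataFrame]:
    """Per-group tissue x tissue Spearman of mean metabolite profiles."""
    out = {}
    tissues = sorted(metabolome)
    for group in (YOUNG, AGED):
        mat = pd.DataFrame(np.eye(len(tissues)), index=tissues, columns=tissues)
        profiles = {}
        for t in tissues:
            m = metabolome[t]
            cols = [s for s in m.sample_ids
                    if s in meta.index and meta.loc[s, "age_group"] == group]
            profiles[t] = m.values[cols].mean(axis=1)
        for i, a in enumerate(tissues):
            for b in tissues[i + 1:]:
                both = pd.DataFrame({"a": profiles[a], "b": profiles[b]}).dropna()
                if both.empty:
                    import warnings
                    warnings.warn(f"no shared metabolites for {a}/{b}")
                    rho = np.nan
                else:
                    rho, _ = spearman(both["a"].to_numpy(), both["b"].to_numpy())
                mat.loc[a, b] = mat.loc[b, a] = rho
        out[group] = mat
    return out


def edge_network(a_matrix: FeatureMatrix, b_matrix: FeatureMatrix,
                 cfg: AnalysisConfig | None = None, context: str = "",
                 meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """All cross pairs with |Spearman rho| >= rho_cutoff and p < alpha.

    Samples are matched by shared sample id, or by subject id when ``meta``
    is given and the id sets are disjoint (e.g. fecal vs tissue samples of
    the same animals).  Self-comparison (a is b) skips identical ids.
    """
    cfg = cfg or AnalysisConfig()
    shared = [s for s in a_matrix.sample_ids if s in set(b_matrix.sample_ids)]
    if shared:
        acols, bcols = shared, shared
    elif meta is not None:
        subj_a = {meta.loc[s, "subject_id"]: s for s in a_matrix.sample_ids
                  if s in meta.index}
        pairs = [(subj_a[meta.loc[s, "subject_id"]], s)
                 for s in b_matrix.sample_ids
                 if s in meta.index and meta.loc[s, "subject_id"] in subj_a]
        if not pairs:
            raise ValueError("no shared samples or matched subjects")
        acols = [p for p, _ in pairs]
        bcols = [s for _, s in pairs]
    else:
        raise ValueError("no shared samples between the matrices")
    A = a_matrix.values[acols].to_numpy(dtype=float)
    B = b_matrix.values[bcols].to_numpy(dtype=float)
    same = a_matrix.values.equals(b_matrix.values)
    rho, p = spearman_matrix(A, B)
    rows = []
    a_ids, b_ids = a_matrix.feature_ids, b_matrix.feature_ids
    for i in range(rho.shape[0]):
        for j in range(rho.shape[1]):
            if same and j <= i:
                continue
            r = rho[i, j]
            if np.isfinite(r) and abs(r) >= cfg.rho_cutoff and p[i, j] < cfg.alpha:
                rows.append((a_ids[i], b_ids[j], float(r), float(p[i, j]),
                             context))
    edges = pd.DataFrame(rows, columns=["a_id", "b_id", "rho", "p", "context"])
    edges["q"] = bh_adjust(edges["p"]) if len(edges) else pd.Series(dtype=float)
    return edges
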
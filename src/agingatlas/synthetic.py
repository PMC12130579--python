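"""Synthetic multi-tissue, multi-omics aging study with planted ground truth.

The generator emulates a young-vs-aged mouse design: a proteome for each
tissue plus plasma, a per-tissue metabolome with superclass labels, fecal
shotgun-style taxa counts with a coupled KO/gene layer, a longitudinal plasma
series, and a toy peptide-evidence table.  Every planted effect (differential
features, tissue-universal up-features, tissue-specific proteins,
plasma-tissue coupled pairs, block-correlated co-expression modules,
differential and antagonistic taxa, taxa-metabolite couplings) is recorded in
a :class:`GroundTruth` object so downstream stages can be tested for recovery
without any external data.

Design notes
------------
* Null proteins share one cross-tissue baseline (drawn once per feature);
  tissue-level deviations come only from planted effects, which keeps the
  tissue-specificity truth unambiguous.
* Planted sets are mutually disjoint, and per-tissue differential sets are
  disjoint from the plasma differential set, so a recovered plasma-tissue
  pair is attributable to exactly one planted cause.
* Latent factors for coupled pairs live inside the ``noise_sd`` variance
  budget (loading a^2 = rho_P * noise_sd^2 with rho_P the Pearson equivalent
  of the target Spearman, rho_P = 2 sin(pi*rho_S/6)), so marginal noise and
  two-group test calibration are unchanged by the coupling.
* Module latent factors are i.i.d. per sample: within-module correlation is
  a^2/(a^2 + sigma^2) with a^2 = sigma^2 * rho_w/(1-rho_w).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (AGED, YOUNG, FeatureMatrix, make_sample_meta,
                   write_feature_matrix, write_sample_meta)

TISSUE_NAMES = ["brain", "liver", "heart", "kidney", "lung", "spleen",
                "thymus", "muscle", "colon", "skin", "testis", "pancreas",
                "bladder", "eye", "stomach", "cerebellum", "spinalcord",
                "smallintestine", "wat", "bat", "beige"]

METABOLITE_CLASSES = [
    "Lipids and lipid-like molecules",
    "Organic acids and derivatives",
    "Organoheterocyclic compounds",
    "Benzenoids",
    "Organic oxygen compounds",
    "Nucleosides, nucleotides, and analogues",
    "Alkaloids and derivatives",
    "Organosulfur compounds",
]


def spearman_to_pearson(rho_s: float) -> float:
    """Pearson rho of a bivariate normal with the given Spearman rho."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic generator."""

    n_tissues: int = 8
    n_per_group: int = 4          # mice per age group in the tissue cohort
    n_proteins: int = 1200
    n_metabolites: int = 800
    n_taxa: int = 120
    n_kos: int = 200
    frac_dep: float = 0.1         # planted differential fraction per tissue
    dep_log2fc: float = 1.5
    n_universal_up: int = 12      # immunoglobulin-like, up in every tissue
    n_specific_per_tissue: int = 15
    specific_shift: float = 6.0   # log2 elevation in the home tissue
    n_pairs: int = 20             # planted plasma-tissue coupled proteins
    pair_rho: float = 0.9         # target Spearman of the latent coupling
    pair_log2fc: float = 2.5      # age shift of pair proteins (strong markers)
    n_modules_per_omics: int = 3
    module_size: int = 60
    within_module_rho: float = 0.8
    n_diff_taxa: int = 10
    taxa_fold: float = 8.0
    antagonist_rho: float = -0.8
    depth: int = 100_000          # mean metagenome library size
    noise_sd: float = 0.4         # residual log2 noise, proteome/metabolome
    seed: int = 0
    # secondary design knobs
    n_enriched: int = 0           # dual-tissue enriched proteins (opt-in:
    enriched_shift: float = 0.32  # targeting the open (2.5,4) TS window needs
                                  # low noise, so the default study plants none)
    n_micro_per_group: int = 12   # fecal cohort size per age group
    taxa_noise_sd: float = 0.5    # log-scale taxon noise
    n_couplings: int = 4          # taxa->metabolite planted couplings
    couple_kappa: float = 2.0
    n_long_subjects: int = 6      # longitudinal subjects passing the window rule
    long_slope: float = 0.004     # log2 units per day for planted slopes
    baseline_mean: float = 20.0
    baseline_sd: float = 1.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name in ("antagonist_rho",):
                continue
            if isinstance(v, (int, float)) and v < 0:
                raise ValueError(f"{f.name} must be non-negative")
        if not 0 <= self.frac_dep < 1:
            raise ValueError("frac_dep must lie in [0, 1)")
        if self.n_modules_per_omics * self.module_size > min(
                self.n_proteins, self.n_metabolites):
            raise ValueError("module blocks exceed the feature count")
        need = (self.n_universal_up + self.n_tissues * self.n_specific_per_tissue
                + self.n_enriched + self.n_pairs
                + self.n_modules_per_omics * self.module_size)
        if need >= self.n_proteins:
            raise ValueError("planted proteome sets exceed n_proteins")


@dataclass
class GroundTruth:
    """Planted truth emitted alongside the synthetic study."""

    dep: dict = field(default_factory=dict)            # tissue -> {feature: dir}
    dem: dict = field(default_factory=dict)            # tissue -> {metabolite: dir}
    universal_up: list = field(default_factory=list)
    specific: dict = field(default_factory=dict)       # feature -> home tissue
    enriched: dict = field(default_factory=dict)       # feature -> [tissues]
    pairs: list = field(default_factory=list)          # (protein, tissue, sign)
    modules: dict = field(default_factory=dict)        # omics -> {feature: idx}
    diff_taxa: dict = field(default_factory=dict)      # taxon -> dir
    antagonist_pair: tuple = ((), ())                  # (up_set, down_set)
    ko_incidence: dict = field(default_factory=dict)   # ko -> [taxa]
    coupling_signs: list = field(default_factory=list)  # (taxon, metabolite, sign)
    class_truth: dict = field(default_factory=dict)    # tissue -> (up_cls, down_cls)
    long_slopes: dict = field(default_factory=dict)    # protein -> slope per day

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["antagonist_pair"] = [list(self.antagonist_pair[0]),
                                list(self.antagonist_pair[1])]
        d["pairs"] = [list(p) for p in self.pairs]
        d["coupling_signs"] = [list(c) for c in self.coupling_signs]
        d["class_truth"] = {t: list(v) for t, v in self.class_truth.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        d["antagonist_pair"] = tuple(tuple(x) for x in d["antagonist_pair"])
        d["pairs"] = [tuple(p) for p in d["pairs"]]
        d["coupling_signs"] = [tuple(c) for c in d["coupling_signs"]]
        d["class_truth"] = {t: tuple(v) for t, v in d["class_truth"].items()}
        return cls(**d)


#: Minimal structural schema for the truth JSON (field name -> container kind).
TRUTH_SCHEMA = {
    "dep": dict, "dem": dict, "universal_up": list, "specific": dict,
    "enriched": dict, "pairs": list, "modules": dict, "diff_taxa": dict,
    "antagonist_pair": list, "ko_incidence": dict, "coupling_signs": list,
    "class_truth": dict, "long_slopes": dict,
}


def validate_truth_dict(d: dict) -> None:
    """Structural check of a serialised GroundTruth against TRUTH_SCHEMA."""
    for key, kind in TRUTH_SCHEMA.items():
        if key not in d:
            raise ValueError(f"truth JSON missing key {key!r}")
        if not isinstance(d[key], kind):
            raise ValueError(f"truth key {key!r} must be {kind.__name__}")
    for entry in d["pairs"]:
        if len(entry) != 3 or entry[2] not in ("positive", "negative"):
            raise ValueError(f"malformed pair entry {entry!r}")
    if len(d["antagonist_pair"]) != 2:
        raise ValueError("antagonist_pair must hold two taxon lists")


@dataclass
class SyntheticStudy:
    """Container for all emitted tables, metadata and the planted truth."""

    proteome: dict                  # tissue (incl. 'plasma') -> FeatureMatrix
    metabolome: dict                # tissue -> FeatureMatrix
    metabolite_classes: pd.Series   # metabolite -> superclass label
    taxa_counts: FeatureMatrix
    gene_counts: FeatureMatrix
    gene_lengths: pd.Series
    gene2ko: pd.Series              # gene -> KO ('' for orphans)
    ko2pathway: pd.Series
    longitudinal: FeatureMatrix
    longitudinal_meta: pd.DataFrame  # sample_id-indexed: subject_id, visit_day, healthy
    evidence: pd.DataFrame
    gene_sets: dict                 # set name -> protein id list
    meta: pd.DataFrame
    truth: GroundTruth
    config: SimConfig


def _tissue_names(n: int) -> list[str]:
    names = list(TISSUE_NAMES[:n])
    while len(names) < n:
        names.append(f"tissue{len(names) + 1:02d}")
    return names


def generate_study(cfg: SimConfig) -> SyntheticStudy:
    """Generate the full synthetic study for one seed (bit-reproducible)."""
    rng = np.random.default_rng(cfg.seed)
    tissues = _tissue_names(cfg.n_tissues)
    subjects_young = [f"Y{i + 1:02d}" for i in range(cfg.n_micro_per_group)]
    subjects_aged = [f"A{i + 1:02d}" for i in range(cfg.n_micro_per_group)]
    cohort_young = subjects_young[:cfg.n_per_group]
    cohort_aged = subjects_aged[:cfg.n_per_group]
    cohort = cohort_young + cohort_aged
    groups = [YOUNG] * cfg.n_per_group + [AGED] * cfg.n_per_group

    proteins = [f"P{i + 1:04d}" for i in range(cfg.n_proteins)]
    metabolites = [f"M{i + 1:04d}" for i in range(cfg.n_metabolites)]
    taxa = [f"taxon_{i + 1:03d}" for i in range(cfg.n_taxa)]
    kos = [f"KO{i + 1:04d}" for i in range(cfg.n_kos)]

    truth = GroundTruth()
    meta_rows: list[dict] = []

    # ---------------- planted proteome sets (mutually disjoint) -------------
    pool = [str(x) for x in rng.permutation(proteins)]
    def take(k: int) -> list[str]:
        picked, rest = pool[:k], pool[k:]
        pool[:] = rest
        return picked

    truth.universal_up = sorted(take(cfg.n_universal_up))
    for t in tissues:
        for f in take(cfg.n_specific_per_tissue):
            truth.specific[f] = t
    for f in take(cfg.n_enriched):
        pair_t = [str(x) for x in rng.choice(tissues, size=2, replace=False)]
        truth.enriched[f] = sorted(pair_t)
    pair_proteins = take(cfg.n_pairs)
    for i, f in enumerate(pair_proteins):
        home = tissues[int(rng.integers(len(tissues)))]
        sign = "positive" if i % 2 == 0 else "negative"
        truth.pairs.append((f, home, sign))
    module_proteins = take(cfg.n_modules_per_omics * cfg.module_size)
    truth.modules["PM"] = {
        f: i // cfg.module_size + 1 for i, f in enumerate(module_proteins)}

    plasma_dep_pool = take(min(int(cfg.frac_dep * cfg.n_proteins), len(pool)))
    null_pool = list(pool)  # untouched by any age effect in any tissue

    # differential sets: plasma gets its own disjoint random set; each tissue
    # draws from the remaining nulls (tissue-to-tissue overlap allowed)
    dirs = np.array(["up", "down"])
    truth.dep["plasma"] = {f: "up" for f in truth.universal_up}
    for f in plasma_dep_pool:
        truth.dep["plasma"][f] = str(rng.choice(dirs))
    for f, _, _ in truth.pairs:
        truth.dep["plasma"][f] = "up"
    n_dep = int(cfg.frac_dep * cfg.n_proteins)
    for t in tissues:
        d = {f: "up" for f in truth.universal_up}
        chosen = rng.choice(len(null_pool), size=min(n_dep, len(null_pool)),
                            replace=False) if null_pool and n_dep else []
        for idx in chosen:
            d[null_pool[idx]] = str(rng.choice(dirs))
        truth.dep[t] = d
    for f, home, sign in truth.pairs:
        truth.dep[home][f] = "up" if sign == "positive" else "down"

    # ---------------- proteome values ---------------------------------------
    baseline = pd.Series(
        rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_proteins),
        index=proteins)
    rho_pair = spearman_to_pearson(cfg.pair_rho)
    a_pair = math.sqrt(rho_pair) * cfg.noise_sd
    resid_pair = math.sqrt(1.0 - rho_pair) * cfg.noise_sd
    a_mod = cfg.noise_sd * math.sqrt(
        cfg.within_module_rho / (1.0 - cfg.within_module_rho))
    z_subject = pd.Series(rng.normal(0, 1, len(cohort)), index=cohort)

    all_prot_tissues = tissues + ["plasma"]
    sample_ids = {t: [f"{t}_{s}" for s in cohort] for t in all_prot_tissues}
    # i.i.d. module factors per sample, shared across omics on shared samples
    factor_ids = [sid for t in all_prot_tissues for sid in sample_ids[t]]
    pm_factors = pd.DataFrame(
        rng.normal(0, 1, (cfg.n_modules_per_omics, len(factor_ids))),
        columns=factor_ids)

    pair_home = {f: (home, 1.0 if sign == "positive" else -1.0)
                 for f, home, sign in truth.pairs}
    prot_index = {f: i for i, f in enumerate(proteins)}
    aged_mask = np.array([g == AGED for g in groups])
    z_arr = z_subject.to_numpy()

    proteome: dict[str, FeatureMatrix] = {}
    for t in all_prot_tissues:
        cols = sample_ids[t]
        vals = np.tile(baseline.to_numpy()[:, None], (1, len(cols))).astype(float)
        noise = rng.normal(0, cfg.noise_sd, vals.shape)
        spec_rows = [prot_index[f] for f, home in truth.specific.items()
                     if home == t]
        vals[spec_rows] += cfg.specific_shift
        enr_rows = [prot_index[f] for f, ts in truth.enriched.items() if t in ts]
        vals[enr_rows] += cfg.enriched_shift
        for f, direction in truth.dep.get(t, {}).items():
            shift = cfg.pair_log2fc if f in pair_home else cfg.dep_log2fc
            vals[prot_index[f], aged_mask] += shift if direction == "up" else -shift
        for f, (home, sgn) in pair_home.items():
            if t == "plasma" or t == home:
                load = 1.0 if t == "plasma" else sgn
                fi = prot_index[f]
                vals[fi] += load * a_pair * z_arr
                noise[fi] = rng.normal(0, resid_pair, len(cols))
        fb = pm_factors[cols].to_numpy()
        mod_rows = np.array([prot_index[f] for f in truth.modules["PM"]])
        mod_idx = np.array([m - 1 for m in truth.modules["PM"].values()])
        if mod_rows.size:
            vals[mod_rows] += a_mod * fb[mod_idx]
        vals += noise
        proteome[t] = FeatureMatrix(
            pd.DataFrame(vals, index=proteins, columns=cols), "log_intensity")
        for s, g in zip(cohort, groups):
            meta_rows.append(dict(sample_id=f"{t}_{s}", tissue=t, age_group=g,
                                  subject_id=s, role="biological"))

    # ---------------- metabolome --------------------------------------------
    classes = pd.Series(
        [METABOLITE_CLASSES[int(i)] for i in rng.integers(
            0, len(METABOLITE_CLASSES), cfg.n_metabolites)],
        index=metabolites, name="superclass")
    mpool = [str(x) for x in rng.permutation(metabolites)]
    module_metabs = mpool[:cfg.n_modules_per_omics * cfg.module_size]
    truth.modules["MM"] = {
        f: i // cfg.module_size + 1 for i, f in enumerate(module_metabs)}
    m_baseline = pd.Series(
        rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_metabolites),
        index=metabolites)
    n_dem = int(cfg.frac_dep * cfg.n_metabolites)
    mm_factors = pm_factors  # shared latent factors couple PM and MM modules

    metabolome: dict[str, FeatureMatrix] = {}
    for ti, t in enumerate(tissues):
        cls_up = METABOLITE_CLASSES[ti % len(METABOLITE_CLASSES)]
        cls_down = METABOLITE_CLASSES[(ti + 1) % len(METABOLITE_CLASSES)]
        truth.class_truth[t] = (cls_up, cls_down)
        dem = {}
        for f in metabolites:
            if classes[f] == cls_up:
                dem[f] = "up"
            elif classes[f] == cls_down:
                dem[f] = "down"
        candidates = [f for f in metabolites if f not in dem]
        chosen = rng.choice(len(candidates), size=min(n_dem, len(candidates)),
                            replace=False)
        for idx in chosen:
            dem[candidates[idx]] = str(rng.choice(dirs))
        truth.dem[t] = dem

        cols = sample_ids[t]
        vals = np.tile(m_baseline.to_numpy()[:, None], (1, len(cols))).astype(float)
        metab_index = {f: i for i, f in enumerate(metabolites)}
        for f, direction in dem.items():
            vals[metab_index[f], aged_mask] += (
                cfg.dep_log2fc if direction == "up" else -cfg.dep_log2fc)
        fb = mm_factors[cols].to_numpy()
        mod_rows = np.array([metab_index[f] for f in truth.modules["MM"]])
        mod_idx = np.array([m - 1 for m in truth.modules["MM"].values()])
        if mod_rows.size:
            vals[mod_rows] += a_mod * fb[mod_idx]
        vals += rng.normal(0, cfg.noise_sd, vals.shape)
        metabolome[t] = FeatureMatrix(
            pd.DataFrame(vals, index=metabolites, columns=cols), "log_intensity")

    # ---------------- taxa ---------------------------------------------------
    micro_subjects = subjects_young + subjects_aged
    micro_groups = [YOUNG] * cfg.n_micro_per_group + [AGED] * cfg.n_micro_per_group
    fecal_ids = [f"feces_{s}" for s in micro_subjects]
    for s, g in zip(micro_subjects, micro_groups):
        meta_rows.append(dict(sample_id=f"feces_{s}", tissue="feces",
                              age_group=g, subject_id=s, role="biological"))

    base_log = rng.normal(0, 2, cfg.n_taxa)
    shares = np.exp(base_log) / np.exp(base_log).sum()
    order = np.argsort(shares)
    # plant in the upper-middle abundance band: the LDA effect-size scale
    # (per-sample sum 1e6) puts the printed cutoff 3.0 at an absolute shift
    # of 1e3, i.e. ~0.1% of the community, so rarer taxa cannot carry a
    # detectable planted fold change
    lo, hi = int(0.65 * cfg.n_taxa), int(0.9 * cfg.n_taxa)
    mid_band = list(order[lo:hi])
    picked = rng.choice(len(mid_band), size=cfg.n_diff_taxa + 4, replace=False)
    diff_idx = [mid_band[i] for i in picked[:cfg.n_diff_taxa]]
    antag_idx = [mid_band[i] for i in picked[cfg.n_diff_taxa:]]
    for j, idx in enumerate(diff_idx):
        truth.diff_taxa[taxa[idx]] = "up" if j % 2 == 0 else "down"
    up_set = tuple(taxa[i] for i in antag_idx[:2])
    down_set = tuple(taxa[i] for i in antag_idx[2:])
    truth.antagonist_pair = (up_set, down_set)

    rho_ant = abs(spearman_to_pearson(abs(cfg.antagonist_rho)))
    beta = cfg.taxa_noise_sd * math.sqrt(rho_ant / (1.0 - rho_ant))
    u_latent = rng.normal(0, 1, len(fecal_ids))
    log_fold = math.log(cfg.taxa_fold)

    logab = np.tile(base_log[:, None], (1, len(fecal_ids)))
    aged_mask_m = np.array([g == AGED for g in micro_groups])
    for taxon, direction in truth.diff_taxa.items():
        fi = taxa.index(taxon)
        logab[fi, aged_mask_m] += log_fold if direction == "up" else -log_fold
    for taxon in up_set:
        logab[taxa.index(taxon)] += beta * u_latent
    for taxon in down_set:
        logab[taxa.index(taxon)] -= beta * u_latent
    taxa_dev = rng.normal(0, cfg.taxa_noise_sd, logab.shape)
    logab = logab + taxa_dev
    rel = np.exp(logab)
    rel /= rel.sum(axis=0, keepdims=True)
    depths = np.round(rng.uniform(0.8, 1.2, len(fecal_ids)) * cfg.depth).astype(int)
    counts = np.column_stack(
        [rng.multinomial(depths[j], rel[:, j]) for j in range(len(fecal_ids))])
    taxa_counts = FeatureMatrix(
        pd.DataFrame(counts, index=taxa, columns=fecal_ids, dtype=float), "count")

    # ---------------- genes / KOs -------------------------------------------
    inc_idx = {ko: sorted(rng.choice(cfg.n_taxa, size=3, replace=False).tolist())
               for ko in kos}
    truth.ko_incidence = {ko: [taxa[i] for i in idx] for ko, idx in inc_idx.items()}
    genes, lengths, g2k = [], [], []
    for ko in kos:
        for rep in range(2):
            genes.append(f"gene_{ko}_{rep + 1}")
            lengths.append(int(rng.integers(300, 3000)))
            g2k.append(ko)
    for i in range(40):  # orphans contribute to the TPM denominator only
        genes.append(f"gene_orph_{i + 1:02d}")
        lengths.append(int(rng.integers(300, 3000)))
        g2k.append("")
    gene_lengths = pd.Series(lengths, index=genes, name="length")
    gene2ko = pd.Series(g2k, index=genes, name="ko")
    ko_abund = np.stack([rel[inc_idx[ko], :].sum(axis=0) for ko in kos])
    orph_abund = np.exp(rng.normal(-4, 1, (40, len(fecal_ids))))
    gc = np.zeros((len(genes), len(fecal_ids)))
    for gi, g in enumerate(genes):
        ko = gene2ko[g]
        ab = ko_abund[kos.index(ko)] if ko else orph_abund[gi - 2 * cfg.n_kos]
        lam = np.maximum(ab * gene_lengths[g] / 1000.0 * 50.0, 1e-9)
        gc[gi] = rng.poisson(lam)
    gene_counts = FeatureMatrix(
        pd.DataFrame(gc, index=genes, columns=fecal_ids, dtype=float), "count")
    pathways = [f"path{i + 1:02d}" for i in range(40)]
    ko2pathway = pd.Series(
        [pathways[int(i)] for i in rng.integers(0, 40, cfg.n_kos)],
        index=kos, name="pathway")

    # ---------------- taxa -> metabolite couplings --------------------------
    couple_tissue = tissues[0]
    couple_taxa = [taxa[i] for i in antag_idx[:2]] if cfg.n_couplings else []
    free_metabs = [f for f in metabolites
                   if f not in truth.modules["MM"] and f not in truth.dem[couple_tissue]]
    cm = [str(x) for x in rng.permutation(free_metabs)][:cfg.n_couplings]
    for j, metab in enumerate(cm):
        taxon = couple_taxa[j % max(len(couple_taxa), 1)]
        sign = "positive" if j % 2 == 0 else "negative"
        truth.coupling_signs.append((taxon, metab, sign))
        ti_dev = taxa_dev[taxa.index(taxon)]  # realized log deviation per fecal sample
        vals = metabolome[couple_tissue].values
        for s in cohort:
            fs = fecal_ids.index(f"feces_{s}")
            sid = f"{couple_tissue}_{s}"
            bump = cfg.couple_kappa * (1.0 if sign == "positive" else -1.0)
            vals.loc[metab, sid] += bump * (ti_dev[fs] + beta * u_latent[fs]
                                            * (1 if taxon in up_set else -1 if taxon in down_set else 0))

    # ---------------- longitudinal plasma -----------------------------------
    long_features = proteins[:200]
    slope_prot = [str(x) for x in rng.permutation(long_features)][:15]
    for j, f in enumerate(slope_prot):
        truth.long_slopes[f] = cfg.long_slope if j < 10 else -cfg.long_slope
    long_cols, long_rows_meta = [], []
    day_plans: list[tuple[int, np.ndarray, np.ndarray]] = []
    for i in range(cfg.n_long_subjects):  # qualifying: >=5 healthy, span 700-731
        n_vis = int(rng.integers(9, 11))
        span = int(rng.integers(700, 732))
        days = np.unique(np.round(np.linspace(0, span, n_vis)).astype(int))
        day_plans.append((i, days, np.ones(len(days), bool)))
    extra = cfg.n_long_subjects
    # excluded subjects: too few visits / short span / long span / unhealthy
    day_plans.append((extra, np.array([0, 200, 400, 710]), np.ones(4, bool)))
    day_plans.append((extra + 1, np.round(np.linspace(0, 600, 6)).astype(int),
                      np.ones(6, bool)))
    day_plans.append((extra + 2, np.round(np.linspace(0, 800, 7)).astype(int),
                      np.ones(7, bool)))
    flags = np.ones(6, bool); flags[[1, 3]] = False
    day_plans.append((extra + 3, np.round(np.linspace(0, 720, 6)).astype(int), flags))

    long_base = pd.Series(rng.normal(cfg.baseline_mean, cfg.baseline_sd,
                                     len(long_features)), index=long_features)
    col_values = []
    for i, days, healthy in day_plans:
        subj = f"L{i + 1:02d}"
        for d, h in zip(days, healthy):
            sid = f"{subj}_d{d:04d}"
            long_cols.append(sid)
            long_rows_meta.append(dict(sample_id=sid, subject_id=subj,
                                       visit_day=int(d), healthy=bool(h)))
            v = long_base.to_numpy().copy()
            for f, slope in truth.long_slopes.items():
                v[long_features.index(f)] += slope * d
            v += rng.normal(0, cfg.noise_sd, len(v))
            col_values.append(v)
    longitudinal = FeatureMatrix(
        pd.DataFrame(np.column_stack(col_values), index=long_features,
                     columns=long_cols), "log_intensity")
    longitudinal_meta = pd.DataFrame(long_rows_meta).set_index("sample_id")

    # ---------------- toy peptide evidence ----------------------------------
    evidence = _toy_evidence()

    # ---------------- toy gene sets -----------------------------------------
    gene_sets = {"UNIVERSAL_UP": list(truth.universal_up)}
    for m in range(cfg.n_modules_per_omics):
        gene_sets[f"PM_BLOCK_{m + 1}"] = [
            f for f, idx in truth.modules["PM"].items() if idx == m + 1]
    for i in range(3):
        gene_sets[f"RANDOM_{i + 1}"] = sorted(
            str(x) for x in rng.choice(proteins, size=40, replace=False))

    meta = make_sample_meta(meta_rows)
    return SyntheticStudy(
        proteome=proteome, metabolome=metabolome, metabolite_classes=classes,
        taxa_counts=taxa_counts, gene_counts=gene_counts,
        gene_lengths=gene_lengths, gene2ko=gene2ko, ko2pathway=ko2pathway,
        longitudinal=longitudinal, longitudinal_meta=longitudinal_meta,
        evidence=evidence, gene_sets=gene_sets, meta=meta, truth=truth,
        config=cfg)


def _toy_evidence() -> pd.DataFrame:
    """Small peptide table exercising all four acceptance filters."""
    rows = [
        # peptide, protein, length, fdr, ppm, score, unique
        ("pep01", "PROT_A", 7, 0.005, 20.0, 40.0, True),    # boundary: kept
        ("pep02", "PROT_A", 9, 0.005, 5.0, 55.0, True),     # kept -> A has 2
        ("pep03", "PROT_A", 6, 0.005, 5.0, 50.0, True),     # too short
        ("pep04", "PROT_B", 9, 0.005, 25.0, 45.0, True),    # ppm fail
        ("pep05", "PROT_B", 9, 0.005, 10.0, 45.0, True),    # kept -> B has 1
        ("pep06", "PROT_C", 12, 0.02, 5.0, 60.0, True),     # fdr fail
        ("pep07", "PROT_C", 12, 0.01, 5.0, 39.0, True),     # score fail
        ("pep08", "PROT_D", 8, 0.001, 3.0, 80.0, False),    # kept, not unique
        ("pep09", "PROT_D", 10, 0.001, 3.0, 80.0, True),    # kept -> D has 1 unique
    ]
    return pd.DataFrame(rows, columns=["peptide_id", "protein_id", "length",
                                       "fdr", "mass_error_ppm", "score",
                                       "unique"])


# ---------------------------------------------------------------------------
# Fixture tree


def write_fixture(study: SyntheticStudy, out_dir: str | Path) -> dict:
    """Write every table as TSV plus truth/manifest JSON; return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    def emit_matrix(m: FeatureMatrix, rel: str) -> None:
        write_feature_matrix(m, out / rel)
        files.append(rel)

    for t, m in study.proteome.items():
        emit_matrix(m, f"proteome/{t}.tsv")
    for t, m in study.metabolome.items():
        emit_matrix(m, f"metabolome/{t}.tsv")
    emit_matrix(study.taxa_counts, "microbiome/taxa_counts.tsv")
    emit_matrix(study.gene_counts, "microbiome/gene_counts.tsv")
    emit_matrix(study.longitudinal, "longitudinal/plasma_visits.tsv")

    (out / "microbiome").mkdir(exist_ok=True)
    study.gene_lengths.to_csv(out / "microbiome/gene_lengths.tsv", sep="\t",
                              index_label="gene_id")
    files.append("microbiome/gene_lengths.tsv")
    study.gene2ko.to_csv(out / "microbiome/gene2ko.tsv", sep="\t",
                         index_label="gene_id")
    files.append("microbiome/gene2ko.tsv")
    study.ko2pathway.to_csv(out / "microbiome/ko2pathway.tsv", sep="\t",
                            index_label="ko_id")
    files.append("microbiome/ko2pathway.tsv")

    study.metabolite_classes.to_csv(out / "metabolome/classes.tsv", sep="\t",
                                    index_label="metabolite_id")
    files.append("metabolome/classes.tsv")
    write_sample_meta(study.meta, out / "sample_meta.tsv")
    files.append("sample_meta.tsv")
    study.longitudinal_meta.to_csv(out / "longitudinal/visit_meta.tsv", sep="\t",
                                   index_label="sample_id")
    files.append("longitudinal/visit_meta.tsv")
    study.evidence.to_csv(out / "evidence.tsv", sep="\t", index=False)
    files.append("evidence.tsv")

    with open(out / "gene_sets.gmt", "w", encoding="utf-8") as fh:
        for name, members in study.gene_sets.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")
    files.append("gene_sets.gmt")

    truth_dict = study.truth.to_dict()
    validate_truth_dict(truth_dict)
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth_dict, fh, indent=1, sort_keys=True)
    files.append("truth.json")
    with open(out / "truth.schema.json", "w", encoding="utf-8") as fh:
        json.dump({k: v.__name__ for k, v in TRUTH_SCHEMA.items()}, fh, indent=1)
    files.append("truth.schema.json")

    manifest = {"seed": study.config.seed,
                "config": dataclasses.asdict(study.config),
                "files": sorted(files)}
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
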
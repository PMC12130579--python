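"""Over-representation and preranked enrichment against user-supplied GMT sets.

Over-representation uses the hypergeometric upper tail; a term is declared
significant only when p < 0.05 AND the overlap holds at least 2 molecules.
Preranked enrichment follows the canonical weighted Kolmogorov-Smirnov
running-sum with gene-label permutations; NES normalises the observed ES by
the mean |ES| of same-sign permutation scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .core import log_stage
from .stats import bh_adjust


@dataclass
class GeneSetCollection:
    sets: dict = field(default_factory=dict)   # name -> member id list
    universe: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.sets)) != len(self.sets):
            raise ValueError("duplicate set names")
        uni = set(self.universe)
        if uni:
            self.sets = {name: [m for m in members if m in uni]
                         for name, members in self.sets.items()}


def read_gmt(path: str | Path, universe: list[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (name, description, members...)."""
    sets = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = parts[2:]
    return GeneSetCollection(sets=sets, universe=universe or [])


def ora(query: set[str] | list[str], gsc: GeneSetCollection, *,
        alpha: float = 0.05, min_overlap: int = 2) -> pd.DataFrame:
    """Hypergeometric over-representation of a query set in each gene set."""
    universe = list(gsc.universe)
    if not universe:
        raise ValueError("gene-set collection needs a universe")
    uni = set(universe)
    q = set(query) & uni
    dropped = len(set(query)) - len(q)
    if dropped:
        import warnings
        warnings.warn(f"{dropped} query ids outside the universe were dropped")
    if not q:
        raise ValueError("query is empty after restriction to the universe")
    N, n = len(uni), len(q)
    rows = []
    for name, members in gsc.sets.items():
        mem = set(members) & uni
        K = len(mem)
        k = len(mem & q)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((name, k, K, n, N, p))
    out = pd.DataFrame(rows, columns=["set_name", "overlap", "set_size",
                                      "query_size", "universe", "p"])
    out["q"] = bh_adjust(out["p"])
    out["significant"] = (out["p"] < alpha) & (out["overlap"] >= min_overlap)
    log_stage("ora", n_sets=len(out), n_sig=int(out["significant"].sum()))
    return out


def enrichment_score(ranked_ids: list[str], scores: np.ndarray,
                     members: set[str], weight: float = 1.0) -> float:
    """Weighted KS running-sum enrichment score for one set."""
    N = len(ranked_ids)
    hit = np.array([g in members for g in ranked_ids])
    K = int(hit.sum())
    if K == 0 or K == N:
        raise ValueError("set is empty or covers all ranked genes")
    w = np.abs(scores) ** weight
    hit_w = np.where(hit, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        hit_w = hit.astype(float)
        denom = hit_w.sum()
    p_hit = np.cumsum(hit_w) / denom
    p_miss = np.cumsum(~hit) / (N - K)
    dev = p_hit - p_miss
    return float(dev[np.argmax(np.abs(dev))])


def gsea_preranked(ranked: pd.Series, gsc: GeneSetCollection,
                   n_perm: int = 999, seed: int = 0, *, weight: float = 1.0,
                   min_size: int = 5, max_size: int = 500) -> pd.DataFrame:
    """Preranked enrichment with gene-label permutation NES and p-values.

    ``ranked`` maps unique ids to finite scores; it is sorted descending
    internally.  Sets outside [min_size, max_size] members (after
    restriction to the ranked ids) or covering every ranked gene are
    skipped with a warning.
    """
    if ranked.index.has_duplicates:
        raise ValueError("ranked ids must be unique")
    if not np.isfinite(ranked.to_numpy(dtype=float)).all():
        raise ValueError("scores must be finite")
    ranked = ranked.sort_values(ascending=False)
    ids = list(ranked.index)
    scores = ranked.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for name, members in gsc.sets.items():
        mem = set(members) & set(ids)
        if not (min_size <= len(mem) <= max_size) or len(mem) == len(ids):
            import warnings
            warnings.warn(f"skipping set {name!r} (size {len(mem)})")
            continue
        es = enrichment_score(ids, scores, mem, weight)
        null = np.empty(n_perm)
        k = len(mem)
        id_arr = np.array(ids)
        for b in range(n_perm):
            perm_members = set(id_arr[rng.choice(len(ids), size=k, replace=False)])
            null[b] = enrichment_score(ids, scores, perm_members, weight)
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        denom = np.abs(same).mean() if same.size else np.abs(null).mean()
        nes = es / denom if denom > 0 else 0.0
        p = ((np.sum(np.abs(same) >= abs(es)) + 1) / (same.size + 1)
             if same.size else 1.0)
        rows.append((name, len(mem), es, nes, p, n_perm))
    out = pd.DataFrame(rows, columns=["set_name", "set_size", "es", "nes",
                                      "p", "n_perm"])
    for sign in (1, -1):
        mask = np.sign(out["es"]) == sign
        out.loc[mask, "q"] = bh_adjust(out.loc[mask, "p"])
    return out
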
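"""Shared data containers, TSV readers/writers and the analysis configuration.

The universal in-memory currency of every stage is the :class:`FeatureMatrix`
-- a features x samples abundance grid backed by a pandas DataFrame in which
missing measurements are NaN (never 0: a zero count is a legitimate value).
Tables travel as tab-separated UTF-8 text with ``NA`` for missing cells.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("agingatlas")

#: Recognised value scales for a FeatureMatrix.
SCALE_TAGS = ("log_intensity", "count", "relative_abundance", "tpm")

YOUNG, AGED = "young", "aged"


class ParseError(ValueError):
    """Raised when a TSV table violates the format contract."""


@dataclass
class FeatureMatrix:
    """Features x samples abundance table with a missing-value mask.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are features, columns are samples, NaN marks missing entries.
    scale_tag : str
        One of :data:`SCALE_TAGS`; ``count`` enforces non-negative integers,
        ``relative_abundance`` enforces per-sample closure to 1.
    """

    values: pd.DataFrame
    scale_tag: str = "log_intensity"

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        idx, cols = self.values.index, self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ParseError(f"duplicate feature ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample ids: {dups}")
        vals = self.values.to_numpy(dtype=float)
        if self.scale_tag == "count":
            obs = vals[~np.isnan(vals)]
            if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
                raise ValueError("count matrix must hold non-negative integers")
        if self.scale_tag == "relative_abundance":
            sums = np.nansum(vals, axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("relative_abundance columns must sum to 1")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self, values: pd.DataFrame | None = None,
             scale_tag: str | None = None) -> "FeatureMatrix":
        return FeatureMatrix(
            values=self.values.copy() if values is None else values,
            scale_tag=self.scale_tag if scale_tag is None else scale_tag,
        )


def read_feature_matrix(path: str | Path, scale_tag: str = "log_intensity") -> FeatureMatrix:
    """Read a TSV abundance table (first column feature ids, header sample ids).

    Empty cells or ``NA`` denote missing values.  Duplicate feature or sample
    ids and non-numeric cells raise :class:`ParseError` naming the offender.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise ParseError(f"{path}: malformed header (need feature-id column plus samples)")
    samples = header[1:]
    seen: set[str] = set()
    for s in samples:
        if s in seen:
            raise ParseError(f"{path}: duplicate sample id {s!r}")
        seen.add(s)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                     keep_default_na=False, dtype=str, encoding="utf-8")
    df.columns = samples
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate feature id {dup[0]!r}")
    num = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col] != "")
        if bad.any():
            row = df.index[bad.to_numpy()][0]
            raise ParseError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
        num[col] = converted
    num.index.name = None
    return FeatureMatrix(values=num, scale_tag=scale_tag)


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write a FeatureMatrix as TSV with ``NA`` for missing entries."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    matrix.values.to_csv(path, sep="\t", na_rep="NA", index_label="feature_id")


# ---------------------------------------------------------------------------
# Sample metadata

META_COLUMNS = ("tissue", "age_group", "subject_id", "visit_day", "role")


def make_sample_meta(rows: Iterable[Mapping]) -> pd.DataFrame:
    """Build a validated sample-metadata frame indexed by sample_id.

    Required per row: ``sample_id``, ``tissue``, ``subject_id``, ``role``
    (``biological`` or ``qc``); ``age_group`` (young/aged) is mandatory for
    biological samples; ``visit_day`` is optional (longitudinal designs).
    """
    df = pd.DataFrame(list(rows))
    if "sample_id" not in df.columns:
        raise ValueError("sample metadata needs a sample_id column")
    df = df.set_index("sample_id")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample_id in metadata: {dup}")
    for col in META_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan if col == "visit_day" else None
    df["role"] = df["role"].fillna("biological")
    bad_role = ~df["role"].isin(["biological", "qc"])
    if bad_role.any():
        raise ValueError(f"unknown sample role(s): {df['role'][bad_role].unique()}")
    bio = df["role"] == "biological"
    missing_age = bio & (df["age_group"].isna() | ~df["age_group"].isin([YOUNG, AGED]))
    if missing_age.any():
        raise ValueError(
            f"age_group must be young/aged for biological samples: {list(df.index[missing_age])}")
    return df[list(META_COLUMNS) + [c for c in df.columns if c not in META_COLUMNS]]


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    return make_sample_meta(df.to_dict("records"))


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    meta.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")


def align_samples(matrix: FeatureMatrix, meta: pd.DataFrame) -> FeatureMatrix:
    """Reorder matrix columns to the canonical (tissue, age_group, subject) order.

    Every matrix sample must appear in ``meta``; metadata rows for samples not
    in the matrix are ignored.  The operation is idempotent.
    """
    missing = [s for s in matrix.sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"samples absent from metadata: {missing}")
    sub = meta.loc[matrix.sample_ids]
    order = sub.sort_values(
        ["tissue", "age_group", "subject_id"], kind="stable").index
    return matrix.copy(values=matrix.values[list(order)])


# ---------------------------------------------------------------------------
# Analysis configuration


@dataclass
class AnalysisConfig:
    """Thresholds for every pipeline stage (defaults follow the study rules)."""

    alpha: float = 0.05                 # two-sided significance level
    fc_cutoff: float = 1.5              # minimum fold change on the linear scale
    rho_cutoff: float = 0.6             # Spearman magnitude for edges / pair screen
    ts_specific_min: float = 4.0        # TS score floor for organ-specific calls
    ts_margin: float = 1.5              # lead over the runner-up tissue
    ts_margin_mode: str = "additive"    # additive | fold
    ts_enriched_interval: tuple[float, float] = (2.5, 4.0)  # open interval
    ts_sem_mult: float = 2.0            # measurement-noise floor on the TS scale sigma
    ts_inclusive_enriched: bool = False  # margin-failing ts>=4 -> enriched if True
    min_shared_tissues: int = 8
    community_rho: float = 0.60         # strict ">" for organ-community edges
    kmeans_k: int = 4
    wgcna_powers: tuple[int, ...] = tuple(range(1, 21))
    wgcna_r2_target: float = 0.90
    wgcna_min_module: int = 30
    lda_cutoff: float = 3.0
    permutations: int = 999
    use_q: bool = False                 # call DEPs on BH q instead of raw p
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("fc_cutoff", "rho_cutoff", "ts_specific_min", "ts_margin",
                     "community_rho", "lda_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ts_margin_mode not in ("additive", "fold"):
            raise ValueError("ts_margin_mode must be additive or fold")
        lo, hi = self.ts_enriched_interval
        if not lo < hi:
            raise ValueError("ts_enriched_interval must be an increasing pair")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("ts_enriched_interval", "wgcna_powers"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Result tables with provenance


@dataclass
class ResultTable:
    """A typed result frame plus provenance (stage, config hash, seed).

    Serialises to TSV with provenance stored in ``#key=value`` header lines so
    the round trip is lossless.
    """

    table: pd.DataFrame
    stage: str
    config_hash: str = ""
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            prov = {"stage": self.stage, "config_hash": self.config_hash,
                    "seed": self.seed, **self.extra}
            for key, val in prov.items():
                fh.write(f"#{key}={json.dumps(val)}\n")
            self.table.to_csv(fh, sep="\t", na_rep="NA", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ResultTable":
        prov: dict = {}
        skip = 0
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, val = line[1:].rstrip("\n").partition("=")
                prov[key] = json.loads(val)
                skip += 1
        if "stage" not in prov:
            raise ParseError(f"{path}: missing provenance header")
        table = pd.read_csv(path, sep="\t", skiprows=skip,
                            na_values=["NA"], keep_default_na=False)
        stage = prov.pop("stage")
        chash = prov.pop("config_hash", "")
        seed = prov.pop("seed", None)
        return cls(table=table, stage=stage, config_hash=chash, seed=seed, extra=prov)


def log_stage(stage: str, **params) -> None:
    """Structured stage log line to stderr."""
    logger.info("stage=%s %s", stage,
                " ".join(f"{k}={v}" for k, v in params.items()))
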
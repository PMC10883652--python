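"""Annotated feature-count tables and their compositional preprocessing.

The central objects are :class:`FeatureTable` (non-negative integer read
counts, features x samples, optionally carrying a seven-rank taxonomic
lineage per feature) and :class:`CompositionTable` (per-sample relative
abundances, each sample summing to one).  Preprocessing mirrors the usual
shotgun-metagenomics workflow: removal of undetermined annotations
("unassigned"/"uncultured"), closure to relative abundances over the
determined features, prevalence filtering, and aggregation of species
counts to higher taxonomic ranks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: metadata columns required for every sample
METADATA_COLUMNS = ("occupation", "gender", "sample_type", "smoking", "drinking")

_METADATA_LEVELS = {
    "occupation": {"student", "laborer"},
    "gender": {"M", "F"},
    "sample_type": {"saliva", "feces"},
    "smoking": {"yes", "no"},
    "drinking": {"yes", "no"},
}


class TableError(ValueError):
    """Raised for malformed tables, metadata or invalid preprocessing calls."""


class TaxonomyTree:
    """A rooted seven-rank taxonomy (kingdom ... species).

    Stored as one full lineage per species; parent links are implied by
    adjacent ranks.  Every species therefore has exactly one ancestor at
    each higher rank.
    """

    def __init__(self, lineages: Mapping[str, Sequence[str]]):
        clean: dict[str, tuple[str, ...]] = {}
        parent: dict[str, str] = {}
        for species, lineage in lineages.items():
            lineage = tuple(lineage)
            if len(lineage) != len(RANKS):
                raise TableError(
                    f"lineage for {species!r} has {len(lineage)} ranks, "
                    f"expected {len(RANKS)}"
                )
            if lineage[-1] != species:
                raise TableError(f"lineage of {species!r} must end in itself")
            for child, par in zip(lineage[1:], lineage[:-1]):
                if parent.setdefault(child, par) != par:
                    raise TableError(
                        f"taxon {child!r} has conflicting parents "
                        f"{parent[child]!r} and {par!r}"
                    )
            clean[species] = lineage
        self._lineages = clean

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self._lineages)

    def lineage(self, species: str) -> tuple[str, ...]:
        return self._lineages[species]

    def ancestor(self, species: str, rank: str) -> str:
        return self._lineages[species][RANKS.index(rank)]

    def __contains__(self, species: str) -> bool:
        return species in self._lineages

    def __len__(self) -> int:
        return len(self._lineages)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TaxonomyTree) and self._lineages == other._lineages


@dataclass
class FeatureTable:
    """Feature x sample matrix of non-negative integer read counts.

    ``counts`` is indexed by feature id with one column per sample.
    ``feature_kind`` names the annotation that produced the features
    (e.g. ``"species"``, ``"kegg-pathway"``, ``"card-type"``).
    """

    counts: pd.DataFrame
    feature_kind: str = "species"
    lineage: TaxonomyTree | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise TableError(f"duplicate feature ids: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise TableError(f"duplicate sample ids: {dups}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise TableError("counts must be integers")
            c = c.round().astype(np.int64)
            object.__setattr__(self, "counts", c)
            arr = c.to_numpy()
        if (arr < 0).any():
            rows = c.index[(arr < 0).any(axis=1)].tolist()
            raise TableError(f"negative counts in features: {rows}")

    @property
    def feature_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def select_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise TableError(f"unknown sample ids: {missing}")
        return FeatureTable(self.counts[list(sample_ids)], self.feature_kind, self.lineage)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.rename_axis("feature_id").to_csv(path, sep="\t")


@dataclass
class CompositionTable:
    """Per-sample relative abundances on the same axes as a FeatureTable."""

    values: pd.DataFrame
    feature_kind: str = "species"

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if (arr < 0).any():
            raise TableError("relative abundances must be non-negative")
        sums = arr.sum(axis=0)
        bad = np.abs(sums - 1.0) > 1e-9
        if bad.any():
            names = self.values.columns[bad].tolist()
            raise TableError(f"sample compositions do not sum to 1: {names}")

    @property
    def feature_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    def sample(self, sample_id: str) -> np.ndarray:
        return self.values[sample_id].to_numpy(dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        self.values.rename_axis("feature_id").to_csv(path, sep="\t")


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Check per-sample metadata (indexed by sample id) for required columns
    and allowed category levels."""
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise TableError(f"metadata missing columns: {missing}")
    if metadata.index.has_duplicates:
        dups = metadata.index[metadata.index.duplicated()].unique().tolist()
        raise TableError(f"duplicate sample ids in metadata: {dups}")
    for col, levels in _METADATA_LEVELS.items():
        bad = set(metadata[col].unique()) - levels
        if bad:
            raise TableError(f"metadata column {col!r} has invalid values {sorted(bad)}")
    return metadata


def group_code(row: Mapping[str, str]) -> str:
    """Cohort group code: gender + occupation + sample type, e.g. 'FStS'
    for a saliva sample from a female student."""
    occ = {"student": "St", "laborer": "La"}[row["occupation"]]
    st = {"saliva": "S", "feces": "F"}[row["sample_type"]]
    return f"{row['gender']}{occ}{st}"


def load_feature_table(
    path: str | Path, metadata_path: str | Path, feature_kind: str = "species"
) -> tuple[FeatureTable, pd.DataFrame]:
    """Read a TSV count table (first column: feature id) and its sample
    metadata TSV (columns: sample_id, occupation, gender, sample_type,
    smoking, drinking), cross-validating the sample ids."""
    try:
        counts = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise TableError(f"cannot parse feature table {path}: {exc}") from exc
    for col in counts.columns:
        if not pd.api.types.is_numeric_dtype(counts[col]):
            bad = counts[col][pd.to_numeric(counts[col], errors="coerce").isna()]
            raise TableError(
                f"non-numeric counts in sample {col!r}, rows {bad.index.tolist()[:5]}"
            )
    metadata = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
    validate_metadata(metadata)
    table_samples = set(counts.columns)
    meta_samples = set(metadata.index)
    if table_samples != meta_samples:
        missing_meta = sorted(table_samples - meta_samples)
        missing_table = sorted(meta_samples - table_samples)
        parts = []
        if missing_meta:
            parts.append(f"samples without metadata: {missing_meta}")
        if missing_table:
            parts.append(f"metadata without samples: {missing_table}")
        raise TableError("; ".join(parts))
    metadata = metadata.loc[counts.columns]
    return FeatureTable(counts, feature_kind=feature_kind), metadata


DEFAULT_UNDETERMINED = ("unassigned", "uncultured")


def drop_undetermined(
    table: FeatureTable, label_patterns: Iterable[str] = DEFAULT_UNDETERMINED
) -> FeatureTable:
    """Remove features whose id (or any lineage taxon) matches an
    undetermined-annotation pattern, case-insensitively."""
    patterns = [re.compile(re.escape(p), re.IGNORECASE) for p in label_patterns]
    if not patterns:
        raise TableError("label_patterns must be non-empty")

    def undetermined(fid: str) -> bool:
        names = [fid]
        if table.lineage is not None and fid in table.lineage:
            names.extend(table.lineage.lineage(fid))
        return any(p.search(n) for p in patterns for n in names)

    keep = [fid for fid in table.feature_ids if not undetermined(fid)]
    if not keep:
        raise TableError("all features matched undetermined patterns")
    return FeatureTable(table.counts.loc[keep], table.feature_kind, table.lineage)


def relative_abundance(table: FeatureTable) -> CompositionTable:
    """Close each sample to relative abundances (count / sample total)."""
    totals = table.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise TableError(f"samples with zero total count: {zero.index.tolist()}")
    values = table.counts / totals
    return CompositionTable(values.astype(float), table.feature_kind)


def prevalence_filter(table: FeatureTable, min_samples: int) -> FeatureTable:
    """Keep features detected (count > 0) in at least ``min_samples`` samples."""
    n = len(table.sample_ids)
    if not 0 <= min_samples <= n:
        raise TableError(f"min_samples must be in [0, {n}], got {min_samples}")
    detected = (table.counts > 0).sum(axis=1)
    keep = table.counts.index[detected >= min_samples]
    if len(keep) == 0:
        raise TableError(f"no feature is detected in >= {min_samples} samples")
    return FeatureTable(table.counts.loc[keep], table.feature_kind, table.lineage)


def aggregate_taxonomy(table: FeatureTable, tree: TaxonomyTree, rank: str) -> FeatureTable:
    """Sum species-level counts up to ``rank``; per-sample totals are
    conserved exactly (integer arithmetic)."""
    if rank not in RANKS:
        raise TableError(f"unknown rank {rank!r}; expected one of {RANKS}")
    missing = [fid for fid in table.feature_ids if fid not in tree]
    if missing:
        raise TableError(f"species missing from taxonomy: {missing}")
    if rank == "species":
        return FeatureTable(table.counts.copy(), table.feature_kind, tree)
    groups = [tree.ancestor(fid, rank) for fid in table.feature_ids]
    agg = table.counts.groupby(pd.Index(groups, name="feature_id"), sort=False).sum()
    return FeatureTable(agg, feature_kind=f"taxon@{rank}")
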
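"""Data model for hierarchical pitfall-trap surveys.

A survey consists of transects running away from a water source, each with
sample points at a fixed set of distance categories and a small number of
traps per sample point, visited in one or more seasons.  The raw observation
unit is a *trap record*: the number of individuals of one morphospecies in
one trap during one season.  This module validates long-format record tables
against the declared survey design and aggregates them into the two matrix
forms everything downstream consumes:

* a **community matrix** (samples x morphospecies counts, at a chosen pooling
  level) for alpha and beta diversity, and
* per transect x season **interaction matrices** (morphospecies x distance
  categories, counts pooled over sample points and traps) for the nestedness
  and modularity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptySelectionError, FormatError, ValidationError

#: Required columns of the long-format input, in canonical order.
COLUMNS = ("transect", "distance_m", "sample_point", "trap", "season", "species", "count")

#: Pooling levels for :func:`build_community_matrix` and the metadata columns
#: that define a sample at each level.
LEVELS: Mapping[str, tuple[str, ...]] = {
    "trap": ("transect", "distance_m", "sample_point", "trap"),
    "sample_point": ("transect", "distance_m", "sample_point"),
    "distance_by_transect": ("transect", "distance_m"),
}


@dataclass(frozen=True)
class SurveyDesign:
    """Declared sampling hierarchy of a trap survey.

    Defaults reproduce a six-transect design with five sample points at each
    of seven distances from water (0-1,000 m) and three pitfall traps per
    point, visited once in the wet and once in the dry season.
    """

    n_transects: int = 6
    distance_categories_m: tuple[int, ...] = (0, 50, 100, 150, 250, 500, 1000)
    n_sample_points: int = 5
    n_traps: int = 3
    seasons: tuple[str, ...] = ("wet", "dry")

    def __post_init__(self) -> None:
        cats = self.distance_categories_m
        if len(cats) == 0 or cats[0] != 0:
            raise ValidationError("distance categories must start at 0 m")
        if any(b <= a for a, b in zip(cats, cats[1:])):
            raise ValidationError("distance categories must be strictly increasing")
        for name in ("n_transects", "n_sample_points", "n_traps"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if len(self.seasons) < 1:
            raise ValidationError("at least one season required")


@dataclass
class TrapTable:
    """Validated long-format trap records plus the design they satisfy."""

    records: pd.DataFrame
    design: SurveyDesign = field(default_factory=SurveyDesign)

    def __post_init__(self) -> None:
        self.records = _validate_records(self.records, self.design)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def total_individuals(self) -> int:
        return int(self.records["count"].sum())


@dataclass
class CommunityMatrix:
    """Samples x morphospecies count matrix with per-sample metadata.

    ``counts`` has one row per sample and one column per morphospecies;
    ``metadata`` is index-aligned with ``counts`` and carries the grouping
    columns of the pooling level (plus ``season`` when present).
    ``zero_species_dropped`` records whether all-zero species columns were
    removed (the default: unobserved species carry no information for the
    per-season metrics).
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    level: str
    zero_species_dropped: bool

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("community matrix has negative entries")
        if not self.counts.index.equals(self.metadata.index):
            raise ValidationError("counts and metadata indices are misaligned")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class InteractionMatrix:
    """Morphospecies (rows) x distance categories (columns) pooled counts
    for one transect and season; all-zero species rows are removed."""

    transect: int
    season: str
    counts: pd.DataFrame  # index: species, columns: distance categories (m)

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValidationError("interaction matrix has negative entries")
        keep = arr.sum(axis=1) > 0
        if not keep.all():
            self.counts = self.counts.loc[keep]

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def _validate_records(df: pd.DataFrame, design: SurveyDesign) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    df = df.loc[:, list(COLUMNS)].copy()

    def offending(mask: pd.Series, what: str) -> None:
        if mask.any():
            lines = [str(i + 2) for i in df.index[mask][:5]]  # +2: header + 1-based
            raise ValidationError(f"{what} at input line(s) {', '.join(lines)}")

    count = pd.to_numeric(df["count"], errors="coerce")
    offending(count.isna() | (count != np.floor(count)), "non-integer count")
    offending(count < 0, "negative count")
    df["count"] = count.astype(np.int64)

    dist = pd.to_numeric(df["distance_m"], errors="coerce")
    offending(~dist.isin(design.distance_categories_m), "unknown distance category")
    df["distance_m"] = dist.astype(np.int64)

    offending(~df["season"].isin(design.seasons), "unknown season")

    for col, upper in (
        ("transect", design.n_transects),
        ("sample_point", design.n_sample_points),
        ("trap", design.n_traps),
    ):
        vals = pd.to_numeric(df[col], errors="coerce")
        offending(vals.isna() | (vals < 1) | (vals > upper), f"{col} outside design")
        df[col] = vals.astype(np.int64)

    key = ["transect", "distance_m", "sample_point", "trap", "season", "species"]
    offending(df.duplicated(subset=key, keep=False), "duplicate trap record")
    return df.reset_index(drop=True)


def read_trap_table(path: str | Path, design: SurveyDesign | None = None) -> TrapTable:
    """Read and validate a long-format CSV of trap records.

    Rows violating the design raise :class:`ValidationError` naming the
    offending input line numbers (header = line 1).
    """
    design = design or SurveyDesign()
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # pragma: no cover - passthrough
        raise FormatError(str(exc)) from exc
    return TrapTable(df, design)


def write_trap_table(table: TrapTable, path: str | Path) -> None:
    table.records.loc[:, list(COLUMNS)].to_csv(path, index=False)


def _sample_id(values: Iterable) -> str:
    return "/".join(str(v) for v in values)


def build_community_matrix(
    table: TrapTable,
    level: str = "trap",
    season_filter: str | None = None,
    drop_zero_species: bool = True,
) -> CommunityMatrix:
    """Aggregate trap records into a samples x species count matrix.

    ``level`` selects the pooling unit (``trap``, ``sample_point`` or
    ``distance_by_transect``).  With ``season_filter`` the matrix covers a
    single season and the season column is dropped from the sample key;
    without it, season remains part of the key so wet and dry visits of one
    trap are distinct samples.
    """
    if level not in LEVELS:
        raise ValidationError(f"unknown pooling level {level!r}")
    df = table.records
    if season_filter is not None:
        if season_filter not in table.design.seasons:
            raise ValidationError(f"unknown season {season_filter!r}")
        df = df[df["season"] == season_filter]
    if df.empty:
        raise EmptySelectionError(
            f"no records remain (level={level}, season_filter={season_filter})"
        )
    keys = list(LEVELS[level]) + ([] if season_filter else ["season"])
    wide = df.pivot_table(
        index=keys, columns="species", values="count", aggfunc="sum", fill_value=0
    ).astype(np.int64)
    if not drop_zero_species:
        # keep the whole species universe of the unfiltered table so paired
        # per-season matrices share one column set
        universe = sorted(table.records["species"].unique())
        wide = wide.reindex(columns=universe, fill_value=0)
    meta = wide.index.to_frame(index=False)
    if season_filter:
        meta["season"] = season_filter
    ids = [_sample_id(t) for t in wide.index]
    counts = pd.DataFrame(wide.to_numpy(), index=ids, columns=list(wide.columns))
    meta.index = pd.Index(ids)
    if drop_zero_species:
        counts = counts.loc[:, counts.sum(axis=0) > 0]
    return CommunityMatrix(counts, meta, level, drop_zero_species)


def build_interaction_matrices(table: TrapTable) -> list[InteractionMatrix]:
    """One morphospecies x distance-category matrix per observed
    (transect, season), pooling counts over sample points and traps."""
    out: list[InteractionMatrix] = []
    cats = list(table.design.distance_categories_m)
    for (transect, season), grp in table.records.groupby(["transect", "season"], sort=True):
        wide = grp.pivot_table(
            index="species", columns="distance_m", values="count",
            aggfunc="sum", fill_value=0,
        ).reindex(columns=cats, fill_value=0).astype(np.int64)
        out.append(InteractionMatrix(int(transect), str(season), wide))
    return out


def write_community_matrix(cm: CommunityMatrix, counts_path: str | Path,
                           metadata_path: str | Path) -> None:
    cm.counts.to_csv(counts_path, index_label="sample")
    cm.metadata.to_csv(metadata_path, index_label="sample")


def read_community_matrix(counts_path: str | Path, metadata_path: str | Path,
                          level: str = "trap",
                          zero_species_dropped: bool = True) -> CommunityMatrix:
    counts = pd.read_csv(counts_path, index_col="sample")
    meta = pd.read_csv(metadata_path, index_col="sample")
    return CommunityMatrix(counts.astype(np.int64), meta, level, zero_species_dropped)


def write_interaction_matrix(im: InteractionMatrix, path: str | Path) -> None:
    """Wide CSV: first column the species label, remaining columns the
    distance categories in metres."""
    im.counts.to_csv(path, index_label="species")


def read_interaction_matrix(path: str | Path, transect: int = 0,
                            season: str = "unknown") -> InteractionMatrix:
    wide = pd.read_csv(path, index_col="species")
    wide.columns = pd.Index([int(c) for c in wide.columns], name="distance_m")
    return InteractionMatrix(transect, season, wide.astype(np.int64))
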
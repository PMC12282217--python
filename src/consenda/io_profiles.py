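"""Profile tables, metadata, and the transforms shared by every stage.

Taxonomic profiles arrive as MetaPhlAn-style merged tables: one row per
clade, named by a pipe-delimited rank string (``k__...|p__...|...|t__SGB...``)
with per-sample relative abundances in percent. Pathway profiles arrive as
HUMAnN-style tables in reads-per-kilobase (RPK), with stratified
``PWY|genus.species`` sub-rows that are dropped for community-level testing.

The :class:`FeatureTable` container keeps the orientation fixed at
samples x features and carries its unit (relative percent, proportion,
count, RPK) and feature level so downstream engines can enforce their
input contracts.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: rank-prefix -> level name, in MetaPhlAn order (SGB terminal)
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__", "t__")
LEVELS = ("kingdom", "phylum", "class", "order", "family", "genus", "species", "sgb")
_PREFIX_TO_LEVEL = dict(zip(RANK_PREFIXES, LEVELS))

UNITS = ("relative_percent", "proportion", "count", "rpk")


@dataclass
class FeatureTable:
    """Samples x features abundance matrix with a unit and feature level.

    ``data`` is indexed by sample id with one column per feature; values are
    non-negative with absences as explicit zeros.
    """

    data: pd.DataFrame
    unit: str
    level: str

    def __post_init__(self):
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        values = self.data.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("abundances must be non-negative")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dup}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def select_features(self, feature_ids) -> "FeatureTable":
        return FeatureTable(self.data.loc[:, list(feature_ids)].copy(), self.unit, self.level)

    def select_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(sample_ids)].copy(), self.unit, self.level)


@dataclass
class SampleMetadata:
    """Per-sample group / subject / time point / BMI / library size."""

    data: pd.DataFrame  # indexed by sample_id

    REQUIRED = ("subject_id", "group", "timepoint", "library_size")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        lib = self.data["library_size"]
        if (lib <= 0).any() or lib.isna().any():
            raise ValueError("library_size must be positive for every sample")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def for_table(self, table: FeatureTable) -> pd.DataFrame:
        """Metadata rows aligned to the table's sample order."""
        missing = set(table.sample_ids) - set(self.data.index)
        if missing:
            raise KeyError(f"samples without metadata: {sorted(missing)}")
        return self.data.loc[table.sample_ids]


@dataclass
class TransformParams:
    """Pseudo-counts and the shared prevalence/abundance filter thresholds.

    Pseudo-counts are applied on each table's native scale: 0.0001 on
    percent-scale taxa and 1 on RPK pathways. The prevalence filter keeps
    features exceeding ``min_abundance`` in at least
    ``ceil(min_prevalence * n_samples)`` samples.
    """

    pseudo_taxa: float = 0.0001
    pseudo_pathway: float = 1.0
    min_prevalence: float = 0.1
    min_abundance: float = 1e-15

    def __post_init__(self):
        if not (0 < self.min_prevalence <= 1):
            raise ValueError("min_prevalence must lie in (0, 1]")
        if self.pseudo_taxa <= 0 or self.pseudo_pathway <= 0:
            raise ValueError("pseudo-counts must be strictly positive")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment=None, dtype=str)
    first = df.columns[0]
    df = df.set_index(first)
    return df.astype(float)


def parse_rank_string(clade: str, lineno: int | None = None) -> tuple[str, str]:
    """Split a pipe-delimited rank string into (level, terminal name).

    Raises ValueError naming the offending line when a component's prefix is
    malformed or out of rank order.
    """
    parts = clade.split("|")
    where = f" (line {lineno})" if lineno is not None else ""
    for depth, part in enumerate(parts):
        if depth >= len(RANK_PREFIXES) or not part.startswith(RANK_PREFIXES[depth]):
            raise ValueError(
                f"malformed rank prefix in {clade!r}{where}: component {part!r} "
                f"at depth {depth}"
            )
        if len(part) <= 3:
            raise ValueError(f"empty rank name in {clade!r}{where}")
    return LEVELS[len(parts) - 1], parts[-1]


def read_merged_taxonomy(path) -> dict[str, FeatureTable]:
    """Read a merged MetaPhlAn-style table and partition rows by rank depth.

    Each row lands in exactly one level's table, keyed by the deepest rank
    its string reaches; values are relative abundances in percent.
    """
    df = _read_tsv(path)
    per_level: dict[str, dict[str, np.ndarray]] = {lv: {} for lv in LEVELS}
    for lineno, (clade, row) in enumerate(df.iterrows(), start=2):
        level, _ = parse_rank_string(str(clade), lineno)
        if clade in per_level[level]:
            raise ValueError(f"duplicate feature string {clade!r} (line {lineno})")
        per_level[level][str(clade)] = row.to_numpy(dtype=float)
    out = {}
    for level, rows in per_level.items():
        if not rows:
            continue
        mat = pd.DataFrame(rows, index=df.columns)
        out[level] = FeatureTable(mat, unit="relative_percent", level=level)
    return out


def read_pathway_table(path, drop_unmapped: bool = True) -> FeatureTable:
    """Read a HUMAnN-style pathway table (RPK), keeping unstratified rows.

    Stratified ``pathway|taxon`` rows are dropped; UNMAPPED/UNINTEGRATED
    rows are dropped by default.
    """
    df = _read_tsv(path)
    keep = [str(f) for f in df.index if "|" not in str(f)]
    if drop_unmapped:
        keep = [f for f in keep if f.split(":")[0] not in ("UNMAPPED", "UNINTEGRATED")]
    if not keep:
        raise ValueError("no unstratified pathway rows found")
    mat = df.loc[keep].T
    return FeatureTable(mat, unit="rpk", level="pathway")


def read_metadata(path) -> SampleMetadata:
    """Read a metadata CSV/TSV with sample_id, subject_id, group, timepoint,
    library_size and optional bmi columns."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if "sample_id" not in df.columns:
        raise ValueError("metadata must contain a sample_id column")
    df = df.set_index("sample_id")
    return SampleMetadata(df)


def write_table(table: FeatureTable, path) -> None:
    """Write features as rows, samples as columns; counts as integers so the
    reader round-trips count tables bit-identically."""
    df = table.data.T
    if table.unit == "count":
        df = df.astype(np.int64)
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_table(path, unit: str, level: str) -> FeatureTable:
    df = _read_tsv(path).T
    return FeatureTable(df, unit=unit, level=level)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.data.rename_axis("sample_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def to_proportions(table: FeatureTable) -> FeatureTable:
    """Renormalise each sample to sum to one (unit ``proportion``)."""
    vals = table.values()
    sums = vals.sum(axis=1, keepdims=True)
    if (sums == 0).any():
        raise ValueError("cannot renormalise a sample whose abundances are all zero")
    return FeatureTable(pd.DataFrame(vals / sums, index=table.data.index,
                                     columns=table.data.columns),
                        unit="proportion", level=table.level)


def _fractions(table: FeatureTable) -> np.ndarray:
    if table.unit == "relative_percent":
        return table.values() / 100.0
    if table.unit == "proportion":
        return table.values()
    raise ValueError(f"expected relative abundances, got unit {table.unit!r}")


def to_approximate_counts(table: FeatureTable, meta: SampleMetadata,
                          round_to_int: bool = False) -> FeatureTable:
    """Approximate counts: relative abundance x per-sample library size.

    Stands in for true mapped-read counts when the profiler reports only
    relative abundance. ``round_to_int`` rounds half-to-even for engines
    with an integer requirement.
    """
    frac = _fractions(table)
    aligned = meta.for_table(table)
    if aligned["library_size"].isna().any():
        raise ValueError("missing library_size")
    counts = frac * aligned["library_size"].to_numpy(dtype=float)[:, None]
    if round_to_int:
        counts = np.rint(counts)
    return FeatureTable(pd.DataFrame(counts, index=table.data.index,
                                     columns=table.data.columns),
                        unit="count", level=table.level)


def prevalence_filter(table: FeatureTable, params: TransformParams | None = None,
                      min_prevalence: float | None = None,
                      min_abundance: float | None = None) -> FeatureTable:
    """Keep features detected in at least ceil(min_prevalence * n) samples.

    Detection means abundance strictly greater than ``min_abundance``
    (default: 0 for count tables, 1e-15 otherwise). Samples are untouched
    and no renormalisation is applied afterwards.
    """
    params = params or TransformParams()
    prev = params.min_prevalence if min_prevalence is None else min_prevalence
    if min_abundance is None:
        min_abundance = 0.0 if table.unit == "count" else params.min_abundance
    need = math.ceil(prev * table.n_samples)
    present = (table.values() > min_abundance).sum(axis=0)
    keep = [f for f, n in zip(table.feature_ids, present) if n >= need]
    return table.select_features(keep)


def clr_transform(table_or_values, pseudo: float) -> np.ndarray:
    """Centred log-ratio transform, per sample, after adding ``pseudo`` on
    the table's native scale. Each output row sums to zero."""
    if pseudo <= 0:
        raise ValueError("pseudo-count must be positive")
    vals = table_or_values.values() if isinstance(table_or_values, FeatureTable) \
        else np.asarray(table_or_values, dtype=float)
    if (vals < 0).any():
        raise ValueError("abundances must be non-negative")
    logx = np.log(vals + pseudo)
    return logx - logx.mean(axis=1, keepdims=True)


def ast_transform(table_or_values) -> np.ndarray:
    """Arcsine-square-root transform of proportions; range [0, pi/2]."""
    vals = table_or_values.values() if isinstance(table_or_values, FeatureTable) \
        else np.asarray(table_or_values, dtype=float)
    if (vals < 0).any() or (vals > 1).any():
        raise ValueError("arcsine-sqrt transform requires values in [0, 1]")
    return np.arcsin(np.sqrt(vals))


def rarefy(table: FeatureTable, depth: int, seed) -> FeatureTable:
    """Subsample each sample's counts to ``depth`` reads without replacement
    (multivariate hypergeometric). Samples below ``depth`` are dropped with
    a warning. Deterministic given ``seed``."""
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    if table.unit != "count":
        raise ValueError("rarefaction requires a count table")
    rng = np.random.default_rng(seed)
    counts = np.rint(table.values()).astype(np.int64)
    sums = counts.sum(axis=1)
    keep_rows = sums >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep_rows) if not k]
    if dropped:
        log.warning("rarefy: dropping %d samples below depth %d: %s",
                    len(dropped), depth, dropped)
    out = np.empty((int(keep_rows.sum()), counts.shape[1]), dtype=np.int64)
    for i, row in enumerate(counts[keep_rows]):
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth, method="marginals")
    idx = [s for s, k in zip(table.sample_ids, keep_rows) if k]
    return FeatureTable(pd.DataFrame(out, index=idx, columns=table.data.columns),
                        unit="count", level=table.level)
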
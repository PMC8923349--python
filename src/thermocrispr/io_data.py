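"""Trait-table and tree I/O with the dataset-construction rules.

A *trait table* holds one row per species: an optimal growth temperature
(Topt, °C) and per-genome counts of defense-system features (CRISPR arrays,
spacers, cas genes, cas gene clusters, restriction-modification genes).
This module reads/writes those tables, reduces raw CRISPR-annotation
records (with evidence levels 1-4) to abundances, merges Topt values from
ranked sources, rounds temperatures to integers, matches tables against a
phylogeny, and selects isolation-source strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical abundance measures, in reporting order
MEASURES = ("arrays", "spacers", "cas_genes", "cas_clusters", "rm_genes")

#: evidence levels whose arrays count toward abundance; 1-2 are putative
#: annotations that are counted as zero
TRUSTED_EVIDENCE_LEVELS = frozenset({3, 4})


class SchemaError(ValueError):
    """A required column is missing or an invariant is violated."""


@dataclass
class TraitTable:
    """Per-species traits: Topt plus abundance counts and metadata.

    ``data`` uses canonical column names: ``species_id``, ``topt_c``, any
    subset of :data:`MEASURES`, optional ``domain`` (Bacteria/Archaea) and
    ``isolation_sources`` (a frozenset of labels per row).
    """

    data: pd.DataFrame
    topt_validity: tuple[float, float] = (0.0, 110.0)

    def __post_init__(self) -> None:
        df = self.data
        if "species_id" not in df.columns or "topt_c" not in df.columns:
            raise SchemaError("trait table needs species_id and topt_c columns")
        dup = df["species_id"][df["species_id"].duplicated()]
        if len(dup):
            raise SchemaError(f"duplicate species_id: {sorted(set(dup))[:5]}")
        lo, hi = self.topt_validity
        bad = df[(df["topt_c"] < lo) | (df["topt_c"] > hi)]
        if len(bad):
            raise SchemaError(
                f"{len(bad)} Topt values outside validity range [{lo}, {hi}]"
            )
        for m in self.measures:
            col = df[m].dropna()
            if (col < 0).any():
                raise SchemaError(f"negative abundance in column {m!r}")
            if not np.allclose(col, np.round(col)):
                raise SchemaError(f"non-integral abundance in column {m!r}")
        self.data = df.reset_index(drop=True)

    @property
    def measures(self) -> list[str]:
        return [m for m in MEASURES if m in self.data.columns]

    @property
    def species(self) -> list[str]:
        return list(self.data["species_id"])

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, mask) -> "TraitTable":
        return TraitTable(self.data[np.asarray(mask)].copy(), self.topt_validity)

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotated CRISPR array with its confidence class (1-4)."""

    species_id: str
    evidence_level: int
    spacer_count: int = 0
    feature: str = "crispr_array"

    def __post_init__(self) -> None:
        if self.evidence_level not in (1, 2, 3, 4):
            raise ValueError(f"evidence_level must be 1-4, got {self.evidence_level}")
        if self.spacer_count < 0:
            raise ValueError("spacer_count must be >= 0")


@dataclass
class ToptSource:
    """One Topt source with a priority rank (1 = most trusted)."""

    source_name: str
    rank: int
    records: dict[str, float] = field(default_factory=dict)


DEFAULT_COLUMN_MAP = {
    "species_id": "species_id",
    "topt_c": "topt_c",
    "arrays": "arrays",
    "spacers": "spacers",
    "cas_genes": "cas_genes",
    "cas_clusters": "cas_clusters",
    "rm_genes": "rm_genes",
    "domain": "domain",
    "isolation_sources": "isolation_sources",
}


def read_trait_table(
    path,
    column_map: dict[str, str] | None = None,
    sep: str | None = None,
    topt_validity: tuple[float, float] = (0.0, 110.0),
) -> TraitTable:
    """Read a delimited trait table, dropping unusable rows with a logged count.

    ``column_map`` maps canonical names (keys of :data:`DEFAULT_COLUMN_MAP`)
    to the file's header names; omitted optional columns are skipped.  Rows
    with a missing/unparseable Topt, or missing every abundance column, are
    dropped (counted in the log), matching the rule that an unannotated
    genome is distinguished from an annotated zero.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    raw = pd.read_csv(path, sep=sep, dtype=str)
    for required in ("species_id", "topt_c"):
        if cmap[required] not in raw.columns:
            raise SchemaError(
                f"required column {cmap[required]!r} (for {required}) not in header"
            )

    df = pd.DataFrame({"species_id": raw[cmap["species_id"]].astype(str)})
    topt = pd.to_numeric(raw[cmap["topt_c"]], errors="coerce")
    n_bad_topt = int(topt.isna().sum())
    df["topt_c"] = topt

    present_measures = [m for m in MEASURES if cmap[m] in raw.columns]
    for m in present_measures:
        df[m] = pd.to_numeric(raw[cmap[m]], errors="coerce")
    if cmap["domain"] in raw.columns:
        df["domain"] = raw[cmap["domain"]]
    if cmap["isolation_sources"] in raw.columns:
        df["isolation_sources"] = [
            frozenset(s.split(";")) if isinstance(s, str) and s else frozenset()
            for s in raw[cmap["isolation_sources"]]
        ]

    keep = df["topt_c"].notna()
    if present_measures:
        keep &= df[present_measures].notna().any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning(
            "read_trait_table: dropped %d/%d rows (%d unparseable Topt)",
            n_dropped, len(df), n_bad_topt,
        )
    return TraitTable(df[keep].reset_index(drop=True), topt_validity)


def write_trait_table(table: TraitTable, path, sep: str = "\t") -> None:
    df = table.data.copy()
    if "isolation_sources" in df.columns:
        df["isolation_sources"] = [";".join(sorted(s)) for s in df["isolation_sources"]]
    df.to_csv(path, sep=sep, index=False)


def read_annotations(path, sep: str = "\t") -> list[AnnotationRecord]:
    """Read annotation records (species_id, evidence_level, spacer_count)."""
    df = pd.read_csv(path, sep=sep)
    return [
        AnnotationRecord(str(r.species_id), int(r.evidence_level), int(r.spacer_count))
        for r in df.itertuples()
    ]


def abundance_from_annotations(
    records: list[AnnotationRecord],
) -> pd.DataFrame:
    """Reduce annotation records to per-species array/spacer abundances.

    Only arrays with evidence level 3 or 4 count; putative arrays at levels
    1-2 contribute zero to both the array count and the spacer sum.
    Species appearing only with levels 1-2 still get an explicit zero row.
    """
    counts: dict[str, list[int]] = {}
    for rec in records:
        arr, spc = counts.setdefault(rec.species_id, [0, 0])
        if rec.evidence_level in TRUSTED_EVIDENCE_LEVELS:
            counts[rec.species_id][0] = arr + 1
            counts[rec.species_id][1] = spc + rec.spacer_count
    out = pd.DataFrame(
        {
            "species_id": sorted(counts),
            "arrays": [counts[s][0] for s in sorted(counts)],
            "spacers": [counts[s][1] for s in sorted(counts)],
        }
    )
    return out


def round_topt(table: TraitTable) -> TraitTable:
    """Round Topt to the nearest integer, halves away from zero.

    The pre-rounding value is kept in a ``topt_raw`` provenance column
    (first call only; the operation is idempotent).
    """
    df = table.data.copy()
    if "topt_raw" not in df.columns:
        df["topt_raw"] = df["topt_c"]
    x = df["topt_c"].to_numpy(dtype=float)
    df["topt_c"] = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return TraitTable(df, table.topt_validity)


def merge_topt_sources(sources: list[ToptSource]) -> dict[str, float]:
    """Resolve conflicting Topt records by source priority (rank 1 wins)."""
    if not sources:
        raise ValueError("merge_topt_sources needs at least one source")
    ranks = [s.rank for s in sources]
    if len(set(ranks)) != len(ranks):
        raise ValueError("source ranks must be distinct")
    merged: dict[str, float] = {}
    for src in sorted(sources, key=lambda s: s.rank, reverse=True):
        merged.update(src.records)  # higher-priority sources overwrite later
    return merged


def read_tree(path_or_string, schema: str = "newick") -> dendropy.Tree:
    """Read a phylogeny and validate its use as a covariance source."""
    if "(" in str(path_or_string):
        tree = dendropy.Tree.get(data=str(path_or_string), schema=schema)
    else:
        tree = dendropy.Tree.get(path=str(path_or_string), schema=schema)
    validate_tree(tree)
    return tree


def validate_tree(tree: dendropy.Tree) -> None:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) < 2:
        raise ValueError("tree must have at least 2 tips")
    if len(set(labels)) != len(labels):
        raise ValueError("tip labels are not unique")
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0  # absent root/edge lengths treated as zero
        elif edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")


def match_tree_table(
    tree: dendropy.Tree, table: TraitTable
) -> tuple[dendropy.Tree, TraitTable, dict[str, list[str]]]:
    """Prune tree and filter table to their common species.

    Degree-2 nodes created by pruning are suppressed with branch lengths
    summed, so every surviving tip keeps its root-to-tip path length.  The
    returned table rows follow the pruned tree's tip order.  The report
    maps ``dropped_from_tree`` / ``dropped_from_table`` to sorted name lists.
    """
    validate_tree(tree)
    tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
    names = set(table.species)
    common = tips & names
    if len(common) < 2:
        raise ValueError(f"only {len(common)} species shared between tree and table")

    pruned = tree.extract_tree_with_taxa_labels(common)
    pruned.suppress_unifurcations()
    validate_tree(pruned)
    order = [lf.taxon.label for lf in pruned.leaf_node_iter()]
    df = table.data.set_index("species_id").loc[order].reset_index()
    report = {
        "dropped_from_tree": sorted(tips - common),
        "dropped_from_table": sorted(names - common),
    }
    if report["dropped_from_tree"] or report["dropped_from_table"]:
        logger.info(
            "match_tree_table: kept %d species, dropped %d tree tips / %d table rows",
            len(common), len(report["dropped_from_tree"]),
            len(report["dropped_from_table"]),
        )
    return pruned, TraitTable(df, table.topt_validity), report


def select_isolation_sources(
    table: TraitTable,
    min_species: int = 150,
    min_upper_c: float = 60.0,
    max_lower_c: float = 30.0,
) -> dict[str, TraitTable]:
    """Select isolation-source strata wide and large enough for the scan.

    A source is retained iff it contains strictly more than ``min_species``
    species, its warmest species has Topt >= ``min_upper_c`` and its coldest
    has Topt <= ``max_lower_c`` — i.e. the stratum brackets the transition
    region instead of sitting on one side of it.
    """
    if "isolation_sources" not in table.data.columns:
        raise ValueError("table has no isolation_sources column")
    all_sources = sorted(set().union(*table.data["isolation_sources"]))
    out: dict[str, TraitTable] = {}
    for src in all_sources:
        mask = [src in s for s in table.data["isolation_sources"]]
        sub = table.data[mask]
        if len(sub) <= min_species:
            continue
        if sub["topt_c"].max() < min_upper_c or sub["topt_c"].min() > max_lower_c:
            continue
        out[src] = TraitTable(sub.copy(), table.topt_validity)
    return out
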
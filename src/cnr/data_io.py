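"""Domain types, file readers/writers, and species-set filtering rules.

The pipeline's tabular exchange format is TSV (tab-separated, UTF-8, header
row); trees are Newick with branch lengths.  Species identifiers are matched
by exact string comparison after trimming surrounding whitespace and
replacing internal whitespace with underscores, so that the same label can
appear in a metadata table and as a Newick tip.

Two filtering rules define the analysis sets used downstream:

* the *life-form set* drops shrub species (intermediate, tree-like habit);
* the *PGLS set* additionally drops algae and any species absent from the
  phylogeny, because the phylogenetic regression needs every species on the
  tree.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Allowed life-form categories, in canonical order.
LIFE_FORMS = ("tree", "perennial_herb", "annual_herb", "alga", "shrub")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


def normalize_species_id(raw: str) -> str:
    """Canonicalize a species label: trim, and join internal whitespace with '_'."""
    return "_".join(str(raw).strip().split())


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesRecord:
    """One species: identifier, life form, and total annotated gene count."""

    species_id: str
    life_form: str
    total_genes: int

    def __post_init__(self) -> None:
        if not self.species_id:
            raise DataError("species_id must be nonempty")
        if self.life_form not in LIFE_FORMS:
            raise DataError(
                f"unknown life_form {self.life_form!r} for {self.species_id!r}; "
                f"allowed: {', '.join(LIFE_FORMS)}"
            )
        if int(self.total_genes) != self.total_genes or self.total_genes < 1:
            raise DataError(
                f"total_genes for {self.species_id!r} must be a positive integer, "
                f"got {self.total_genes!r}"
            )


@dataclass
class CopyNumberTable:
    """Species-by-family integer copy-number matrix plus per-species metadata.

    ``counts`` is indexed by species_id (rows, in species order) with one
    column per gene family.  Column sums N_j and the grand total N_total are
    derived quantities, not stored.
    """

    species: list[SpeciesRecord]
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        ids = [s.species_id for s in self.species]
        dupes = _duplicates(ids)
        if dupes:
            raise DataError(f"duplicate species ids: {sorted(dupes)}")
        if list(self.counts.index) != ids:
            raise DataError("counts row index does not match species order")
        fam_dupes = _duplicates(self.counts.columns)
        if fam_dupes:
            raise DataError(f"duplicate family ids: {sorted(fam_dupes)}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise DataError("copy numbers must be integers")
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            bad = self.counts.index[(arr < 0).any(axis=1)][0]
            raise DataError(f"negative copy number for species {bad!r}")
        totals = self.totals.to_numpy()
        over = arr.sum(axis=1) > totals
        if over.any():
            bad = self.counts.index[over][0]
            raise DataError(
                f"family counts for species {bad!r} exceed its total gene count"
            )

    # -- accessors ----------------------------------------------------------

    @property
    def species_ids(self) -> list[str]:
        return [s.species_id for s in self.species]

    @property
    def families(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def totals(self) -> pd.Series:
        """Per-species total gene counts L_total,i, aligned with the rows."""
        return pd.Series(
            [s.total_genes for s in self.species],
            index=self.counts.index,
            name="total_genes",
        )

    @property
    def life_forms(self) -> pd.Series:
        return pd.Series(
            [s.life_form for s in self.species],
            index=self.counts.index,
            name="life_form",
        )

    def subset(self, species_ids: Sequence[str]) -> "CopyNumberTable":
        """Return a new table restricted to ``species_ids`` (kept in current order)."""
        keep = set(species_ids)
        missing = keep - set(self.species_ids)
        if missing:
            raise DataError(f"species not in table: {sorted(missing)}")
        recs = [s for s in self.species if s.species_id in keep]
        frame = self.counts.loc[[s.species_id for s in recs]]
        return CopyNumberTable(species=recs, counts=frame.copy())


class Phylogeny:
    """A rooted tree with branch lengths, thinly wrapping a dendropy tree.

    Tip labels are species ids.  Branch lengths must be nonnegative; a tree
    whose branches are all zero is rejected.  Ultrametricity can be checked
    but is not required.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick_string(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parser error types
            raise DataError(f"Newick parse error: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_newick_path(cls, path) -> "Phylogeny":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_newick_string(fh.read())

    def _validate(self) -> None:
        labels = self.tip_labels
        dupes = _duplicates(labels)
        if dupes:
            raise DataError(f"duplicate tip labels: {sorted(dupes)}")
        total = 0.0
        for edge in self._tree.preorder_edge_iter():
            if edge.tail_node is None:  # the root's stem; length optional
                continue
            if edge.length is None:
                head = edge.head_node
                name = head.taxon.label if head.taxon else "<internal>"
                raise DataError(f"missing branch length above node {name!r}")
            if edge.length < 0:
                raise DataError("negative branch length")
            total += edge.length
        if total == 0.0:
            raise DataError("all branch lengths are zero")

    # -- accessors ----------------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".17g",
        )
        return s.strip() + "\n"

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_newick())

    # -- geometry -----------------------------------------------------------

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length for every tip."""
        depths: dict[str, float] = {}
        for node in self._tree.preorder_node_iter():
            parent = node.parent_node
            d = 0.0 if parent is None else _node_depth(node, parent)
            node._cnr_depth = d  # type: ignore[attr-defined]
            if node.is_leaf():
                depths[node.taxon.label] = d
        return depths

    def is_ultrametric(self, tol: float = 1e-8) -> bool:
        depths = list(self.tip_depths().values())
        return (max(depths) - min(depths)) <= tol * max(max(depths), 1.0)

    def prune_to(self, labels: Iterable[str]) -> "Phylogeny":
        """Return a new tree retaining only ``labels`` (path lengths preserved)."""
        keep = list(dict.fromkeys(labels))
        missing = set(keep) - set(self.tip_labels)
        if missing:
            raise DataError(f"species not on tree: {sorted(missing)}")
        clone = self._tree.clone(depth=1)
        clone.retain_taxa_with_labels(keep)
        clone.suppress_unifurcations()
        return Phylogeny(clone)


def _node_depth(node, parent) -> float:
    return getattr(parent, "_cnr_depth", 0.0) + (node.edge.length or 0.0)


@dataclass
class GrowthTable:
    """Mean (and optional min/max) height-growth rates, m/year, per species."""

    rates: pd.DataFrame  # index species_id; columns mean_rate[, min_rate, max_rate]

    def __post_init__(self) -> None:
        df = self.rates
        if "mean_rate" not in df.columns:
            raise DataError("growth table needs a mean_rate column")
        if (df["mean_rate"] <= 0).any():
            bad = df.index[df["mean_rate"] <= 0][0]
            raise DataError(f"nonpositive growth rate for {bad!r}")
        if {"min_rate", "max_rate"} <= set(df.columns):
            ok = (df["min_rate"] <= df["mean_rate"]) & (
                df["mean_rate"] <= df["max_rate"]
            )
            if not ok.all():
                bad = df.index[~ok][0]
                raise DataError(f"growth bounds disordered for {bad!r}")
            if (df["min_rate"] <= 0).any():
                raise DataError("growth rates must be positive")

    @property
    def species_ids(self) -> list[str]:
        return list(self.rates.index)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_species_table(path) -> list[SpeciesRecord]:
    """Read a species metadata TSV (species_id, life_form, total_genes).

    File order is preserved.  Duplicate ids, unknown life-form tokens and
    non-integer gene totals are hard errors that name the offending line.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"species_id", "life_form", "total_genes"}
    if not required <= set(df.columns):
        raise DataError(f"species table must have columns {sorted(required)}")
    records: list[SpeciesRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        sid = normalize_species_id(row["species_id"])
        if sid in seen:
            raise DataError(f"duplicate species_id {sid!r} (line {line})")
        seen.add(sid)
        form = str(row["life_form"]).strip()
        if form not in LIFE_FORMS:
            raise DataError(
                f"unknown life_form {form!r} on line {line}; "
                f"allowed: {', '.join(LIFE_FORMS)}"
            )
        try:
            total = int(str(row["total_genes"]).strip())
        except ValueError as exc:
            raise DataError(
                f"non-integer total_genes {row['total_genes']!r} on line {line}"
            ) from exc
        records.append(SpeciesRecord(sid, form, total))
    return records


def write_species_table(records: Sequence[SpeciesRecord], path) -> None:
    df = pd.DataFrame(
        {
            "species_id": [r.species_id for r in records],
            "life_form": [r.life_form for r in records],
            "total_genes": [r.total_genes for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_copy_number_table(counts_path, species_table: Sequence[SpeciesRecord]) -> CopyNumberTable:
    """Read a species-by-family count TSV and align it with species metadata.

    Rows are matched to ``species_table`` by id; any species present in one
    input but missing from the other is a hard error naming it.  Cells must
    be nonnegative integers and each row sum must not exceed the species'
    total gene count.
    """
    df = pd.read_csv(counts_path, sep="\t", dtype=str)
    first = df.columns[0]
    df[first] = df[first].map(normalize_species_id)
    df = df.set_index(first)
    try:
        df = df.astype(np.int64)
    except ValueError as exc:
        raise DataError(f"non-integer copy-number cell: {exc}") from exc
    meta_ids = [r.species_id for r in species_table]
    extra = set(df.index) - set(meta_ids)
    if extra:
        raise DataError(f"species in counts but absent from metadata: {sorted(extra)}")
    missing = set(meta_ids) - set(df.index)
    if missing:
        raise DataError(f"species in metadata but absent from counts: {sorted(missing)}")
    df = df.loc[meta_ids]
    return CopyNumberTable(species=list(species_table), counts=df)


def write_copy_number_table(table: CopyNumberTable, path) -> None:
    out = table.counts.copy()
    out.index.name = "species_id"
    out.to_csv(path, sep="\t")


def read_newick(path) -> Phylogeny:
    return Phylogeny.from_newick_path(path)


def read_growth_table(path) -> GrowthTable:
    df = pd.read_csv(path, sep="\t")
    if "species_id" not in df.columns:
        raise DataError("growth table needs a species_id column")
    df["species_id"] = df["species_id"].map(normalize_species_id)
    dupes = _duplicates(df["species_id"])
    if dupes:
        raise DataError(f"duplicate species in growth table: {sorted(dupes)}")
    df = df.set_index("species_id")
    return GrowthTable(rates=df)


def write_growth_table(growth: GrowthTable, path) -> None:
    out = growth.rates.copy()
    out.index.name = "species_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Analysis-set filters
# ---------------------------------------------------------------------------


def prepare_lifeform_set(table: CopyNumberTable) -> CopyNumberTable:
    """Drop shrub species (intermediate life form) from the table.

    Returns the life-form comparison set.  Removals are logged by name; an
    all-shrub input yields an empty table with a warning.
    """
    shrubs = [s.species_id for s in table.species if s.life_form == "shrub"]
    if not shrubs:
        return table
    keep = [s.species_id for s in table.species if s.life_form != "shrub"]
    logger.info("removed %d shrub species: %s", len(shrubs), ", ".join(shrubs))
    if not keep:
        logger.warning("all species were shrubs; result is empty")
        return CopyNumberTable(species=[], counts=table.counts.iloc[0:0])
    return table.subset(keep)


def prepare_phylo_set(
    table: CopyNumberTable, tree: Phylogeny
) -> tuple[CopyNumberTable, Phylogeny]:
    """Restrict to species usable in PGLS: on the tree and not algae.

    Algae are dropped (no marker sequences, hence no branch lengths in the
    reference analysis), as is any species missing from the tree; the tree is
    pruned to the retained set.  Fewer than 3 retained species is an error
    because the regression would be underdetermined.
    """
    tips = set(tree.tip_labels)
    dropped_algae = [s.species_id for s in table.species if s.life_form == "alga"]
    dropped_missing = [
        s.species_id
        for s in table.species
        if s.life_form != "alga" and s.species_id not in tips
    ]
    keep = [
        s.species_id
        for s in table.species
        if s.life_form != "alga" and s.species_id in tips
    ]
    if dropped_algae:
        logger.info("removed algae: %s", ", ".join(dropped_algae))
    if dropped_missing:
        logger.info("removed species missing from tree: %s", ", ".join(dropped_missing))
    if len(keep) < 3:
        raise DataError(
            f"only {len(keep)} species retained; PGLS needs at least 3"
        )
    sub = table.subset(keep)
    pruned = tree.prune_to(keep)
    return sub, pruned


# ---------------------------------------------------------------------------
# Bundled reference roster
# ---------------------------------------------------------------------------


def load_reference_lifeforms() -> pd.DataFrame:
    """Life-form roster of the 65 plant species in the PLAZA comparative set.

    Columns: species_id, life_form.  Covers the Dicots PLAZA 4.0 + Gymno
    PLAZA 1.0 species used for copy-number comparison: 23 trees, 15 perennial
    herbs, 21 annual herbs, 2 algae and 4 shrubs.
    """
    ref = resources.files("cnr").joinpath("data/reference_species.tsv")
    return pd.read_csv(io.StringIO(ref.read_text(encoding="utf-8")), sep="\t")


def reference_copy_number_table() -> CopyNumberTable:
    """The reference roster as a CopyNumberTable with placeholder zero counts.

    Gene totals and counts are placeholders (1 and 0): the object exists so
    the species-set filters can be exercised on the real roster without the
    proprietary count matrix.
    """
    df = load_reference_lifeforms()
    species = [
        SpeciesRecord(row.species_id, row.life_form, 1) for row in df.itertuples()
    ]
    counts = pd.DataFrame(
        0, index=[s.species_id for s in species], columns=["placeholder"], dtype=np.int64
    )
    return CopyNumberTable(species=species, counts=counts)


def _duplicates(items: Iterable) -> set:
    seen: set = set()
    dup: set = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup
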
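"""Input model for comparative orthogroup analysis.

Three standard artifacts feed the pipeline: an orthogroup-by-species gene
count matrix in the OrthoFinder ``Orthogroups.GeneCount.tsv`` dialect, a
species metadata table carrying clade labels and nodulation status, and a
rooted Newick species tree.  This module reads each one into a validated,
cross-checked in-memory model.

Species whose nodulation status is unknown are retained everywhere (they
still appear in profiles and trees) but belong to no test group in any
comparison mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

NODULATION_STATUSES = ("nodulating", "non_nodulating", "unknown")

#: Default comparison modes.  "Fabales" contrasts nodulating Fabales against
#: every other status-assigned species (including non-nodulating legumes);
#: "Viridiplantae" contrasts all known nodulators against all known
#: non-nodulators.  Unknown-status species join neither group in either mode.
DEFAULT_MODES = ("Fabales", "Viridiplantae")


class PanelError(ValueError):
    """Invalid or inconsistent input artifact."""


@dataclass
class SpeciesRecord:
    """One species (or dataset) in the panel."""

    species_id: str
    display_name: str = ""
    order_label: str | None = None
    family_label: str | None = None
    subfamily_label: str | None = None
    clade_label: str | None = None
    nodulation_status: str = "unknown"
    total_genes: int | None = None
    dataset_of: str | None = None

    def __post_init__(self) -> None:
        if not self.species_id or not str(self.species_id).strip():
            raise PanelError("species_id must be a non-empty token")
        if self.nodulation_status not in NODULATION_STATUSES:
            raise PanelError(
                f"unrecognized nodulation status {self.nodulation_status!r} for "
                f"{self.species_id!r}; allowed tokens: {', '.join(NODULATION_STATUSES)}"
            )


ModePredicate = Callable[[SpeciesRecord], bool]


def _fabales_group1(rec: SpeciesRecord) -> bool:
    return rec.nodulation_status == "nodulating" and rec.order_label == "Fabales"


def _fabales_group2(rec: SpeciesRecord) -> bool:
    return rec.nodulation_status != "unknown" and not _fabales_group1(rec)


def _virid_group1(rec: SpeciesRecord) -> bool:
    return rec.nodulation_status == "nodulating"


def _virid_group2(rec: SpeciesRecord) -> bool:
    return rec.nodulation_status == "non_nodulating"


def default_mode_definitions() -> dict[str, tuple[ModePredicate, ModePredicate]]:
    return {
        "Fabales": (_fabales_group1, _fabales_group2),
        "Viridiplantae": (_virid_group1, _virid_group2),
    }


class SpeciesPanel:
    """Ordered collection of species records plus the comparison modes."""

    def __init__(
        self,
        records: Iterable[SpeciesRecord],
        mode_definitions: Mapping[str, tuple[ModePredicate, ModePredicate]] | None = None,
    ) -> None:
        self.records: list[SpeciesRecord] = list(records)
        seen: set[str] = set()
        for rec in self.records:
            if rec.species_id in seen:
                raise PanelError(f"duplicate species_id {rec.species_id!r} in panel")
            seen.add(rec.species_id)
        self.mode_definitions = dict(mode_definitions or default_mode_definitions())
        self._by_id = {rec.species_id: rec for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, species_id: str) -> bool:
        return species_id in self._by_id

    def __getitem__(self, species_id: str) -> SpeciesRecord:
        return self._by_id[species_id]

    @property
    def species_ids(self) -> list[str]:
        return [rec.species_id for rec in self.records]

    def status_of(self, species_id: str) -> str:
        return self._by_id[species_id].nodulation_status

    def groups(self, mode: str) -> tuple[list[str], list[str]]:
        """Species ids of (group1, group2) under a comparison mode.

        Membership is exclusive: a record matching the group1 predicate is
        never placed in group2 even if both predicates hold.
        """
        if mode not in self.mode_definitions:
            raise PanelError(
                f"unknown mode {mode!r}; defined modes: {sorted(self.mode_definitions)}"
            )
        pred1, pred2 = self.mode_definitions[mode]
        g1 = [r.species_id for r in self.records if pred1(r)]
        g1_set = set(g1)
        g2 = [
            r.species_id
            for r in self.records
            if r.species_id not in g1_set and pred2(r)
        ]
        return g1, g2

    def tips_with_status(self, status: str) -> list[str]:
        return [r.species_id for r in self.records if r.nodulation_status == status]

    def tips_in_clade(self, label: str) -> list[str]:
        """Species whose clade/subfamily/family/order label equals ``label``."""
        out = []
        for r in self.records:
            if label in (r.clade_label, r.subfamily_label, r.family_label, r.order_label):
                out.append(r.species_id)
        return out


class OrthogroupCountMatrix:
    """Non-negative integer gene counts per (orthogroup, species).

    ``species_totals`` holds the total number of annotated genes in each
    genome/transcriptome, which bounds the assigned-gene column sums from
    above (orthogroup assignment never covers every gene).
    """

    def __init__(self, counts: pd.DataFrame, species_totals: pd.Series | None = None):
        if counts.empty:
            raise PanelError("empty count matrix")
        if counts.index.duplicated().any():
            dup = counts.index[counts.index.duplicated()][0]
            raise PanelError(f"duplicate orthogroup id {dup!r}")
        if counts.columns.duplicated().any():
            dup = counts.columns[counts.columns.duplicated()][0]
            raise PanelError(f"duplicate species column {dup!r}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            frac, _ = np.modf(arr.astype(float))
            if np.isnan(arr.astype(float)).any() or (frac != 0).any():
                bad = np.argwhere(np.isnan(arr.astype(float)) | (frac != 0))[0]
                raise PanelError(
                    f"non-integer count at orthogroup {counts.index[bad[0]]!r}, "
                    f"species {counts.columns[bad[1]]!r}"
                )
            counts = counts.astype(np.int64)
            arr = counts.to_numpy()
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise PanelError(
                f"negative count at orthogroup {counts.index[bad[0]]!r}, "
                f"species {counts.columns[bad[1]]!r}"
            )
        self.counts = counts.astype(np.int64)
        self.counts.index.name = "Orthogroup"
        self.counts.columns.name = None
        colsums = self.counts.sum(axis=0)
        if species_totals is None:
            species_totals = colsums.copy()
        species_totals = pd.Series(species_totals).reindex(self.counts.columns)
        if species_totals.isna().any():
            missing = species_totals.index[species_totals.isna()][0]
            raise PanelError(f"species_totals missing for species {missing!r}")
        if (species_totals <= 0).any():
            bad = species_totals.index[species_totals <= 0][0]
            raise PanelError(f"species total must be positive for species {bad!r}")
        short = species_totals < colsums
        if short.any():
            bad = species_totals.index[short][0]
            raise PanelError(
                f"species total for {bad!r} is below its assigned-gene column sum"
            )
        self.species_totals = species_totals.astype(np.int64)

    @property
    def orthogroup_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.counts.columns)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"OrthogroupCountMatrix({len(self.orthogroup_ids)} orthogroups x "
            f"{len(self.species_ids)} species)"
        )


@dataclass
class SpeciesTree:
    """Rooted species tree with tips resolved against the panel."""

    tree: dendropy.Tree
    tip_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.tip_labels:
            self.tip_labels = [
                _clean_label(leaf.taxon.label) for leaf in self.tree.leaf_node_iter()
            ]

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        for leaf in tree.leaf_node_iter():
            leaf.taxon.label = _clean_label(leaf.taxon.label)
        return cls(tree=tree)


def _clean_label(label: str) -> str:
    return str(label).strip().strip("'\"").strip()


def read_gene_counts(path: str | Path) -> OrthogroupCountMatrix:
    """Read an ``Orthogroups.GeneCount.tsv``-dialect table.

    The first column names orthogroups; a trailing ``Total`` column (the
    per-orthogroup row sum OrthoFinder appends) is dropped if present.
    species_totals are initialized to per-species column sums; callers may
    override them with true genome totals from the metadata table.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2 or df.shape[0] == 0:
        raise PanelError(f"empty or column-less count matrix in {path}")
    og_col = df.columns[0]
    if df.columns[-1] == "Total":
        df = df.drop(columns=["Total"])
    df = df.set_index(og_col)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise PanelError(f"duplicate orthogroup id {dup!r} in {path}")
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=np.int64)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() | (converted != converted.round()) | (converted < 0)
        if bad.any():
            row = df.index[bad][0]
            raise PanelError(
                f"non-integer or negative count at row {row!r}, column {col!r} in {path}"
            )
        numeric[col] = converted.astype(np.int64)
    return OrthogroupCountMatrix(numeric)


def write_gene_counts(matrix: OrthogroupCountMatrix, path: str | Path) -> None:
    """Write the canonical TSV echo of a validated matrix (no Total column)."""
    out = matrix.counts.copy()
    out.index.name = "Orthogroup"
    out.to_csv(path, sep="\t")


METADATA_REQUIRED = ("species_id", "nodulation_status")
METADATA_OPTIONAL = (
    "display_name",
    "order",
    "family",
    "subfamily",
    "clade",
    "total_genes",
    "dataset_of",
)


def read_species_metadata(path: str | Path) -> SpeciesPanel:
    """Read the species metadata TSV/CSV into a panel with default modes.

    Required columns: ``species_id`` and ``nodulation_status`` (tokens
    ``nodulating`` / ``non_nodulating`` / ``unknown``).  Optional columns:
    ``order``, ``family``, ``subfamily``, ``clade``, ``display_name``,
    ``total_genes``, ``dataset_of``.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in METADATA_REQUIRED:
        if col not in df.columns:
            raise PanelError(f"metadata file {path} lacks required column {col!r}")
    records = []
    for _, row in df.iterrows():
        status = str(row["nodulation_status"]).strip()
        if status not in NODULATION_STATUSES:
            raise PanelError(
                f"unrecognized status token {status!r} for species "
                f"{row['species_id']!r}; allowed: {', '.join(NODULATION_STATUSES)}"
            )
        total = row.get("total_genes")
        records.append(
            SpeciesRecord(
                species_id=str(row["species_id"]).strip(),
                display_name=str(row.get("display_name", "") or ""),
                order_label=_opt(row.get("order")),
                family_label=_opt(row.get("family")),
                subfamily_label=_opt(row.get("subfamily")),
                clade_label=_opt(row.get("clade")),
                nodulation_status=status,
                total_genes=int(total) if total not in (None, "", "NA") and not pd.isna(total) else None,
                dataset_of=_opt(row.get("dataset_of")),
            )
        )
    return SpeciesPanel(records)


def _opt(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    value = str(value).strip()
    return value or None


def write_species_metadata(panel: SpeciesPanel, path: str | Path) -> None:
    rows = []
    for r in panel.records:
        rows.append(
            {
                "species_id": r.species_id,
                "display_name": r.display_name,
                "order": r.order_label or "",
                "family": r.family_label or "",
                "subfamily": r.subfamily_label or "",
                "clade": r.clade_label or "",
                "nodulation_status": r.nodulation_status,
                "total_genes": "" if r.total_genes is None else r.total_genes,
                "dataset_of": r.dataset_of or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_tree(path: str | Path, panel: SpeciesPanel) -> SpeciesTree:
    """Read a rooted Newick tree and validate its tips against the panel.

    A basal trifurcation (unrooted convention) is accepted as-is, treating
    the basal node as the root.  Tips with no matching panel species are an
    error; panel species missing from the tree trigger a warning only (they
    remain usable in the statistical tracks but not in phyletic
    classification).
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    for leaf in tree.leaf_node_iter():
        leaf.taxon.label = _clean_label(leaf.taxon.label)
    stree = SpeciesTree(tree=tree)
    panel_ids = set(panel.species_ids)
    for tip in stree.tip_labels:
        if tip not in panel_ids:
            raise PanelError(f"tree tip {tip!r} has no matching species in the panel")
    missing = panel_ids - set(stree.tip_labels)
    if missing:
        warnings.warn(
            "species missing from the tree (excluded from phyletic "
            f"classification): {', '.join(sorted(missing))}",
            stacklevel=2,
        )
    return stree


def apply_panel_totals(
    matrix: OrthogroupCountMatrix, panel: SpeciesPanel
) -> OrthogroupCountMatrix:
    """Override default species_totals with metadata ``total_genes`` values."""
    totals = matrix.species_totals.copy()
    for rec in panel.records:
        if rec.total_genes is not None and rec.species_id in totals.index:
            totals[rec.species_id] = rec.total_genes
    return OrthogroupCountMatrix(matrix.counts, totals)


def collapse_duplicate_datasets(
    matrix: OrthogroupCountMatrix, mapping: Mapping[str, str]
) -> OrthogroupCountMatrix:
    """Collapse multiple datasets of one species by element-wise maximum.

    Presence evidence from any of a species' datasets counts, without
    pseudo-replicating the species in group tests.  ``mapping`` sends every
    dataset column to its species id; species_totals take the maximum of the
    contributing dataset totals.
    """
    for dataset in mapping:
        if dataset not in matrix.counts.columns:
            raise PanelError(f"mapping references absent dataset column {dataset!r}")
    unmapped = [c for c in matrix.counts.columns if c not in mapping]
    if unmapped:
        raise PanelError(
            f"dataset columns missing from the mapping: {', '.join(map(str, unmapped))}"
        )
    order: list[str] = []
    for dataset in matrix.counts.columns:
        sp = mapping[dataset]
        if sp not in order:
            order.append(sp)
    collapsed = {}
    totals = {}
    for sp in order:
        cols = [d for d in matrix.counts.columns if mapping[d] == sp]
        collapsed[sp] = matrix.counts[cols].max(axis=1)
        # max of dataset totals, floored by the collapsed column sum (the
        # element-wise count maximum can exceed any single dataset's sum)
        totals[sp] = max(
            int(matrix.species_totals[cols].max()), int(collapsed[sp].sum())
        )
    out = pd.DataFrame(collapsed, index=matrix.counts.index)[order]
    return OrthogroupCountMatrix(out, pd.Series(totals))
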
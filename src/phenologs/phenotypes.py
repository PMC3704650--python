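"""Gene-phenotype association tables and binary phenotype matrices.

A phenotype here is any qualitative label attached to a set of genes:
a disease, a mutant phenotype, a GO biological process, sensitivity to a
chemical condition, or an in-situ expression territory.  All sources are
reduced to the same 4-column association table (species, phenotype_id,
phenotype_name, gene_id) and then to binary element x phenotype incidence
matrices, where an element is either a gene of one species or an
orthogroup of a species pair.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order of the association-table TSV dialect
ASSOC_COLUMNS = ["species", "phenotype_id", "phenotype_name", "gene_id"]


class ParseError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass(frozen=True)
class PhenotypeDescriptor:
    """Identity and size of one phenotype column."""

    id: str
    species: str
    name: str
    cardinality: int


@dataclass
class AssociationTable:
    """De-duplicated gene-phenotype association records.

    ``df`` has columns species, phenotype_id, phenotype_name, gene_id and an
    auxiliary ``phenotype_species`` column: for primary data it equals
    ``species``, but after orthology translation the gene may live in a
    different species than the phenotype it annotates.
    """

    df: pd.DataFrame
    source_label: str = ""

    def __post_init__(self) -> None:
        cols = ASSOC_COLUMNS + ["phenotype_species"]
        if "phenotype_species" not in self.df.columns:
            self.df = self.df.assign(phenotype_species=self.df["species"])
        self.df = (
            self.df[cols]
            .astype(str)
            .drop_duplicates(subset=["species", "phenotype_id", "gene_id"])
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def species(self) -> set[str]:
        return set(self.df["species"].unique())

    @property
    def phenotype_ids(self) -> list[str]:
        return sorted(self.df["phenotype_id"].unique())

    def genes_of(self, phenotype_id: str) -> frozenset[str]:
        sel = self.df.loc[self.df["phenotype_id"] == phenotype_id, "gene_id"]
        return frozenset(sel)

    def phenotype_name(self, phenotype_id: str) -> str:
        sel = self.df.loc[self.df["phenotype_id"] == phenotype_id, "phenotype_name"]
        return str(sel.iloc[0]) if len(sel) else ""

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        source_label: str = "",
        phenotype_species: Optional[Iterable[str]] = None,
    ) -> "AssociationTable":
        """Build a table from (species, phenotype_id, phenotype_name, gene_id) tuples."""
        df = pd.DataFrame(list(records), columns=ASSOC_COLUMNS)
        if phenotype_species is not None:
            df["phenotype_species"] = list(phenotype_species)
        return cls(df, source_label=source_label)

    def to_tsv(self, path) -> None:
        self.df[ASSOC_COLUMNS].to_csv(path, sep="\t", index=False)


def read_associations(path, source_label: str = "") -> AssociationTable:
    """Read a 4-column association TSV (header required) and de-duplicate.

    Raises :class:`ParseError` on missing columns or empty required fields.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=ASSOC_COLUMNS)
    missing = [c for c in ASSOC_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    df = df[ASSOC_COLUMNS]
    for col in ("species", "phenotype_id", "gene_id"):
        bad = df[col].isna() | (df[col].astype(str).str.strip() == "")
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header is line 1
            raise ParseError(f"{path}: empty required field '{col}' at line {line}")
    df["phenotype_name"] = df["phenotype_name"].fillna("")
    return AssociationTable(df, source_label=source_label)


def filter_min_genes(table: AssociationTable, minimum: int = 3) -> AssociationTable:
    """Drop phenotypes with fewer than ``minimum`` distinct associated genes.

    The default of 3 reflects the standard dataset-construction rule that
    phenotypes with fewer than three genes carry too little overlap signal.
    Idempotent: the surviving phenotypes all satisfy the threshold already.
    """
    if minimum < 1:
        raise ValueError("minimum must be >= 1")
    counts = table.df.groupby("phenotype_id")["gene_id"].nunique()
    keep = set(counts.index[counts >= minimum])
    out = table.df[table.df["phenotype_id"].isin(keep)].reset_index(drop=True)
    return AssociationTable(out, source_label=table.source_label)


#: GO evidence codes retained by default: experimental and curated codes,
#: excluding electronic (IEA) and sequence/orthology-based codes so that
#: annotations projected from other model organisms are not counted twice.
DEFAULT_EVIDENCE_CODES = frozenset(
    {"IMP", "IDA", "IPI", "IGI", "TAS", "NAS", "IC", "IEP"}
)

#: all evidence codes defined by the GO consortium (for warning on unknowns)
_KNOWN_EVIDENCE_CODES = DEFAULT_EVIDENCE_CODES | {
    "EXP", "HTP", "HDA", "HMP", "HGI", "HEP", "IBA", "IBD", "IKR", "IRD",
    "ISS", "ISO", "ISA", "ISM", "IGC", "RCA", "ND", "IEA",
}


def filter_evidence_codes(
    gaf_path,
    species: str,
    allowed: frozenset[str] = DEFAULT_EVIDENCE_CODES,
    source_label: str = "",
) -> AssociationTable:
    """Convert a GAF 2.x file into an association table, keeping only
    annotations whose evidence code is in ``allowed``.

    GO term ids become phenotype ids; the DB object symbol (column 3 of the
    GAF) becomes the gene id.  Rows with a NOT qualifier are dropped, and
    (gene, term) pairs are de-duplicated across evidence codes.  Unknown
    evidence codes are excluded with a logged warning rather than an error.
    """
    from Bio.UniProt import GOA

    rows = []
    with open(gaf_path) as handle:
        for rec in GOA.gafiterator(handle):
            code = rec["Evidence"]
            if code not in _KNOWN_EVIDENCE_CODES:
                logger.warning("unknown evidence code %r: record skipped", code)
                continue
            if code not in allowed:
                continue
            if any(q.startswith("NOT") for q in rec["Qualifier"]):
                continue
            # GAF carries no term names; the GO id doubles as the display name
            rows.append((species, rec["GO_ID"], rec["GO_ID"], rec["DB_Object_Symbol"]))
    df = pd.DataFrame(rows, columns=ASSOC_COLUMNS)
    return AssociationTable(df, source_label=source_label)


def profile_to_phenotypes(
    profiles: pd.DataFrame,
    species: str,
    top_k: int = 40,
    bottom_k: int = 40,
    source_label: str = "",
) -> AssociationTable:
    """Convert a quantitative phenomic profile matrix into phenotypes.

    ``profiles`` is genes x conditions (index gene ids, columns condition
    names, numeric scores).  Each condition becomes a phenotype; a gene is
    associated with the conditions where its growth/fitness score is among
    its own ``top_k`` highest or ``bottom_k`` lowest — the conditions where
    the gene's perturbation matters most, in either direction.  Score ties
    are broken by condition name so the assignment is deterministic.
    """
    values = profiles.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        raise ParseError("non-numeric score in profile matrix")
    conditions = list(profiles.columns)
    rows = []
    for gene, scores in values.iterrows():
        # sort by (score, condition id): stable, deterministic under ties
        order = sorted(conditions, key=lambda c: (scores[c], c))
        chosen = set(order[:bottom_k]) | set(order[-top_k:])
        for cond in chosen:
            rows.append((species, cond, cond, str(gene)))
    df = pd.DataFrame(rows, columns=ASSOC_COLUMNS)
    return AssociationTable(df, source_label=source_label)


def expand_location_stage(
    annotations: pd.DataFrame,
    species: str,
    location_gene_threshold: int = 50,
    stage_min_genes: int = 3,
    source_label: str = "",
) -> AssociationTable:
    """Expand in-situ expression annotations into location (and stage) phenotypes.

    ``annotations`` has columns gene, location, stage.  Every anatomical
    location becomes a phenotype.  For locations with strictly more than
    ``location_gene_threshold`` distinct genes, each stage there with
    strictly more than ``stage_min_genes`` distinct genes additionally
    becomes a phenotype named ``"<location> at stage <stage>"``.
    """
    need = {"gene", "location", "stage"}
    if not need.issubset(annotations.columns):
        raise ParseError(f"expression table needs columns {sorted(need)}")
    ann = annotations.astype(str)
    rows = []
    for loc, grp in ann.groupby("location"):
        genes = grp["gene"].unique()
        for g in genes:
            rows.append((species, loc, loc, g))
        if len(genes) > location_gene_threshold:
            for stage, sgrp in grp.groupby("stage"):
                sgenes = sgrp["gene"].unique()
                if len(sgenes) > stage_min_genes:
                    pid = f"{loc} at stage {stage}"
                    for g in sgenes:
                        rows.append((species, pid, pid, g))
    df = pd.DataFrame(rows, columns=ASSOC_COLUMNS)
    return AssociationTable(df, source_label=source_label)


@dataclass
class PhenotypeMatrix:
    """Binary element x phenotype incidence, stored column-wise as sets.

    ``element_kind`` is ``"genes"`` (elements are genes of ``species``) or
    ``"orthogroups"`` (elements are orthogroup ids of the species ``pair``).
    ``elements`` is the full universe; a column is the set of elements
    carrying that phenotype.  N for overlap statistics is ``len(elements)``.
    """

    element_kind: str
    elements: tuple[str, ...]
    phenotypes: tuple[PhenotypeDescriptor, ...]
    columns: Mapping[str, frozenset[str]]
    species: Optional[str] = None
    pair: Optional[tuple[str, str]] = None

    def __post_init__(self) -> None:
        if self.element_kind not in ("genes", "orthogroups"):
            raise ValueError(f"bad element_kind {self.element_kind!r}")
        if len(set(self.elements)) != len(self.elements):
            raise ValueError("duplicate element ids")

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def phenotype_ids(self) -> list[str]:
        return [p.id for p in self.phenotypes]

    def column(self, phenotype_id: str) -> frozenset[str]:
        return self.columns[phenotype_id]

    def descriptor(self, phenotype_id: str) -> PhenotypeDescriptor:
        for p in self.phenotypes:
            if p.id == phenotype_id:
                return p
        raise KeyError(phenotype_id)

    def cardinality(self, phenotype_id: str) -> int:
        return len(self.columns[phenotype_id])

    def drop_from_column(
        self, phenotype_id: str, hidden: Iterable[str]
    ) -> "PhenotypeMatrix":
        """Copy of the matrix with ``hidden`` elements removed from one column.

        Used by cross-validation to mask a withheld gene (and its
        orthogroups) out of the target phenotype; every other column is
        shared, not copied.
        """
        if phenotype_id not in self.columns:
            return self
        new_col = self.columns[phenotype_id] - frozenset(hidden)
        cols = dict(self.columns)
        cols[phenotype_id] = new_col
        phens = tuple(
            replace(p, cardinality=len(new_col)) if p.id == phenotype_id else p
            for p in self.phenotypes
        )
        return PhenotypeMatrix(
            self.element_kind, self.elements, phens, cols, self.species, self.pair
        )

    def to_dense(self) -> pd.DataFrame:
        """Dense 0/1 DataFrame (elements x phenotypes), for export and checks."""
        idx = {e: i for i, e in enumerate(self.elements)}
        arr = np.zeros((len(self.elements), len(self.phenotypes)), dtype=np.int8)
        for j, p in enumerate(self.phenotypes):
            for e in self.columns[p.id]:
                arr[idx[e], j] = 1
        return pd.DataFrame(arr, index=list(self.elements), columns=self.phenotype_ids)


def build_matrix(
    table: AssociationTable,
    element_kind: str = "genes",
    universe: Optional[Iterable[str]] = None,
    species: Optional[str] = None,
    pair: Optional[tuple[str, str]] = None,
) -> PhenotypeMatrix:
    """Build a binary incidence matrix from an association table.

    For ``element_kind="orthogroups"`` the table must already be projected so
    that its gene_id field holds orthogroup ids (see
    :func:`phenologs.orthology.project_to_orthogroups`); ``universe`` should
    then be the full set of orthogroups of the pair.  Elements in the table
    but absent from an explicitly supplied universe are dropped with a
    logged count.  Element and phenotype ordering is lexicographic.
    """
    df = table.df
    if universe is None:
        universe = sorted(df["gene_id"].unique())
    else:
        universe = sorted(set(universe))
        known = set(universe)
        dropped = (~df["gene_id"].isin(known)).sum()
        if dropped:
            logger.info("build_matrix: dropped %d records outside universe", dropped)
        df = df[df["gene_id"].isin(known)]

    columns: dict[str, frozenset[str]] = {}
    phens: list[PhenotypeDescriptor] = []
    for pid, grp in df.groupby("phenotype_id", sort=True):
        members = frozenset(grp["gene_id"])
        columns[pid] = members
        phens.append(
            PhenotypeDescriptor(
                id=str(pid),
                species=str(grp["phenotype_species"].iloc[0]),
                name=str(grp["phenotype_name"].iloc[0]),
                cardinality=len(members),
            )
        )
    return PhenotypeMatrix(
        element_kind=element_kind,
        elements=tuple(universe),
        phenotypes=tuple(phens),
        columns=columns,
        species=species,
        pair=pair,
    )
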
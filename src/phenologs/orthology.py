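"""Pairwise orthology maps and cross-species translation of annotations.

Orthology arrives as orthogroups: for a pair of species, a group of genes
descending from a single gene in their last common ancestor, containing the
orthologs plus any lineage-specific inparalogs on each side.  A gene belongs
to at most one orthogroup per species pair.  Two translation frameworks are
supported downstream:

* gene-based — annotations of one species are rewritten onto every ortholog
  in the other species (paralog expansions multiply records);
* orthogroup-based — annotations of either species are projected onto the
  orthogroup itself (paralogs collapse to a single element), which makes
  cross-species overlap statistics symmetric in the two species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .phenotypes import ASSOC_COLUMNS, AssociationTable, ParseError


class IntegrityError(ValueError):
    """Orthology input violates a structural invariant."""


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered species pair under a canonical lexicographic key."""
    if a == b:
        raise ValueError(f"species pair requires two distinct species, got {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class Orthogroup:
    id: str
    species_pair: tuple[str, str]
    members: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        a, b = self.species_pair
        if set(self.members) != {a, b}:
            raise IntegrityError(
                f"orthogroup {self.id}: members must cover exactly {self.species_pair}"
            )
        for sp, genes in self.members.items():
            if not genes:
                raise IntegrityError(f"orthogroup {self.id}: empty side {sp!r}")

    def side(self, species: str) -> frozenset[str]:
        return self.members[species]


class OrthologyMap:
    """Orthogroups indexed by species pair and by (species, gene).

    Lookups are symmetric in pair order; within one pair every gene belongs
    to at most one orthogroup (enforced at construction).
    """

    def __init__(self, groups: Iterable[Orthogroup] = ()) -> None:
        self._groups: dict[tuple[str, str], dict[str, Orthogroup]] = {}
        self._gene_index: dict[tuple[tuple[str, str], str, str], str] = {}
        for g in groups:
            self.add(g)

    def add(self, group: Orthogroup) -> None:
        pair = canonical_pair(*group.species_pair)
        per_pair = self._groups.setdefault(pair, {})
        if group.id in per_pair:
            raise IntegrityError(f"duplicate orthogroup id {group.id} for pair {pair}")
        for sp, genes in group.members.items():
            for gene in genes:
                key = (pair, sp, gene)
                if key in self._gene_index:
                    raise IntegrityError(
                        f"gene {sp}:{gene} assigned to two orthogroups "
                        f"({self._gene_index[key]}, {group.id}) in pair {pair}"
                    )
                self._gene_index[key] = group.id
        per_pair[group.id] = group

    @property
    def species_pairs(self) -> set[tuple[str, str]]:
        return set(self._groups)

    def groups(self, species_a: str, species_b: str) -> dict[str, Orthogroup]:
        return self._groups.get(canonical_pair(species_a, species_b), {})

    def group(self, species_a: str, species_b: str, group_id: str) -> Orthogroup:
        return self._groups[canonical_pair(species_a, species_b)][group_id]

    def group_of(self, species: str, gene: str, other_species: str) -> Optional[str]:
        """Orthogroup id of ``gene`` in the pair (species, other_species), or None."""
        pair = canonical_pair(species, other_species)
        return self._gene_index.get((pair, species, gene))

    def genes_with_orthologs(self, species: str, other_species: str) -> frozenset[str]:
        """All genes of ``species`` that belong to some orthogroup of the pair."""
        out = set()
        for g in self.groups(species, other_species).values():
            out |= g.side(species)
        return frozenset(out)

    @classmethod
    def union(cls, maps: Iterable["OrthologyMap"]) -> "OrthologyMap":
        merged = cls()
        for m in maps:
            for per_pair in m._groups.values():
                for g in per_pair.values():
                    merged.add(g)
        return merged


def load_orthology(path, species_a: str, species_b: str) -> OrthologyMap:
    """Load one species pair's orthogroups from a 3-column TSV.

    Columns: orthogroup_id, species, gene_id (an optional 4th confidence
    column is ignored; '#'-prefixed comment lines are skipped).  Orthogroups
    with an empty side and genes appearing in two orthogroups are rejected.
    """
    pair = canonical_pair(species_a, species_b)
    try:
        df = pd.read_csv(
            path, sep="\t", dtype=str, comment="#", header=None,
            names=["orthogroup_id", "species", "gene_id", "confidence"],
        )
    except pd.errors.EmptyDataError:
        return OrthologyMap()
    # a header row is tolerated: detect and drop it
    if len(df) and tuple(df.iloc[0][:3]) == ("orthogroup_id", "species", "gene_id"):
        df = df.iloc[1:].reset_index(drop=True)
    for i, row in df.iterrows():
        if pd.isna(row["orthogroup_id"]) or pd.isna(row["species"]) or pd.isna(row["gene_id"]):
            raise ParseError(f"{path}: malformed row at line {int(i) + 1}")
        if row["species"] not in (species_a, species_b):
            raise ParseError(
                f"{path}: line {int(i) + 1}: species {row['species']!r} "
                f"not in pair {pair}"
            )
    groups = []
    for gid, grp in df.groupby("orthogroup_id", sort=True):
        members = {
            sp: frozenset(grp.loc[grp["species"] == sp, "gene_id"])
            for sp in pair
        }
        for sp in pair:
            if not members[sp]:
                raise IntegrityError(
                    f"{path}: orthogroup {gid} has no member in species {sp!r}"
                )
        groups.append(Orthogroup(id=str(gid), species_pair=pair, members=members))
    return OrthologyMap(groups)


def translate_gene_based(
    assoc: AssociationTable,
    source: str,
    target: str,
    omap: OrthologyMap,
) -> AssociationTable:
    """Rewrite source-species associations onto target-species orthologs.

    Each (source gene, phenotype) record becomes one record per target gene
    sharing its orthogroup; genes without an orthogroup in the pair
    contribute nothing; duplicates (two source paralogs mapping onto the
    same target gene) collapse.  The output's ``species`` column is the
    target species, while ``phenotype_species`` remembers where the
    phenotype was observed.
    """
    if source == target:
        raise ValueError("source and target species must differ")
    pair = canonical_pair(source, target)
    if pair not in omap.species_pairs:
        raise KeyError(f"no orthology loaded for pair {pair}")
    bad = assoc.species - {source}
    if bad:
        raise KeyError(f"association table contains unexpected species {bad}")
    rows, phen_species = [], []
    for rec in assoc.df.itertuples(index=False):
        gid = omap.group_of(source, rec.gene_id, target)
        if gid is None:
            continue
        for tgene in sorted(omap.group(source, target, gid).side(target)):
            rows.append((target, rec.phenotype_id, rec.phenotype_name, tgene))
            phen_species.append(rec.phenotype_species)
    return AssociationTable.from_records(
        rows, source_label=assoc.source_label, phenotype_species=phen_species
    )


def project_to_orthogroups(
    assoc: AssociationTable,
    species_a: str,
    species_b: str,
    omap: OrthologyMap,
) -> AssociationTable:
    """Project gene-level associations of either species onto orthogroups.

    A record (orthogroup, phenotype) is present iff at least one member gene
    on the phenotype's own species side carries the phenotype.  Genes outside
    any orthogroup of the pair are dropped.  The result is independent of
    the order in which the two species are given.
    """
    pair = canonical_pair(species_a, species_b)
    bad = assoc.species - set(pair)
    if bad:
        raise KeyError(f"association table contains species outside the pair: {bad}")
    rows, phen_species = [], []
    for rec in assoc.df.itertuples(index=False):
        other = pair[1] if rec.species == pair[0] else pair[0]
        gid = omap.group_of(rec.species, rec.gene_id, other)
        if gid is None:
            continue
        rows.append((rec.species, rec.phenotype_id, rec.phenotype_name, gid))
        phen_species.append(rec.phenotype_species)
    return AssociationTable.from_records(
        rows, source_label=assoc.source_label, phenotype_species=phen_species
    )
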
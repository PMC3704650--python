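"""Phenotype-phenotype overlap statistics and nearest-neighbor search.

Every comparison between two phenotypes reduces to four counts: v shared
elements, m elements of the target phenotype, n of the candidate neighbor,
and N elements in the universe they share.  All supported similarity and
distance measures are closed-form functions of (v, m, n, N) on 0/1
indicator vectors, so a single overlap computation yields every measure:

* hypergeom  — P(X >= v), the upper tail of Hypergeometric(N, m, n): the
  probability of an overlap at least as large by chance;
* pearson    — sample correlation of the indicator vectors, identical to
  the phi coefficient of the 2x2 contingency table;
* cosine     — v / sqrt(m n);
* tanimoto   — v / (m + n - v) (Jaccard on sets);
* euclidean  — sqrt(m + n - 2v);
* manhattan  — m + n - 2v.

Cross-species comparisons are made in the orthogroup space of the species
pair (direction-symmetric); within-species comparisons in the target
species' own gene space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd
from scipy import stats

from .orthology import (
    OrthologyMap,
    canonical_pair,
    project_to_orthogroups,
    translate_gene_based,
)
from .phenotypes import (
    AssociationTable,
    PhenotypeDescriptor,
    PhenotypeMatrix,
    build_matrix,
    filter_min_genes,
)

MEASURES = ("pearson", "cosine", "tanimoto", "euclidean", "manhattan", "hypergeom")

#: measures where a smaller value means a nearer neighbor
_ASCENDING = frozenset({"hypergeom", "euclidean", "manhattan"})


class UndefinedValueError(ValueError):
    """A measure is undefined for the given vectors (e.g. Pearson on a
    constant indicator)."""


def hypergeom_tail(v: int, m: int, n: int, N: int) -> float:
    """P(X >= v) for X ~ Hypergeometric(N, m, n).

    The chance that two random subsets of sizes m and n out of N elements
    share at least v elements.  Delegates to the survival function, which is
    numerically stable for extreme tails.
    """
    if not (0 <= m <= N and 0 <= n <= N):
        raise ValueError(f"require m,n <= N, got m={m} n={n} N={N}")
    if not (0 <= v <= min(m, n)):
        raise ValueError(f"require 0 <= v <= min(m,n), got v={v} m={m} n={n}")
    if m > n:  # the distribution is symmetric in (m, n); canonicalize so the
        m, n = n, m  # returned float is bit-identical under argument swap
    return float(stats.hypergeom.sf(v - 1, N, m, n))


def measure_from_counts(v: int, m: int, n: int, N: int, measure: str) -> float:
    """Any supported measure evaluated from the overlap counts alone."""
    if measure == "hypergeom":
        return hypergeom_tail(v, m, n, N)
    if measure == "pearson":
        denom = m * (N - m) * n * (N - n)
        if denom == 0:
            raise UndefinedValueError(
                f"pearson undefined for constant indicator (m={m}, n={n}, N={N})"
            )
        return (N * v - m * n) / math.sqrt(denom)
    if measure == "cosine":
        return v / math.sqrt(m * n) if m and n else 0.0
    if measure == "tanimoto":
        union = m + n - v
        return v / union if union else 0.0
    if measure == "euclidean":
        return math.sqrt(m + n - 2 * v)
    if measure == "manhattan":
        return float(m + n - 2 * v)
    raise KeyError(f"unknown measure {measure!r}")


def binary_similarity(
    x: Iterable[str], y: Iterable[str], universe: int, measure: str
) -> float:
    """Measure between two element sets within a universe of given size."""
    xs, ys = set(x), set(y)
    if universe < 1:
        raise ValueError("universe must be >= 1")
    if len(xs) > universe or len(ys) > universe:
        raise ValueError("set larger than universe")
    return measure_from_counts(len(xs & ys), len(xs), len(ys), universe, measure)


def nearness_key(measure: str, value: float) -> float:
    """Sort key under which smaller = nearer, uniformly across measures."""
    return value if measure in _ASCENDING else -value


@dataclass(frozen=True)
class PhenologScore:
    """Overlap record between a target phenotype and one neighbor.

    ``space`` identifies the element space of the comparison: a canonical
    species pair (orthogroup space) for cross-species neighbors, or
    ``("within", species)`` for same-species (paralogous) neighbors.
    ``neighbor_elements`` is the neighbor's column in that space, retained
    so classifiers can attribute scores to genes.
    """

    target: PhenotypeDescriptor
    neighbor: PhenotypeDescriptor
    space: tuple[str, str]
    v: int
    m: int
    n: int
    N: int
    distance_measure: str
    distance_value: float
    neighbor_elements: frozenset[str] = field(repr=False, default=frozenset())

    def measure(self, name: str) -> float:
        return measure_from_counts(self.v, self.m, self.n, self.N, name)

    @property
    def is_within_species(self) -> bool:
        return self.space[0] == "within"


@dataclass
class MatrixSet:
    """All phenotype matrices relevant to predicting one target species.

    ``within`` is the target species' own gene x phenotype matrix (used both
    for same-species neighbors and for flagging already-known genes).
    ``cross`` maps each species pair involving the target to a matrix whose
    columns are the phenotypes of both species, expressed in the pair's
    comparison space: orthogroups under the orthogroup framework, or
    target-species genes with orthologs under the gene-based framework.
    """

    target_species: str
    within: Optional[PhenotypeMatrix]
    cross: dict[tuple[str, str], PhenotypeMatrix]
    orthology: OrthologyMap
    framework: str = "orthogroup"

    def other_species(self, pair: tuple[str, str]) -> str:
        a, b = pair
        return b if a == self.target_species else a

    def phenotype_species(self, phenotype_id: str) -> Optional[str]:
        for mat in self.all_matrices():
            if phenotype_id in mat.columns:
                return mat.descriptor(phenotype_id).species
        return None

    def all_matrices(self) -> list[PhenotypeMatrix]:
        mats = list(self.cross.values())
        if self.within is not None:
            mats.append(self.within)
        return mats

    def has_phenotype(self, phenotype_id: str) -> bool:
        return any(phenotype_id in m.columns for m in self.all_matrices())

    def candidate_genes(self) -> tuple[str, ...]:
        """Target-species genes that can receive a score: any gene with an
        ortholog in some pair, plus any gene annotated within-species."""
        pool: set[str] = set()
        for pair in self.cross:
            pool |= self.orthology.genes_with_orthologs(
                self.target_species, self.other_species(pair)
            )
        if self.within is not None:
            pool |= set(self.within.elements)
        return tuple(sorted(pool))

    def mask_target(
        self, phenotype_id: str, hidden_gene: str
    ) -> tuple["MatrixSet", dict]:
        """Hide one gene — and every orthogroup containing it — from the
        target phenotype's column in all spaces.

        Returns the masked MatrixSet plus a record of what was hidden per
        space, used by the cross-validation leakage check.  In the
        within-species gene space, paralogs sharing an orthogroup with the
        hidden gene are masked too, mirroring the orthogroup-level hiding.
        """
        hidden_per_space: dict[tuple[str, str], frozenset[str]] = {}
        cross = {}
        paralogs = {hidden_gene}
        for pair, mat in self.cross.items():
            other = self.other_species(pair)
            gid = self.orthology.group_of(self.target_species, hidden_gene, other)
            if self.framework == "orthogroup":
                hidden = frozenset({gid}) if gid is not None else frozenset()
            else:  # gene framework: the pair space is target-species genes
                if gid is not None:
                    members = self.orthology.group(
                        self.target_species, other, gid
                    ).side(self.target_species)
                    hidden = frozenset(members)
                else:
                    hidden = frozenset({hidden_gene})
            if gid is not None:
                paralogs |= self.orthology.group(
                    self.target_species, other, gid
                ).side(self.target_species)
            hidden_per_space[pair] = hidden
            cross[pair] = mat.drop_from_column(phenotype_id, hidden)
        within = self.within
        if within is not None:
            hidden_per_space[("within", self.target_species)] = frozenset(paralogs)
            within = within.drop_from_column(phenotype_id, paralogs)
        masked = MatrixSet(
            target_species=self.target_species,
            within=within,
            cross=cross,
            orthology=self.orthology,
            framework=self.framework,
        )
        return masked, {
            "hidden_gene": hidden_gene,
            "hidden_per_space": hidden_per_space,
        }


def build_matrix_set(
    tables: dict[str, AssociationTable],
    orthology: OrthologyMap,
    target_species: str,
    framework: str = "orthogroup",
    min_genes: int = 3,
) -> MatrixSet:
    """Assemble the matrices needed to predict genes of ``target_species``.

    ``tables`` maps species name to its association table.  Phenotypes with
    fewer than ``min_genes`` distinct genes are removed first.  For each
    pair (target, other) with loaded orthology, a cross-species matrix is
    built in the chosen framework; the target species' own annotations also
    form the within-species gene matrix.
    """
    if framework not in ("orthogroup", "gene"):
        raise ValueError(f"unknown framework {framework!r}")
    if target_species not in tables:
        raise KeyError(f"no association table for target species {target_species!r}")
    filtered = {
        sp: filter_min_genes(t, min_genes) if min_genes > 1 else t
        for sp, t in tables.items()
    }
    # phenotype ids must be globally unique: columns from different species
    # would otherwise silently merge when matrices are assembled
    seen: dict[str, str] = {}
    for sp, t in filtered.items():
        for pid in t.phenotype_ids:
            if pid in seen and seen[pid] != sp:
                raise ValueError(
                    f"phenotype id {pid!r} appears in both {seen[pid]!r} and {sp!r}"
                )
            seen[pid] = sp

    target_table = filtered[target_species]
    within = (
        build_matrix(target_table, "genes", species=target_species)
        if len(target_table)
        else None
    )

    cross: dict[tuple[str, str], PhenotypeMatrix] = {}
    for other, table in filtered.items():
        if other == target_species:
            continue
        pair = canonical_pair(target_species, other)
        if pair not in orthology.species_pairs:
            continue
        if framework == "orthogroup":
            both = AssociationTable(
                pd.concat([target_table.df, table.df], ignore_index=True)
            )
            projected = project_to_orthogroups(both, *pair, orthology)
            universe = sorted(orthology.groups(*pair))
            cross[pair] = build_matrix(
                projected, "orthogroups", universe=universe, pair=pair
            )
        else:
            translated = translate_gene_based(table, other, target_species, orthology)
            universe = sorted(
                orthology.genes_with_orthologs(target_species, other)
            )
            both = AssociationTable(
                pd.concat([target_table.df, translated.df], ignore_index=True)
            )
            cross[pair] = build_matrix(
                both, "genes", universe=universe, species=target_species, pair=pair
            )
    return MatrixSet(
        target_species=target_species,
        within=within,
        cross=cross,
        orthology=orthology,
        framework=framework,
    )


def nearest_neighbors(
    matrix_set: MatrixSet,
    target_phenotype: str,
    k: int,
    distance_measure: str = "pearson",
    include_within_species: bool = True,
    species_subset: Optional[Iterable[str]] = None,
) -> list[PhenologScore]:
    """The k nearest neighbor phenotypes of the target, across all spaces.

    Each candidate is compared with the target in the element space the two
    phenotypes share.  Candidates for which the measure is undefined (a
    constant indicator under Pearson) are skipped.  Ordering is by nearness
    then by (species, phenotype id); the target itself is never a neighbor.
    Returns fewer than k scores when fewer candidates exist.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if distance_measure not in MEASURES:
        raise KeyError(f"unknown measure {distance_measure!r}")
    if not matrix_set.has_phenotype(target_phenotype):
        raise KeyError(f"unknown phenotype {target_phenotype!r}")
    subset = set(species_subset) if species_subset is not None else None

    scored: list[PhenologScore] = []
    for pair, mat in matrix_set.cross.items():
        if target_phenotype not in mat.columns:
            continue
        other = matrix_set.other_species(pair)
        if subset is not None and other not in subset:
            continue
        target_col = mat.column(target_phenotype)
        target_desc = mat.descriptor(target_phenotype)
        if not target_col:
            continue
        for p in mat.phenotypes:
            if p.species != other or p.id == target_phenotype:
                continue
            scored.extend(
                _score_one(mat, target_desc, target_col, p, pair, distance_measure)
            )
    if include_within_species and matrix_set.within is not None and (
        subset is None or matrix_set.target_species in subset
    ):
        mat = matrix_set.within
        if target_phenotype in mat.columns:
            target_col = mat.column(target_phenotype)
            target_desc = mat.descriptor(target_phenotype)
            if target_col:
                space = ("within", matrix_set.target_species)
                for p in mat.phenotypes:
                    if p.id == target_phenotype:
                        continue
                    scored.extend(
                        _score_one(
                            mat, target_desc, target_col, p, space, distance_measure
                        )
                    )
    scored.sort(
        key=lambda s: (
            nearness_key(s.distance_measure, s.distance_value),
            s.neighbor.species,
            s.neighbor.id,
        )
    )
    return scored[:k]


def _score_one(mat, target_desc, target_col, neighbor_desc, space, measure):
    col = mat.column(neighbor_desc.id)
    if not col:
        return []
    v = len(target_col & col)
    m, n, N = len(target_col), len(col), mat.n_elements
    try:
        value = measure_from_counts(v, m, n, N, measure)
    except UndefinedValueError:
        return []
    return [
        PhenologScore(
            target=target_desc,
            neighbor=neighbor_desc,
            space=space,
            v=v,
            m=m,
            n=n,
            N=N,
            distance_measure=measure,
            distance_value=value,
            neighbor_elements=col,
        )
    ]
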
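"""Synthetic multi-species orthology and phenotype fixtures.

The generator plants the structure the phenolog method assumes: a set of
ancestral genes (orthogroups) shared across species, a handful of conserved
functional modules — groups of orthogroups that tend to be disrupted
together — and per-species phenotypes whose gene sets are drawn partly
from one module (the signal) and partly at random (the noise).  Two
phenotypes planted on the same module in different species are true
phenologs; background phenotypes drawn entirely at random are not.

Lineage history is emulated with two knobs per species: a retention
probability (an orthogroup may have been lost in a lineage) and a
geometric paralog count with mean >= 1 (heavy-tailed family expansions, as
seen in plant genomes where over a third of proteins belong to sizeable
families).  Pairwise orthology is derived from the shared ancestral
orthogroup id, so a gene belongs to at most one orthogroup per species
pair, consistently across all pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .orthology import Orthogroup, OrthologyMap, canonical_pair
from .phenotypes import ASSOC_COLUMNS, AssociationTable


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic benchmark.

    Defaults describe a four-species benchmark with 500 ancestral
    orthogroups, five conserved modules of 20 orthogroups, six phenotypes
    per module per species whose gene sets are 60% module-derived, and
    phenotype sizes of 5-15 genes — enough planted structure for phenolog
    search to find, with realistic noise around it.
    """

    species: tuple[str, ...] = ("human", "mouse", "worm", "yeast")
    n_orthogroups: int = 500
    expansion_mean: float = 2.0
    ortholog_retention: float = 0.8
    n_modules: int = 5
    module_size: int = 20
    phenotypes_per_module: int = 6
    signal_fraction: float = 0.6
    background_phenotypes: int = 10
    phenotype_size_range: tuple[int, int] = (5, 15)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.species) < 2:
            raise ValueError("need at least two species")
        if not 0.0 <= self.ortholog_retention <= 1.0:
            raise ValueError("ortholog_retention must be a probability")
        if not 0.0 <= self.signal_fraction <= 1.0:
            raise ValueError("signal_fraction must be in [0,1]")
        if self.expansion_mean < 1.0:
            raise ValueError("expansion_mean must be >= 1")
        lo, hi = self.phenotype_size_range
        if lo < 3 or hi < lo:
            raise ValueError("phenotype sizes must satisfy 3 <= min <= max")
        if self.n_modules * self.module_size > self.n_orthogroups:
            raise ValueError("modules cannot cover more orthogroups than exist")
        if math.ceil(self.signal_fraction * hi) > self.module_size:
            raise ValueError(
                "module_size too small for the largest signal draw "
                f"(need {math.ceil(self.signal_fraction * hi)})"
            )


@dataclass
class SynthTruth:
    """Ground truth behind a generated dataset.

    ``genes``: one row per gene (species, gene_id, orthogroup).
    ``modules``: orthogroup -> module assignment (NaN for unassigned).
    ``phenotypes``: phenotype_id, species, module (NaN for background), size.
    """

    genes: pd.DataFrame
    modules: pd.DataFrame
    phenotypes: pd.DataFrame

    def to_tsv(self, directory) -> None:
        directory = Path(directory)
        self.genes.to_csv(directory / "truth_genes.tsv", sep="\t", index=False)
        self.modules.to_csv(directory / "truth_modules.tsv", sep="\t", index=False)
        self.phenotypes.to_csv(
            directory / "truth_phenotypes.tsv", sep="\t", index=False
        )


@dataclass
class SynthData:
    """In-memory result of :func:`generate`, with TSV writers matching the
    dialects the orthology and phenotypes readers consume."""

    config: SynthConfig
    orthology: OrthologyMap
    associations: dict[str, AssociationTable]
    truth: SynthTruth

    def write(self, directory) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        species = self.config.species
        for i, a in enumerate(species):
            for b in species[i + 1 :]:
                pair = canonical_pair(a, b)
                rows = []
                for gid, grp in sorted(self.orthology.groups(*pair).items()):
                    for sp in pair:
                        for gene in sorted(grp.side(sp)):
                            rows.append((gid, sp, gene))
                path = directory / f"orthology_{pair[0]}_{pair[1]}.tsv"
                pd.DataFrame(
                    rows, columns=["orthogroup_id", "species", "gene_id"]
                ).to_csv(path, sep="\t", index=False, header=False)
                paths[f"orthology:{pair[0]}-{pair[1]}"] = path
        for sp, table in sorted(self.associations.items()):
            path = directory / f"associations_{sp}.tsv"
            df = table.df[ASSOC_COLUMNS].sort_values(ASSOC_COLUMNS)
            df.to_csv(path, sep="\t", index=False)
            paths[f"associations:{sp}"] = path
        self.truth.to_tsv(directory)
        return paths


def generate(config: SynthConfig = SynthConfig()) -> SynthData:
    """Generate orthology + gene-phenotype fixtures with planted phenologs.

    Deterministic under ``config.seed``: the same configuration always
    yields byte-identical files from :meth:`SynthData.write`.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.phenotype_size_range

    # --- gene complements: per species, which orthogroups survive and how
    # many paralogs each carries
    gene_rows = []
    members: dict[tuple[str, int], list[str]] = {}
    p_geom = 1.0 / config.expansion_mean
    for sp in config.species:
        for og in range(config.n_orthogroups):
            if rng.random() > config.ortholog_retention:
                continue
            n_paralogs = int(rng.geometric(p_geom))
            genes = [f"{sp}_g{og:04d}_{i}" for i in range(n_paralogs)]
            members[(sp, og)] = genes
            for g in genes:
                gene_rows.append((sp, g, f"OG{og:04d}"))

    # --- pairwise orthology from the shared ancestral orthogroup
    groups = []
    for i, a in enumerate(config.species):
        for b in config.species[i + 1 :]:
            pair = canonical_pair(a, b)
            for og in range(config.n_orthogroups):
                ga, gb = members.get((a, og)), members.get((b, og))
                if ga and gb:
                    groups.append(
                        Orthogroup(
                            id=f"OG{og:04d}",
                            species_pair=pair,
                            members={pair[0]: frozenset(members[(pair[0], og)]),
                                     pair[1]: frozenset(members[(pair[1], og)])},
                        )
                    )
    orthology = OrthologyMap(groups)

    # --- conserved modules: disjoint blocks of orthogroups
    perm = rng.permutation(config.n_orthogroups)
    module_of: dict[int, int] = {}
    for mod in range(config.n_modules):
        block = perm[mod * config.module_size : (mod + 1) * config.module_size]
        for og in block:
            module_of[int(og)] = mod

    # --- phenotypes
    phen_rows: dict[str, list[tuple]] = {sp: [] for sp in config.species}
    truth_phen = []
    for sp in config.species:
        sp_genes = sorted(g for s, g, _ in gene_rows if s == sp)
        for mod in range(config.n_modules):
            mod_ogs = sorted(og for og, m in module_of.items() if m == mod)
            available = [og for og in mod_ogs if (sp, og) in members]
            for idx in range(config.phenotypes_per_module):
                size = int(rng.integers(lo, hi + 1))
                n_sig = min(math.ceil(config.signal_fraction * size), len(available))
                chosen_ogs = rng.choice(available, size=n_sig, replace=False)
                chosen = {
                    str(rng.choice(members[(sp, int(og))])) for og in chosen_ogs
                }
                rest = [g for g in sp_genes if g not in chosen]
                n_noise = min(size - len(chosen), len(rest))
                if n_noise > 0:
                    chosen |= set(
                        str(g) for g in rng.choice(rest, size=n_noise, replace=False)
                    )
                pid = f"{sp}:M{mod}:P{idx}"
                name = f"{sp} module-{mod} phenotype {idx}"
                for g in sorted(chosen):
                    phen_rows[sp].append((sp, pid, name, g))
                truth_phen.append((pid, sp, mod, len(chosen)))
        for idx in range(config.background_phenotypes):
            size = int(rng.integers(lo, hi + 1))
            chosen = rng.choice(sp_genes, size=min(size, len(sp_genes)), replace=False)
            pid = f"{sp}:BG:P{idx}"
            name = f"{sp} background phenotype {idx}"
            for g in sorted(str(g) for g in chosen):
                phen_rows[sp].append((sp, pid, name, g))
            truth_phen.append((pid, sp, None, len(chosen)))

    associations = {
        sp: AssociationTable.from_records(rows, source_label="synthetic")
        for sp, rows in phen_rows.items()
    }
    truth = SynthTruth(
        genes=pd.DataFrame(gene_rows, columns=["species", "gene_id", "orthogroup"]),
        modules=pd.DataFrame(
            [(f"OG{og:04d}", module_of.get(og)) for og in range(config.n_orthogroups)],
            columns=["orthogroup", "module"],
        ),
        phenotypes=pd.DataFrame(
            truth_phen, columns=["phenotype_id", "species", "module", "size"]
        ),
    )
    return SynthData(
        config=config, orthology=orthology, associations=associations, truth=truth
    )


def summarize(truth: SynthTruth) -> pd.DataFrame:
    """Per-species gene/orthogroup counts and mean paralogs per orthogroup."""
    rows = []
    for sp, grp in truth.genes.groupby("species"):
        n_genes = len(grp)
        n_ogs = grp["orthogroup"].nunique()
        rows.append((sp, n_genes, n_ogs, n_genes / n_ogs if n_ogs else float("nan")))
    return pd.DataFrame(
        rows, columns=["species", "n_genes", "n_orthogroups", "mean_paralogs"]
    )
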
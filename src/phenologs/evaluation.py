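"""Cross-validation harnesses and the randomized-matrix control.

Two evaluation schemes:

* leave-one-out — for each phenotype, hide one known gene together with
  every orthogroup containing it, re-run the neighbor search and scoring on
  the masked data, and record the rank at which the hidden gene is
  recovered (mean rank over score ties).  Repeated with different hidden
  genes; the median hidden-gene rank summarises the phenotype.
* n-fold — known genes split across folds; withheld genes are positives,
  every other ranked gene a negative; per-phenotype ROC and precision-
  recall curves and areas.

The randomized-matrix control redraws each phenotype column uniformly at
the same cardinality, destroying the orthology structure while preserving
the size distribution; real data should beat it decisively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from sklearn.metrics import auc, precision_recall_curve, roc_auc_score, roc_curve

from .classifiers import PredictionList, WeightingSpec, predict
from .phenotypes import PhenotypeMatrix
from .similarity import MatrixSet

logger = logging.getLogger(__name__)


@dataclass
class CVReport:
    """Leave-one-out results: one row per (phenotype, repeat, hidden gene).

    ``records`` columns: phenotype, repeat, hidden_gene, rank, pool_size.
    ``fold_details`` (optional) retains per-fold masking info and neighbor
    scores for auditing that no hidden element leaked into the overlaps.
    """

    records: pd.DataFrame
    spec: WeightingSpec
    seed: int
    repeats: int
    fold_details: list[dict] = field(default_factory=list, repr=False)

    @property
    def medians(self) -> pd.Series:
        """Median hidden-gene rank per phenotype over the repeats."""
        if self.records.empty:
            return pd.Series(dtype=float, name="median_rank")
        med = self.records.groupby("phenotype")["rank"].median()
        med.name = "median_rank"
        return med

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def _fallback_rank(prediction_list: PredictionList) -> float:
    """Rank convention for a hidden gene absent from the candidate pool:
    the mean rank it would share with the zero-score group if appended."""
    scores = np.array([p.score for p in prediction_list.predictions])
    pool = len(scores)
    n_zero = int((scores == 0.0).sum())
    # zero group occupies ranks (pool - n_zero + 1) .. (pool + 1) once extended
    return (pool - n_zero + 1 + pool + 1) / 2.0


def loocv(
    matrix_set: MatrixSet,
    spec: WeightingSpec = WeightingSpec(),
    repeats: int = 3,
    seed: int = 0,
    phenotypes: Optional[Iterable[str]] = None,
    species_subset: Optional[Iterable[str]] = None,
    collect_details: bool = False,
) -> CVReport:
    """Orthogroup-aware leave-one-out cross-validation.

    For each evaluated phenotype (all target-species phenotypes with at
    least two known genes unless ``phenotypes`` narrows the list) and each
    repeat, one associated gene is drawn with a seeded generator, masked
    out of the phenotype's column in every comparison space along with all
    orthogroups containing it, and its recovered rank recorded.  Distinct
    genes are hidden across repeats where the phenotype is large enough.
    """
    if matrix_set.within is None:
        raise ValueError("target species has no annotated phenotypes to evaluate")
    rng = np.random.default_rng(seed)
    if phenotypes is None:
        phenotypes = matrix_set.within.phenotype_ids
    rows = []
    details: list[dict] = []
    for pid in phenotypes:
        column = sorted(matrix_set.within.column(pid))
        if len(column) < 2:
            logger.info("loocv: skipping %s (fewer than 2 genes)", pid)
            continue
        if len(column) >= repeats:
            hidden_genes = list(rng.choice(column, size=repeats, replace=False))
        else:
            hidden_genes = list(column)
            while len(hidden_genes) < repeats:
                hidden_genes.append(str(rng.choice(column)))
        for rep, hidden in enumerate(hidden_genes):
            masked, mask_info = matrix_set.mask_target(pid, hidden)
            plist = predict(pid, masked, spec, species_subset=species_subset)
            rank = plist.rank_of(hidden)
            if rank is None:
                rank = _fallback_rank(plist)
            rows.append((pid, rep, hidden, float(rank), len(plist)))
            if collect_details:
                details.append(
                    {
                        "phenotype": pid,
                        "repeat": rep,
                        "mask": mask_info,
                        "neighbors": plist.neighbors,
                        "masked_set": masked,
                    }
                )
    records = pd.DataFrame(
        rows, columns=["phenotype", "repeat", "hidden_gene", "rank", "pool_size"]
    )
    return CVReport(
        records=records,
        spec=spec,
        seed=seed,
        repeats=repeats,
        fold_details=details,
    )


def rank_auroc(report: CVReport) -> float:
    """Mean per-fold AUROC implied by the recovered ranks.

    With a single withheld positive at (mean) rank r out of a pool of P
    ranked genes, the ROC area equals (P - r) / (P - 1); averaging over
    folds summarises how far above the bulk the hidden genes sit (0.5 is
    chance level)."""
    rec = report.records
    if rec.empty:
        return float("nan")
    vals = (rec["pool_size"] - rec["rank"]) / (rec["pool_size"] - 1)
    return float(vals.mean())


def recovery_curve(report: CVReport, max_rank: int) -> pd.DataFrame:
    """How many phenotypes have median hidden-gene rank <= r, for r=1..max_rank."""
    med = report.medians
    rs = np.arange(1, max_rank + 1)
    counts = [(med <= r).sum() for r in rs]
    return pd.DataFrame({"rank": rs, "phenotypes_recovered": counts})


def nfold_cv(
    matrix_set: MatrixSet,
    spec: WeightingSpec = WeightingSpec(),
    folds: int = 5,
    min_phenotype_size: int = 4,
    seed: int = 0,
    phenotypes: Optional[Iterable[str]] = None,
    species_subset: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """n-fold cross-validation with per-phenotype ROC and precision-recall.

    Each phenotype's known genes are shuffled into ``folds`` folds; per
    fold, the whole fold (and the orthogroups of its genes) is hidden from
    the phenotype column, genes are re-scored, and the withheld genes
    become positives against all other ranked genes.  Returns one row per
    phenotype with AUROC and area under the PR curve; the full curves are
    stored in ``DataFrame.attrs["curves"]``.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if matrix_set.within is None:
        raise ValueError("target species has no annotated phenotypes to evaluate")
    rng = np.random.default_rng(seed)
    if phenotypes is None:
        phenotypes = matrix_set.within.phenotype_ids
    rows = []
    curves: dict[str, dict] = {}
    for pid in phenotypes:
        column = sorted(matrix_set.within.column(pid))
        if len(column) < min_phenotype_size:
            continue
        perm = list(rng.permutation(column))
        fold_slices = np.array_split(perm, folds)
        scores: list[float] = []
        labels: list[int] = []
        for fold_genes in fold_slices:
            if len(fold_genes) == 0:
                continue
            masked = matrix_set
            for g in fold_genes:
                masked, _ = masked.mask_target(pid, str(g))
            plist = predict(pid, masked, spec, species_subset=species_subset)
            held = set(str(g) for g in fold_genes)
            for pred in plist.predictions:
                scores.append(pred.score)
                labels.append(1 if pred.gene_id in held else 0)
        if sum(labels) == 0 or sum(labels) == len(labels):
            continue
        y, s = np.array(labels), np.array(scores)
        auroc = roc_auc_score(y, s)
        prec, rec, _ = precision_recall_curve(y, s)
        aupr = auc(rec, prec)
        fpr, tpr, _ = roc_curve(y, s)
        curves[pid] = {"fpr": fpr, "tpr": tpr, "precision": prec, "recall": rec}
        rows.append((pid, len(column), float(auroc), float(aupr)))
    out = pd.DataFrame(rows, columns=["phenotype", "n_genes", "auroc", "aupr"])
    out.attrs["curves"] = curves
    return out


def randomize_matrix(matrix: PhenotypeMatrix, seed: int = 0) -> PhenotypeMatrix:
    """Null control: redraw every column uniformly at its own cardinality.

    Column sizes are preserved exactly, so any performance on the
    randomized matrix reflects cardinality structure alone, not biology.
    """
    rng = np.random.default_rng(seed)
    elements = list(matrix.elements)
    cols = {}
    for p in matrix.phenotypes:
        card = len(matrix.columns[p.id])
        drawn = rng.choice(elements, size=card, replace=False)
        cols[p.id] = frozenset(str(e) for e in drawn)
    return PhenotypeMatrix(
        element_kind=matrix.element_kind,
        elements=matrix.elements,
        phenotypes=matrix.phenotypes,
        columns=cols,
        species=matrix.species,
        pair=matrix.pair,
    )


def randomize_matrix_set(matrix_set: MatrixSet, seed: int = 0) -> MatrixSet:
    """Apply :func:`randomize_matrix` to every matrix of a MatrixSet, with
    independent seeded draws per matrix."""
    rng = np.random.default_rng(seed)
    cross = {
        pair: randomize_matrix(mat, seed=int(rng.integers(2**31)))
        for pair, mat in sorted(matrix_set.cross.items())
    }
    within = (
        randomize_matrix(matrix_set.within, seed=int(rng.integers(2**31)))
        if matrix_set.within is not None
        else None
    )
    return MatrixSet(
        target_species=matrix_set.target_species,
        within=within,
        cross=cross,
        orthology=matrix_set.orthology,
        framework=matrix_set.framework,
    )


def species_ablation(
    matrix_set: MatrixSet,
    spec: WeightingSpec,
    subsets: list[Iterable[str]],
    repeats: int = 3,
    seed: int = 0,
    max_rank: int = 100,
    phenotypes: Optional[Iterable[str]] = None,
) -> dict[tuple[str, ...], pd.DataFrame]:
    """Leave-one-out recovery curves with neighbors restricted to species
    subsets, to attribute predictive power to individual source datasets.

    All subsets are evaluated on the same phenotype list (and the same
    seed, hence the same hidden genes), so curves are directly comparable.
    """
    known_species = {matrix_set.target_species} | {
        matrix_set.other_species(pair) for pair in matrix_set.cross
    }
    curves = {}
    for subset in subsets:
        sub = tuple(sorted(set(subset)))
        if not sub:
            raise ValueError("species subset must be nonempty")
        unknown = set(sub) - known_species
        if unknown:
            raise KeyError(f"unknown species in subset: {sorted(unknown)}")
        report = loocv(
            matrix_set,
            spec,
            repeats=repeats,
            seed=seed,
            phenotypes=phenotypes,
            species_subset=sub,
        )
        curves[sub] = recovery_curve(report, max_rank)
    return curves


def plot_recovery(
    curves: dict[str, pd.DataFrame], ax=None, title: str = "Recovery of withheld genes"
):
    """Plot one or more recovery curves (label -> curve table)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        ax.step(
            curve["rank"], curve["phenotypes_recovered"], where="post", label=label
        )
    ax.set_xlabel("rank threshold r")
    ax.set_ylabel("phenotypes with median hidden rank <= r")
    ax.set_title(title)
    ax.legend()
    return ax
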
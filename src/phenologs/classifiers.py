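"""Integration of k nearest phenologs into per-gene prediction scores.

Two schemes combine the evidence from the neighbor phenotypes:

* naive Bayes (multiplicative):  X_i = 1 - prod_l (1 - f_l * w_l) over the
  neighbors l whose column contains element i, treating each neighbor as an
  independent noisy predictor.  f_l = v/m is the fraction of the target
  phenotype's elements shared with neighbor l — an empirical estimate of
  the precision of that single phenolog — and w_l in [0,1] is a weight
  derived from the phenotype-phenotype similarity.
* additive:  X_i = sum_l w_l * Phi_il, the incidence matrix times the
  weight vector.  Scores are not probabilities but decompose exactly into
  per-neighbor contributions, which makes predictions easy to inspect.

Cross-species neighbors score orthogroups; a target-species gene inherits
the contribution of every orthogroup it belongs to (at most one per
species pair).  Within-species (paralogous-phenotype) neighbors score
genes directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .similarity import MEASURES, MatrixSet, PhenologScore, nearest_neighbors

_CLASSIFIERS = ("naive_bayes", "additive")


@dataclass(frozen=True)
class WeightingSpec:
    """Configuration of a phenolog search: how neighbors are found, weighted
    and combined.

    The default pairing — Pearson correlation to rank neighbors,
    hypergeometric tail to weight them — is the best-performing combination
    for the naive Bayes scheme; all pairings are available.
    ``f_denominator`` selects whether f divides the shared count by the
    target's cardinality ("target", the documented choice) or the
    neighbor's ("neighbor").
    """

    distance_measure: str = "pearson"
    weight_measure: str = "hypergeom"
    k: int = 40
    classifier: str = "naive_bayes"
    include_within_species: bool = True
    f_denominator: str = "target"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        for meas in (self.distance_measure, self.weight_measure):
            if meas not in MEASURES:
                raise KeyError(f"unknown measure {meas!r}")
        if self.classifier not in _CLASSIFIERS:
            raise KeyError(f"unknown classifier {self.classifier!r}")
        if self.f_denominator not in ("target", "neighbor"):
            raise ValueError("f_denominator must be 'target' or 'neighbor'")


@dataclass(frozen=True)
class Contribution:
    """One neighbor phenotype's input to one gene's score."""

    neighbor_id: str
    neighbor_species: str
    f: float
    w: float
    term: float  # w for additive, f*w for naive Bayes


@dataclass(frozen=True)
class Prediction:
    gene_id: str
    score: float
    known: bool
    contributions: tuple[Contribution, ...] = field(repr=False, default=())


@dataclass
class PredictionList:
    """Ranked candidate genes for one target phenotype.

    Predictions are ordered by non-increasing score (ties broken by gene
    id for determinism); ``ranks`` assigns tied scores their mean rank, so
    the ranks always sum to P(P+1)/2.
    """

    target_phenotype: str
    spec: WeightingSpec
    predictions: tuple[Prediction, ...]
    neighbors: tuple[PhenologScore, ...]
    ranks: np.ndarray

    def __len__(self) -> int:
        return len(self.predictions)

    def rank_of(self, gene_id: str) -> Optional[float]:
        for pred, rank in zip(self.predictions, self.ranks):
            if pred.gene_id == gene_id:
                return float(rank)
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pred, rank in zip(self.predictions, self.ranks):
            top = ";".join(
                f"{c.neighbor_id}" for c in pred.contributions[:3]
            )
            rows.append(
                (rank, pred.gene_id, float(f"{pred.score:.6g}"), pred.known, top)
            )
        return pd.DataFrame(
            rows, columns=["rank", "gene_id", "score", "known", "top_phenotypes"]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def fraction_f(v: int, n_target: int) -> float:
    """Fraction of the target phenotype's elements shared with a neighbor —
    the empirical precision of that single phenolog as a predictor."""
    if n_target < 1:
        raise ValueError("target cardinality must be >= 1")
    if not 0 <= v <= n_target:
        raise ValueError(f"require 0 <= v <= n_target, got v={v} n={n_target}")
    return v / n_target


def weight_from_measure(value: float, measure: str) -> float:
    """Map a similarity/distance value onto a weight in [0, 1].

    Small hypergeometric tails (significant overlaps) map near 1; negative
    correlations clamp to 0; bounded similarities pass through; unbounded
    distances shrink as 1/(1+d).
    """
    if measure == "hypergeom":
        return 1.0 - value
    if measure == "pearson":
        return max(value, 0.0)
    if measure in ("cosine", "tanimoto"):
        return float(value)
    if measure in ("euclidean", "manhattan"):
        return 1.0 / (1.0 + value)
    raise KeyError(f"unknown measure {measure!r}")


def score_additive(
    neighbors: Iterable[tuple[frozenset[str], float]]
) -> dict[str, float]:
    """X_i = sum_l w_l * Phi_il over neighbor columns."""
    scores: dict[str, float] = {}
    for column, w in neighbors:
        if w < 0:
            raise ValueError("additive weights must be non-negative")
        for el in column:
            scores[el] = scores.get(el, 0.0) + w
    return scores


def score_naive_bayes(
    neighbors: Iterable[tuple[frozenset[str], float, float]]
) -> dict[str, float]:
    """X_i = 1 - prod_l (1 - f_l w_l) over neighbors containing element i."""
    survival: dict[str, float] = {}
    for column, f, w in neighbors:
        if not (0.0 <= f <= 1.0 and 0.0 <= w <= 1.0):
            raise ValueError("f and w must lie in [0, 1]")
        for el in column:
            survival[el] = survival.get(el, 1.0) * (1.0 - f * w)
    return {el: 1.0 - s for el, s in survival.items()}


def predict(
    target_phenotype: str,
    matrix_set: MatrixSet,
    spec: WeightingSpec = WeightingSpec(),
    species_subset: Optional[Iterable[str]] = None,
    neighbors: Optional[Sequence[PhenologScore]] = None,
) -> PredictionList:
    """Rank target-species genes for a phenotype from its k nearest phenologs.

    Finds the neighbors (unless pre-computed ones are supplied), converts
    each neighbor's overlap into (f, w), expands orthogroup-level columns to
    target-species genes, and combines contributions with the configured
    classifier.  Every gene in the candidate pool appears in the output;
    genes untouched by any neighbor score 0 and share the bottom ranks.
    Genes already associated with the target (or sharing an orthogroup with
    one) are flagged as known but retained.
    """
    if neighbors is None:
        neighbors = nearest_neighbors(
            matrix_set,
            target_phenotype,
            k=spec.k,
            distance_measure=spec.distance_measure,
            include_within_species=spec.include_within_species,
            species_subset=species_subset,
        )

    per_gene: dict[str, list[Contribution]] = {}
    for ns in neighbors:
        denom = ns.m if spec.f_denominator == "target" else ns.n
        f = fraction_f(ns.v, denom) if denom else 0.0
        w = weight_from_measure(ns.measure(spec.weight_measure), spec.weight_measure)
        term = w if spec.classifier == "additive" else f * w
        contrib = Contribution(
            neighbor_id=ns.neighbor.id,
            neighbor_species=ns.neighbor.species,
            f=f,
            w=w,
            term=term,
        )
        for gene in _genes_of_column(ns, matrix_set):
            per_gene.setdefault(gene, []).append(contrib)

    pool = matrix_set.candidate_genes()
    scores = np.zeros(len(pool))
    gene_pos = {g: i for i, g in enumerate(pool)}
    for gene, contribs in per_gene.items():
        if gene not in gene_pos:
            continue
        if spec.classifier == "additive":
            scores[gene_pos[gene]] = sum(c.w for c in contribs)
        else:
            prod = 1.0
            for c in contribs:
                prod *= 1.0 - c.f * c.w
            scores[gene_pos[gene]] = 1.0 - prod

    known = _known_genes(target_phenotype, matrix_set)
    order = sorted(range(len(pool)), key=lambda i: (-scores[i], pool[i]))
    ordered_scores = scores[order]
    ranks = rankdata(-ordered_scores, method="average")
    predictions = tuple(
        Prediction(
            gene_id=pool[i],
            score=float(scores[i]),
            known=pool[i] in known,
            contributions=tuple(
                sorted(
                    per_gene.get(pool[i], ()), key=lambda c: (-c.term, c.neighbor_id)
                )
            ),
        )
        for i in order
    )
    return PredictionList(
        target_phenotype=target_phenotype,
        spec=spec,
        predictions=predictions,
        neighbors=tuple(neighbors),
        ranks=ranks,
    )


def _genes_of_column(ns: PhenologScore, matrix_set: MatrixSet) -> frozenset[str]:
    """Target-species genes reached by one neighbor's column."""
    if ns.is_within_species:
        return ns.neighbor_elements
    if matrix_set.framework == "gene":
        return ns.neighbor_elements  # already target-species genes
    pair = ns.space
    target_sp = matrix_set.target_species
    other = matrix_set.other_species(pair)
    genes: set[str] = set()
    for gid in ns.neighbor_elements:
        genes |= matrix_set.orthology.group(target_sp, other, gid).side(target_sp)
    return frozenset(genes)


def _known_genes(target_phenotype: str, matrix_set: MatrixSet) -> frozenset[str]:
    """Genes already associated with the target, or in an orthogroup that is."""
    known: set[str] = set()
    if matrix_set.within is not None and target_phenotype in matrix_set.within.columns:
        known |= matrix_set.within.column(target_phenotype)
    target_sp = matrix_set.target_species
    for pair, mat in matrix_set.cross.items():
        if target_phenotype not in mat.columns:
            continue
        other = matrix_set.other_species(pair)
        if matrix_set.framework == "gene":
            known |= mat.column(target_phenotype)
        else:
            for gid in mat.column(target_phenotype):
                known |= matrix_set.orthology.group(target_sp, other, gid).side(
                    target_sp
                )
    return frozenset(known)


def decompose(
    predictions: PredictionList, top_n_phenotypes: int = 20
) -> pd.DataFrame:
    """Per-gene contribution table: one column per top-n neighbor phenotype
    plus a remainder bucket aggregating the rest.

    Exact for the additive classifier (rows sum to the scores); for naive
    Bayes the entries are the f*w factors, whose combination is
    multiplicative — the table is still emitted, flagged via the
    ``additive`` attribute in ``DataFrame.attrs``.
    """
    top_ids = [ns.neighbor.id for ns in predictions.neighbors[:top_n_phenotypes]]
    remainder_label = f"below top-{top_n_phenotypes} phenotypes"
    has_remainder = len(predictions.neighbors) > top_n_phenotypes
    cols = top_ids + ([remainder_label] if has_remainder else [])
    rows = {}
    for pred in predictions.predictions:
        if not pred.contributions:
            continue
        row = dict.fromkeys(cols, 0.0)
        for c in pred.contributions:
            key = c.neighbor_id if c.neighbor_id in row else remainder_label
            row[key] += c.term
        rows[pred.gene_id] = row
    out = pd.DataFrame.from_dict(rows, orient="index", columns=cols).fillna(0.0)
    out.attrs["additive"] = predictions.spec.classifier == "additive"
    return out
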
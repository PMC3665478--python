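"""GO ancestor closure and the disease/neutral log-odds functional score.

A protein's functional signal enters the classifier as two numbers: the sum,
over its annotation closure, of per-term log2 odds of Disease versus Neutral
training variants (pseudocount-smoothed), and the number of GO terms in that
closure.  Proteins without annotation contribute the fixed (0, 0) fallback.
Term statistics are fitted per training fold and guarded against leakage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .errors import IntegrityError, LookupFailure, TrainingError
from .io_formats import DatasetTable, GoGraph
from .profiles import saturation_scale

GO_COUNT_SCALE_K = 100.0


def ancestor_closure(
    graph: GoGraph,
    terms: set[str],
    relations: tuple[str, ...] = ("is_a", "part_of"),
) -> set[str]:
    """Terms plus all ancestors reachable via is_a/part_of edges.

    Obsolete terms are dropped from the closure; unknown ids raise.
    """
    unknown = terms - graph.terms
    if unknown:
        raise LookupFailure(f"unknown GO term ids: {sorted(unknown)}")
    closure: set[str] = set()
    stack = list(terms)
    while stack:
        term = stack.pop()
        if term in closure:
            continue
        closure.add(term)
        stack.extend(graph.parents(term, relations))
    return closure - set(graph.obsolete)


@dataclass
class GoTermStats:
    """Per-term Disease/Neutral training-variant counts (variants, not proteins)."""

    d_t: dict[str, int]
    n_t: dict[str, int]
    d_tot: int
    n_tot: int
    pseudocount: float = 1.0
    fitted_fold: Optional[int] = None
    fitted_proteins: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        for t, d in self.d_t.items():
            if d > self.d_tot:
                raise IntegrityError(f"term {t}: d_t exceeds D_tot")
        for t, n in self.n_t.items():
            if n > self.n_tot:
                raise IntegrityError(f"term {t}: n_t exceeds N_tot")

    def term_log_odds(self, term: str) -> float:
        """log2 of smoothed Disease vs Neutral odds; unseen terms count 0/0."""
        pi = self.pseudocount
        d = self.d_t.get(term, 0)
        n = self.n_t.get(term, 0)
        return math.log2(
            ((d + pi) / (self.d_tot + 2 * pi)) / ((n + pi) / (self.n_tot + 2 * pi))
        )


def fit_term_stats(
    train: DatasetTable,
    annotations: dict[str, set[str]],
    graph: GoGraph,
    pseudocount: float = 1.0,
    relations: tuple[str, ...] = ("is_a", "part_of"),
    fitted_fold: Optional[int] = None,
) -> GoTermStats:
    """Count Disease/Neutral training variants per GO term over closures.

    Each labeled variant adds 1 to every term in its protein's annotation
    closure; proteins without annotation contribute only to the class totals.
    """
    if not train.records:
        raise TrainingError("cannot fit GO term statistics on an empty training set")
    closures: dict[str, set[str]] = {}
    for pid in train.proteins():
        closures[pid] = ancestor_closure(graph, annotations.get(pid, set()), relations)
    d_t: dict[str, int] = {}
    n_t: dict[str, int] = {}
    d_tot = n_tot = 0
    for rec in train.records:
        if rec.label == "Disease":
            d_tot += 1
            target = d_t
        else:
            n_tot += 1
            target = n_t
        for term in closures[rec.protein_id]:
            target[term] = target.get(term, 0) + 1
    return GoTermStats(
        d_t=d_t,
        n_t=n_t,
        d_tot=d_tot,
        n_tot=n_tot,
        pseudocount=pseudocount,
        fitted_fold=fitted_fold,
        fitted_proteins=frozenset(train.proteins()),
    )


@dataclass(frozen=True)
class GoFeatures:
    """The two functional SVM inputs: log-odds score and scaled term count."""

    go_score: float
    n_terms: int

    def as_tuple(self, count_scale_k: float = GO_COUNT_SCALE_K) -> tuple[float, float]:
        return (self.go_score, saturation_scale(float(self.n_terms), count_scale_k))


def go_features(
    protein_terms: set[str],
    stats: GoTermStats,
    graph: GoGraph,
    relations: tuple[str, ...] = ("is_a", "part_of"),
    protein_id: Optional[str] = None,
) -> GoFeatures:
    """Sum per-term log-odds over the protein's closure.

    An unannotated protein yields (0, 0).  Supplying ``protein_id`` arms the
    leakage guard: computing features for a protein that contributed to the
    fitted statistics raises.
    """
    if protein_id is not None and protein_id in stats.fitted_proteins:
        raise IntegrityError(
            f"leakage guard: protein {protein_id} contributed to the supplied "
            f"GO statistics (fold {stats.fitted_fold})"
        )
    if not protein_terms:
        return GoFeatures(go_score=0.0, n_terms=0)
    closure = ancestor_closure(graph, protein_terms, relations)
    if not closure:
        return GoFeatures(go_score=0.0, n_terms=0)
    score = sum(stats.term_log_odds(t) for t in closure)
    return GoFeatures(go_score=score, n_terms=len(closure))
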
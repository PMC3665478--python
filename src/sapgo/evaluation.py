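"""Performance indexes, ROC/AUC, RI stratification and cluster-aware k-fold CV.

Implements the standard binary-classification scores for the two classes
D (disease-related) and N (neutral): overall accuracy Qtot = C/T, the
Matthews correlation coefficient, per-class sensitivity S(s) = p/(p+u) and
positive predictive value P(s) = p/(p+o), the ROC curve (TPR = S(D) against
FPR = 1 - S(N)) with trapezoid AUC, and performance restricted to
high-reliability predictions (RI >= threshold).

Cross-validation folds are cluster-aware: proteins grouped by sequence
similarity (e.g. 30% identity / 80% coverage single linkage) never straddle
folds, and blind evaluation refuses to score test proteins that cluster with
the training set.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .classifier import Prediction, TrainedModel, predict_many
from .errors import ConfigError, SapgoError, UndefinedMetricError
from .feature_assembly import FeatureVector
from .io_formats import DatasetTable, VariantRecord


@dataclass(frozen=True)
class ClassCounts:
    """Confusion counts from the Disease-class viewpoint.

    For the complementary class the roles swap: p(N) = n(D), o(N) = u(D),
    u(N) = o(D), n(N) = p(D).
    """

    p_d: int  # true positives for D
    n_d: int  # true negatives for D
    u_d: int  # false negatives for D
    o_d: int  # false positives for D

    def p(self, s: str) -> int:
        return self.p_d if s == "D" else self.n_d

    def n(self, s: str) -> int:
        return self.n_d if s == "D" else self.p_d

    def u(self, s: str) -> int:
        return self.u_d if s == "D" else self.o_d

    def o(self, s: str) -> int:
        return self.o_d if s == "D" else self.u_d

    @property
    def total(self) -> int:
        return self.p_d + self.n_d + self.u_d + self.o_d

    @property
    def correct(self) -> int:
        return self.p_d + self.n_d


def confusion(
    preds: Sequence[Prediction],
    labels: Sequence[str],
    threshold: float = 0.5,
) -> ClassCounts:
    """Tally the confusion counts under the strict O(D) > threshold rule."""
    if len(preds) != len(labels):
        raise SapgoError("predictions and labels differ in length")
    p = n = u = o = 0
    for pred, label in zip(preds, labels):
        predicted_d = pred.o_d > threshold
        if label == "Disease":
            if predicted_d:
                p += 1
            else:
                u += 1
        else:
            if predicted_d:
                o += 1
            else:
                n += 1
    return ClassCounts(p_d=p, n_d=n, u_d=u, o_d=o)


def q_tot(counts: ClassCounts) -> float:
    """Overall accuracy C/T."""
    if counts.total == 0:
        raise UndefinedMetricError("Qtot undefined on zero predictions")
    return counts.correct / counts.total


def mcc(counts: ClassCounts, s: str = "D") -> float:
    """Matthews correlation coefficient for class ``s``.

    (p*n - u*o) / sqrt((p+u)(p+o)(n+u)(n+o)); any zero marginal gives 0.
    """
    p, n, u, o = counts.p(s), counts.n(s), counts.u(s), counts.o(s)
    w2 = (p + u) * (p + o) * (n + u) * (n + o)
    if w2 == 0:
        return 0.0
    return (p * n - u * o) / math.sqrt(w2)


def sensitivity(counts: ClassCounts, s: str) -> float:
    """Coverage S(s) = p/(p+u)."""
    denom = counts.p(s) + counts.u(s)
    if denom == 0:
        raise UndefinedMetricError(f"S({s}) undefined: no true members of class {s}")
    return counts.p(s) / denom


def precision(counts: ClassCounts, s: str) -> float:
    """Positive predictive value P(s) = p/(p+o)."""
    denom = counts.p(s) + counts.o(s)
    if denom == 0:
        raise UndefinedMetricError(f"P({s}) undefined: no predictions of class {s}")
    return counts.p(s) / denom


def roc_auc(
    scores: Sequence[float], labels: Sequence[str]
) -> tuple[list[tuple[float, float]], float]:
    """ROC curve by threshold sweep and its trapezoid area.

    The curve plots TPR = S(D) against FPR = 1 - S(N) at every distinct
    score threshold; the trapezoid area equals the tie-aware concordance
    (Mann-Whitney) statistic.
    """
    if len(scores) != len(labels):
        raise SapgoError("scores and labels differ in length")
    y = np.array([1 if l == "Disease" else 0 for l in labels])
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC undefined with a single class")
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    curve: list[tuple[float, float]] = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(s_sorted):
        j = i
        while j < len(s_sorted) and s_sorted[j] == s_sorted[i]:
            tp += int(y_sorted[j])
            fp += 1 - int(y_sorted[j])
            j += 1
        curve.append((fp / n_neg, tp / n_pos))
        i = j
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(curve[:-1], curve[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2.0
    return curve, auc


@dataclass(frozen=True)
class MetricsReport:
    """Eqs-style summary: Qtot, MCC, per-class S and P, AUC, totals."""

    q_tot: float
    mcc: float
    s_d: float
    s_n: float
    p_d: float
    p_n: float
    auc: Optional[float]
    total: int
    correct: int

    def as_row(self) -> str:
        auc = f"{self.auc:.3f}" if self.auc is not None else "NA"
        return (
            f"{self.q_tot:.3f}\t{self.p_d:.3f}\t{self.s_d:.3f}\t{self.p_n:.3f}"
            f"\t{self.s_n:.3f}\t{self.mcc:.3f}\t{auc}"
        )

    HEADER = "Qtot\tP[D]\tS[D]\tP[N]\tS[N]\tMCC\tAUC"


def metrics_report(
    preds: Sequence[Prediction],
    labels: Sequence[str],
    with_auc: bool = True,
) -> MetricsReport:
    """Full report from predictions: confusion-derived indexes plus AUC."""
    counts = confusion(preds, labels)
    auc: Optional[float] = None
    if with_auc:
        try:
            _, auc = roc_auc([p.o_d for p in preds], labels)
        except UndefinedMetricError:
            auc = None
    return MetricsReport(
        q_tot=q_tot(counts),
        mcc=mcc(counts, "D"),
        s_d=sensitivity(counts, "D"),
        s_n=sensitivity(counts, "N"),
        p_d=precision(counts, "D"),
        p_n=precision(counts, "N"),
        auc=auc,
        total=counts.total,
        correct=counts.correct,
    )


def ri_stratified(
    preds: Sequence[Prediction],
    labels: Sequence[str],
    ri_min: int,
) -> tuple[MetricsReport, float]:
    """Metrics restricted to predictions with RI >= ``ri_min``.

    Returns (report, coverage) where coverage is the retained fraction.  An
    empty subset raises, with the (zero) coverage attached to the error.
    """
    if len(preds) != len(labels):
        raise SapgoError("predictions and labels differ in length")
    kept = [(p, l) for p, l in zip(preds, labels) if p.ri >= ri_min]
    coverage = len(kept) / len(preds) if preds else 0.0
    if not kept:
        err = UndefinedMetricError(f"no predictions with RI >= {ri_min}")
        err.coverage = coverage
        raise err
    sub_preds, sub_labels = zip(*kept)
    return metrics_report(list(sub_preds), list(sub_labels)), coverage


# ---------------------------------------------------------------------------
# Cluster-aware folds
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    """Fold index per protein; all proteins of one cluster share a fold."""

    protein_fold: dict[str, int]
    cluster_fold: dict[str, int]
    k: int

    def fold_of(self, protein_id: str) -> int:
        if protein_id not in self.protein_fold:
            raise SapgoError(f"protein {protein_id} has no fold assignment")
        return self.protein_fold[protein_id]


def cluster_folds(
    clusters: dict[str, str],
    k: int = 20,
    seed: int = 0,
    variant_counts: Optional[dict[str, int]] = None,
    allow_fewer: bool = False,
) -> FoldAssignment:
    """Deal whole clusters onto k folds, balancing variant counts greedily.

    Clusters are sorted canonically, shuffled with the seeded RNG, stably
    re-sorted by descending variant weight, and assigned largest-first to the
    currently lightest fold.  Permuting the input order never moves a
    cluster.  ``k`` larger than the number of clusters is an error unless
    ``allow_fewer`` reduces k to that number.
    """
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    members: dict[str, list[str]] = {}
    for protein, cluster in clusters.items():
        members.setdefault(cluster, []).append(protein)
    if k > len(members):
        if not allow_fewer:
            raise ConfigError(
                f"k={k} exceeds the number of clusters ({len(members)})"
            )
        k = len(members)
    weights = {
        cluster: sum((variant_counts or {}).get(p, 1) for p in plist)
        for cluster, plist in members.items()
    }
    rng = random.Random(seed)
    order = sorted(members)
    rng.shuffle(order)
    order.sort(key=lambda c: -weights[c])  # stable: seeded order breaks ties
    fold_load = [0] * k
    cluster_fold: dict[str, int] = {}
    for cluster in order:
        fold = min(range(k), key=lambda f: (fold_load[f], f))
        cluster_fold[cluster] = fold
        fold_load[fold] += weights[cluster]
    protein_fold = {p: cluster_fold[c] for p, c in clusters.items()}
    return FoldAssignment(protein_fold=protein_fold, cluster_fold=cluster_fold, k=k)


def clusters_from_identity(
    proteins: Sequence[str],
    pairs: Sequence[tuple[str, str, float, float]],
    identity_min: float = 30.0,
    coverage_min: float = 80.0,
) -> dict[str, str]:
    """Single-linkage clusters over a pairwise (identity %, coverage %) table.

    Two proteins link when identity >= ``identity_min`` and coverage >=
    ``coverage_min``; connected components become clusters named after their
    lexicographically smallest member.
    """
    parent = {p: p for p in proteins}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, ident, cov in pairs:
        if a in parent and b in parent and ident >= identity_min and cov >= coverage_min:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    groups: dict[str, list[str]] = {}
    for p in proteins:
        groups.setdefault(find(p), []).append(p)
    return {p: root for root, plist in groups.items() for p in plist}


def augment_reverse_neutrals(table: DatasetTable) -> DatasetTable:
    """Add the reverse of every neutral substitution as a new neutral record.

    For each unaugmented neutral A->B at a position, B->A is added once
    (deduplicated against existing records); Disease records are untouched.
    """
    existing = {(r.protein_id, r.wt, r.pos, r.mut) for r in table.records}
    added: list[VariantRecord] = []
    for rec in table.records:
        if rec.label != "Neutral":
            continue
        key = (rec.protein_id, rec.mut, rec.pos, rec.wt)
        if key not in existing:
            existing.add(key)
            added.append(
                VariantRecord(rec.protein_id, rec.mut, rec.pos, rec.wt, "Neutral")
            )
    return DatasetTable(
        records=table.records + added,
        provenance=table.provenance + "+reverse-neutral" if table.provenance else "reverse-neutral",
        structure_map=dict(table.structure_map),
    )


def blind_eval(
    model: TrainedModel,
    test: DatasetTable,
    vectors: Sequence[FeatureVector],
    clusters: dict[str, str],
) -> tuple[MetricsReport, list[VariantRecord]]:
    """Evaluate on a blind set, excluding proteins that cluster with training.

    ``vectors`` align with ``test.records``.  Any test variant whose protein
    shares a cluster with the model's training fingerprint is excluded and
    returned in the exclusion list; metrics cover the remainder.
    """
    if len(vectors) != len(test.records):
        raise SapgoError("one feature vector per test record required")
    kept_vectors: list[FeatureVector] = []
    kept_labels: list[str] = []
    excluded: list[VariantRecord] = []
    for rec, vec in zip(test.records, vectors):
        cluster = clusters.get(rec.protein_id)
        if cluster is not None and cluster in model.training_clusters:
            excluded.append(rec)
            continue
        kept_vectors.append(vec)
        kept_labels.append(rec.label)
    if not kept_vectors:
        raise UndefinedMetricError(
            "every test protein clusters with the training set"
        )
    preds = predict_many(model, kept_vectors)
    return metrics_report(preds, kept_labels), excluded
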
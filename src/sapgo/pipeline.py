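"""End-to-end glue: featurize variants, train, cross-validate, evaluate.

This module wires the feature blocks into full vectors for whole datasets,
with the fallbacks the method defines: a query-only profile when no
alignments are supplied, the PANTHER (0.5, 0, 0, 0) block when the external
predictor is silent, and the GO (0, 0) block for unannotated proteins.  GO
term statistics are always fitted on the training side only, and the leakage
guard is armed whenever a held-out protein is featurized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .classifier import Prediction, SvmParams, TrainedModel, predict_many, train
from .errors import ConfigError, SapgoError
from .evaluation import (
    FoldAssignment,
    MetricsReport,
    cluster_folds,
    metrics_report,
)
from .feature_assembly import FeaturePreset, FeatureVector, assemble_variant, get_preset
from .go_function import GoFeatures, GoTermStats, fit_term_stats, go_features
from .io_formats import (
    AccessibilityRecord,
    DatasetTable,
    GoGraph,
    PantherRecord,
    ProteinRecord,
    StructureModel,
    VariantRecord,
)
from .profiles import (
    AlignmentRecord,
    SequenceProfile,
    build_profile,
    profile_features,
)
from .structure_env import (
    map_variant_to_structure,
    relative_accessibility,
    structural_environment,
)


@dataclass
class FeatureResources:
    """Everything needed to featurize variants; unused parts may stay empty."""

    proteins: dict[str, ProteinRecord]
    hits: dict[str, list[AlignmentRecord]] = field(default_factory=dict)
    graph: Optional[GoGraph] = None
    annotations: dict[str, set[str]] = field(default_factory=dict)
    structures: dict[str, StructureModel] = field(default_factory=dict)
    chain: str = "A"
    accessibility: dict[str, AccessibilityRecord] = field(default_factory=dict)
    panther: dict[tuple[str, str], PantherRecord] = field(default_factory=dict)
    _profile_cache: dict[str, SequenceProfile] = field(default_factory=dict)

    def profile_for(self, protein_id: str) -> SequenceProfile:
        """One profile per protein, shared by all of its variants."""
        if protein_id not in self._profile_cache:
            protein = self.proteins[protein_id]
            self._profile_cache[protein_id] = build_profile(
                protein, self.hits.get(protein_id, [])
            )
        return self._profile_cache[protein_id]


def featurize_variant(
    resources: FeatureResources,
    record: VariantRecord,
    preset: FeaturePreset | str,
    go_stats: Optional[GoTermStats] = None,
    guard_protein: bool = False,
) -> FeatureVector:
    """Build the full vector for one variant.

    ``guard_protein`` arms the GO leakage guard (use for held-out variants).
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    protein = resources.proteins.get(record.protein_id)
    if protein is None:
        raise SapgoError(f"unknown protein {record.protein_id}")
    # Reverse-of-neutral records carry the mutant as their wild type; they are
    # accepted when the sequence residue matches the record's mutant instead.
    try:
        record.resolve(protein)
    except SapgoError:
        if protein.residue(record.pos) != record.mut:
            raise
    prof = profile_features(resources.profile_for(record.protein_id), record)

    go: Optional[GoFeatures] = None
    if go_stats is not None and resources.graph is not None:
        go = go_features(
            resources.annotations.get(record.protein_id, set()),
            go_stats,
            resources.graph,
            protein_id=record.protein_id if guard_protein else None,
        )

    struct_env = rsa = None
    needed = {name for name, _ in preset.blocks}
    if "struct_env" in needed or "rsa" in needed:
        model = resources.structures.get(record.protein_id)
        if model is None:
            raise ConfigError(
                f"preset {preset.name} needs a structure for {record.protein_id}"
            )
        try:
            handle = map_variant_to_structure(record, model, resources.chain)
        except SapgoError:
            if protein.residue(record.pos) != record.mut:
                raise
            swapped = VariantRecord(
                record.protein_id, record.mut, record.pos, record.wt, record.label
            )
            handle = map_variant_to_structure(swapped, model, resources.chain)
        struct_env = structural_environment(model, handle)
        acc = resources.accessibility.get(record.protein_id)
        if acc is None:
            from .structure_env import compute_accessibility

            acc = compute_accessibility(model)
            resources.accessibility[record.protein_id] = acc
        rsa = relative_accessibility(acc, handle)

    return assemble_variant(
        preset,
        wt=record.wt,
        mut=record.mut,
        profile=prof,
        sequence=protein.sequence,
        pos=record.pos,
        struct_env=struct_env,
        rsa=rsa,
        panther=resources.panther.get((record.protein_id, record.token)),
        go=go,
    )


def featurize_dataset(
    resources: FeatureResources,
    table: DatasetTable,
    preset: FeaturePreset | str,
    go_stats: Optional[GoTermStats] = None,
    guard_proteins: bool = False,
) -> list[FeatureVector]:
    return [
        featurize_variant(resources, rec, preset, go_stats, guard_proteins)
        for rec in table.records
    ]


def train_on_dataset(
    resources: FeatureResources,
    table: DatasetTable,
    preset: FeaturePreset | str = "snpsgo_seq",
    params: Optional[SvmParams] = None,
    seed: int = 0,
    clusters: Optional[dict[str, str]] = None,
    go_pseudocount: float = 1.0,
) -> TrainedModel:
    """Fit GO statistics and the SVM on one labeled table."""
    go_stats = None
    if resources.graph is not None:
        go_stats = fit_term_stats(
            table, resources.annotations, resources.graph, pseudocount=go_pseudocount
        )
    vectors = featurize_dataset(resources, table, preset, go_stats)
    labels = [r.label for r in table.records]
    training_clusters = frozenset(
        (clusters or {}).get(p, p) for p in table.proteins()
    )
    return train(
        vectors,
        labels,
        params=params,
        seed=seed,
        training_clusters=training_clusters,
        go_stats=go_stats,
    )


def evaluate_holdout(
    resources: FeatureResources,
    model: TrainedModel,
    test: DatasetTable,
    preset: FeaturePreset | str = "snpsgo_seq",
) -> tuple[MetricsReport, list[Prediction], list[str]]:
    """Score a held-out table with the model's own GO statistics."""
    vectors = featurize_dataset(
        resources, test, preset, model.go_stats, guard_proteins=True
    )
    preds = predict_many(model, vectors)
    labels = [r.label for r in test.records]
    return metrics_report(preds, labels), preds, labels


def cross_validate(
    resources: FeatureResources,
    table: DatasetTable,
    clusters: dict[str, str],
    preset: FeaturePreset | str = "snpsgo_seq",
    k: int = 20,
    seed: int = 0,
    params: Optional[SvmParams] = None,
) -> tuple[MetricsReport, list[Prediction], list[str], FoldAssignment]:
    """Cluster-aware k-fold CV with per-fold GO statistics.

    Pooled out-of-fold predictions over the whole table feed one report.
    """
    counts: dict[str, int] = {}
    for rec in table.records:
        counts[rec.protein_id] = counts.get(rec.protein_id, 0) + 1
    folds = cluster_folds(clusters, k=k, seed=seed, variant_counts=counts)
    all_preds: list[Optional[Prediction]] = [None] * len(table.records)
    for fold in range(folds.k):
        train_recs = [
            r for r in table.records if folds.fold_of(r.protein_id) != fold
        ]
        test_idx = [
            i for i, r in enumerate(table.records) if folds.fold_of(r.protein_id) == fold
        ]
        if not test_idx:
            continue
        train_table = DatasetTable(
            records=train_recs, provenance=table.provenance + f"/fold{fold}"
        )
        model = train_on_dataset(
            resources, train_table, preset, params=params, seed=seed, clusters=clusters
        )
        test_table = DatasetTable(
            records=[table.records[i] for i in test_idx],
            provenance=table.provenance + f"/fold{fold}-test",
        )
        _, preds, _ = evaluate_holdout(resources, model, test_table, preset)
        for i, pred in zip(test_idx, preds):
            all_preds[i] = pred
    preds_final = [p for p in all_preds if p is not None]
    labels_final = [
        r.label for r, p in zip(table.records, all_preds) if p is not None
    ]
    return metrics_report(preds_final, labels_final), preds_final, labels_final, folds
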
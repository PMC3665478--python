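"""Metric implementations against brute-force oracles; fold integrity."""

import math
import random

import numpy as np
import pytest

from sapgo.classifier import Prediction
from sapgo.errors import ConfigError, UndefinedMetricError
from sapgo.evaluation import (
    ClassCounts,
    augment_reverse_neutrals,
    blind_eval,
    cluster_folds,
    clusters_from_identity,
    confusion,
    mcc,
    metrics_report,
    precision,
    q_tot,
    ri_stratified,
    roc_auc,
    sensitivity,
)
from sapgo.io_formats import DatasetTable, VariantRecord


def _preds(o_ds):
    return [Prediction.from_probability(o) for o in o_ds]


def _random_case(rng, n=50):
    o_ds = [rng.random() for _ in range(n)]
    labels = [rng.choice(["Disease", "Neutral"]) for _ in range(n)]
    return _preds(o_ds), labels


def brute_counts(preds, labels):
    """Independent tally by explicit enumeration."""
    p = sum(1 for x, l in zip(preds, labels) if l == "Disease" and x.o_d > 0.5)
    u = sum(1 for x, l in zip(preds, labels) if l == "Disease" and x.o_d <= 0.5)
    o = sum(1 for x, l in zip(preds, labels) if l == "Neutral" and x.o_d > 0.5)
    n = sum(1 for x, l in zip(preds, labels) if l == "Neutral" and x.o_d <= 0.5)
    return p, n, u, o


def mann_whitney_auc(scores, labels):
    """Pair-count concordance with ties counted one half."""
    pos = [s for s, l in zip(scores, labels) if l == "Disease"]
    neg = [s for s, l in zip(scores, labels) if l == "Neutral"]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_all_correct(self):
        preds = _preds([0.9] * 4 + [0.1] * 3)
        labels = ["Disease"] * 4 + ["Neutral"] * 3
        c = confusion(preds, labels)
        assert (c.p_d, c.n_d, c.u_d, c.o_d) == (4, 3, 0, 0)

    def test_all_wrong(self):
        preds = _preds([0.1] * 4 + [0.9] * 3)
        labels = ["Disease"] * 4 + ["Neutral"] * 3
        c = confusion(preds, labels)
        assert (c.p_d, c.n_d) == (0, 0)

    def test_random_fixture_matches_bruteforce(self):
        rng = random.Random(4)
        for _ in range(10):
            preds, labels = _random_case(rng)
            c = confusion(preds, labels)
            assert (c.p_d, c.n_d, c.u_d, c.o_d) == brute_counts(preds, labels)

    def test_class_identities(self):
        c = ClassCounts(p_d=4, n_d=3, u_d=1, o_d=2)
        assert c.p("N") == c.n("D")
        assert c.o("N") == c.u("D")
        assert c.u("N") == c.o("D")
        assert c.n("N") == c.p("D")


class TestScalarMetrics:
    def test_q_tot_arithmetic(self):
        assert q_tot(ClassCounts(5, 3, 1, 1)) == 0.8
        assert q_tot(ClassCounts(5, 5, 0, 0)) == 1.0
        assert q_tot(ClassCounts(0, 0, 5, 5)) == 0.0

    def test_q_tot_undefined_on_empty(self):
        with pytest.raises(UndefinedMetricError):
            q_tot(ClassCounts(0, 0, 0, 0))

    def test_mcc_hand_value(self):
        # p=4, n=3, u=1, o=2 -> (12 - 2)/sqrt(5*6*4*5) = 10/sqrt(600)
        c = ClassCounts(p_d=4, n_d=3, u_d=1, o_d=2)
        assert mcc(c, "D") == pytest.approx(10 / math.sqrt(600))
        assert mcc(c, "D") == pytest.approx(0.4082, abs=1e-4)

    def test_mcc_symmetry_between_classes(self):
        rng = random.Random(9)
        for _ in range(20):
            preds, labels = _random_case(rng, 30)
            c = confusion(preds, labels)
            assert mcc(c, "D") == pytest.approx(mcc(c, "N"))

    def test_mcc_perfect_and_zero_marginal(self):
        assert mcc(ClassCounts(5, 5, 0, 0)) == 1.0
        assert mcc(ClassCounts(0, 0, 0, 5)) == 0.0

    def test_sensitivity_precision_hand_values(self):
        c = ClassCounts(p_d=4, n_d=3, u_d=1, o_d=2)
        assert sensitivity(c, "D") == pytest.approx(0.8)
        assert precision(c, "D") == pytest.approx(2 / 3)

    def test_zero_denominator_distinct_from_zero(self):
        c = ClassCounts(p_d=0, n_d=5, u_d=0, o_d=0)
        with pytest.raises(UndefinedMetricError):
            sensitivity(c, "D")
        with pytest.raises(UndefinedMetricError):
            precision(c, "D")


class TestRocAuc:
    def test_perfect_separation(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        labels = ["Disease", "Disease", "Neutral", "Neutral"]
        _, auc = roc_auc(scores, labels)
        assert auc == 1.0

    def test_eight_point_hand_fixture_vs_pair_counts(self):
        scores = [0.9, 0.8, 0.8, 0.6, 0.5, 0.4, 0.4, 0.1]
        labels = ["Disease", "Disease", "Neutral", "Disease",
                  "Neutral", "Neutral", "Disease", "Neutral"]
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)

    def test_random_fixtures_match_pair_counts_and_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = random.Random(21)
        for _ in range(20):
            preds, labels = _random_case(rng, 40)
            scores = [p.o_d for p in preds]
            if len(set(labels)) < 2:
                continue
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)
            y = [1 if l == "Disease" else 0 for l in labels]
            assert auc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_coin_labels_near_half(self):
        rng = random.Random(5)
        scores = [rng.random() for _ in range(2000)]
        labels = [rng.choice(["Disease", "Neutral"]) for _ in range(2000)]
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([0.4, 0.6], ["Disease", "Disease"])


class TestRiStratified:
    def test_ri_zero_equals_unstratified(self):
        rng = random.Random(2)
        preds, labels = _random_case(rng, 60)
        full = metrics_report(preds, labels)
        sub, coverage = ri_stratified(preds, labels, 0)
        assert coverage == 1.0
        assert sub.q_tot == full.q_tot

    def test_ri_ten_keeps_only_extremes(self):
        preds = _preds([0.0, 1.0, 0.6, 0.97])
        labels = ["Neutral", "Disease", "Disease", "Disease"]
        sub, coverage = ri_stratified(preds, labels, 10)
        assert coverage == 0.5
        assert sub.total == 2

    def test_empty_subset_reports_coverage(self):
        preds = _preds([0.52, 0.48])
        with pytest.raises(UndefinedMetricError) as err:
            ri_stratified(preds, ["Disease", "Neutral"], 9)
        assert err.value.coverage == 0.0

    def test_accuracy_nondecreasing_on_calibrated_run(self, strong_run):
        preds, labels = strong_run["preds"], strong_run["labels"]
        q_values = []
        for ri_min in (0, 2, 4, 6):
            sub, coverage = ri_stratified(preds, labels, ri_min)
            q_values.append(sub.q_tot)
            assert 0 < coverage <= 1
        assert all(b >= a - 0.01 for a, b in zip(q_values, q_values[1:]))


class TestClusterFolds:
    def test_no_cluster_spans_folds(self):
        rng = random.Random(1)
        clusters = {f"P{i}": f"C{i % 13}" for i in range(100)}
        folds = cluster_folds(clusters, k=5, seed=3)
        for cluster in set(clusters.values()):
            members = {folds.fold_of(p) for p, c in clusters.items() if c == cluster}
            assert len(members) == 1

    def test_forty_singletons_on_twenty_folds(self):
        clusters = {f"P{i:02d}": f"C{i:02d}" for i in range(40)}
        folds = cluster_folds(clusters, k=20, seed=0)
        loads = [0] * 20
        for p in clusters:
            loads[folds.fold_of(p)] += 1
        assert loads == [2] * 20

    def test_k_exceeding_clusters_rejected(self):
        with pytest.raises(ConfigError):
            cluster_folds({"P1": "C1"}, k=2, seed=0)

    def test_k_exceeding_clusters_fallback(self):
        folds = cluster_folds({"P1": "C1"}, k=2, seed=0, allow_fewer=True)
        assert folds.k == 1

    def test_deterministic_and_order_invariant(self):
        clusters = {f"P{i}": f"C{i % 7}" for i in range(50)}
        a = cluster_folds(clusters, k=4, seed=11)
        shuffled = dict(sorted(clusters.items(), key=lambda kv: hash(kv[0])))
        b = cluster_folds(shuffled, k=4, seed=11)
        assert a.cluster_fold == b.cluster_fold

    def test_weighting_balances_variant_counts(self):
        clusters = {"P1": "C1", "P2": "C2", "P3": "C3", "P4": "C4"}
        counts = {"P1": 100, "P2": 1, "P3": 1, "P4": 1}
        folds = cluster_folds(clusters, k=2, seed=0, variant_counts=counts)
        # the heavy cluster sits alone; the three light ones share the other fold
        heavy = folds.cluster_fold["C1"]
        others = {folds.cluster_fold[c] for c in ("C2", "C3", "C4")}
        assert others == {1 - heavy}


class TestIdentityClustering:
    def test_single_linkage_thresholds(self):
        proteins = ["A", "B", "C", "D"]
        pairs = [
            ("A", "B", 45.0, 90.0),  # links
            ("B", "C", 35.0, 70.0),  # coverage too low
            ("C", "D", 25.0, 95.0),  # identity too low
        ]
        clusters = clusters_from_identity(proteins, pairs)
        assert clusters["A"] == clusters["B"]
        assert clusters["C"] != clusters["A"]
        assert clusters["C"] != clusters["D"]

    def test_transitive_linkage(self):
        proteins = ["A", "B", "C"]
        pairs = [("A", "B", 90, 90), ("B", "C", 90, 90)]
        clusters = clusters_from_identity(proteins, pairs)
        assert len(set(clusters.values())) == 1


class TestReverseNeutralAugmentation:
    def test_growth_and_dedup(self):
        table = DatasetTable(
            records=[
                VariantRecord("P1", "A", 5, "V", "Neutral"),
                VariantRecord("P1", "V", 5, "A", "Neutral"),  # reverse exists
                VariantRecord("P1", "G", 9, "R", "Neutral"),
                VariantRecord("P1", "C", 2, "Y", "Disease"),
            ]
        )
        out = augment_reverse_neutrals(table)
        tokens = {r.token for r in out.records}
        assert "R9G" in tokens  # added
        assert len(out.records) == 5  # only one addition: A5V/V5A dedup
        d, n = out.class_counts()
        assert (d, n) == (1, 4)

    def test_disease_untouched(self):
        table = DatasetTable(records=[VariantRecord("P1", "C", 2, "Y", "Disease")])
        assert len(augment_reverse_neutrals(table).records) == 1


class TestBlindEval:
    def test_cluster_sharing_proteins_excluded(self, strong_run):
        from sapgo.pipeline import featurize_dataset

        model = strong_run["model"]
        res = strong_run["resources"]
        ds = strong_run["dataset"]
        train_t, test_t = strong_run["train"], strong_run["test"]
        # contaminate: pretend one test protein shares a training cluster
        some_train_protein = next(iter(train_t.proteins()))
        some_test_protein = next(iter(test_t.proteins()))
        clusters = dict(ds.clusters)
        clusters[some_test_protein] = clusters[some_train_protein]
        vectors = featurize_dataset(res, test_t, "snpsgo_3d", model.go_stats)
        report, excluded = blind_eval(model, test_t, vectors, clusters)
        assert {r.protein_id for r in excluded} == {some_test_protein}
        assert report.total == len(test_t.records) - len(excluded)
        assert report.correct <= report.total

    def test_disjoint_clusters_score_everything(self, strong_run):
        from sapgo.pipeline import featurize_dataset

        model = strong_run["model"]
        test_t = strong_run["test"]
        ds = strong_run["dataset"]
        vectors = featurize_dataset(
            strong_run["resources"], test_t, "snpsgo_3d", model.go_stats
        )
        report, excluded = blind_eval(model, test_t, vectors, ds.clusters)
        assert excluded == []
        assert report.total == len(test_t.records)
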
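import warnings

import networkx as nx
import pytest

from sapgo.io_formats import DatasetTable, GoGraph, VariantRecord
from sapgo.pipeline import FeatureResources, evaluate_holdout, train_on_dataset
from sapgo.synthetic_fixtures import generate, null_v1, split_dataset, strong_v1

warnings.filterwarnings(
    "ignore", message="The `probability` parameter", category=FutureWarning
)

SEED = 1234


def _resources(ds) -> FeatureResources:
    return FeatureResources(
        proteins=ds.proteins,
        hits=ds.hits,
        graph=ds.graph,
        annotations=ds.annotations,
        structures=ds.structures,
        accessibility=ds.accessibility,
        panther=ds.panther,
    )


@pytest.fixture(scope="session")
def strong_run():
    """One strong planted-signal run shared by every test that needs it:
    generate -> protein-disjoint 2000/1000 split -> train structure preset ->
    held-out report."""
    ds = generate(strong_v1(SEED))
    res = _resources(ds)
    train_t, test_t = split_dataset(ds, 2 / 3, SEED)
    model = train_on_dataset(res, train_t, "snpsgo_3d", seed=SEED, clusters=ds.clusters)
    report, preds, labels = evaluate_holdout(res, model, test_t, "snpsgo_3d")
    return {
        "dataset": ds,
        "resources": res,
        "train": train_t,
        "test": test_t,
        "model": model,
        "report": report,
        "preds": preds,
        "labels": labels,
    }


@pytest.fixture(scope="session")
def null_run():
    """Same pipeline with all effect sizes zero."""
    ds = generate(null_v1(SEED))
    res = _resources(ds)
    train_t, test_t = split_dataset(ds, 2 / 3, SEED)
    model = train_on_dataset(res, train_t, "snpsgo_3d", seed=SEED, clusters=ds.clusters)
    report, preds, labels = evaluate_holdout(res, model, test_t, "snpsgo_3d")
    return {"report": report, "preds": preds, "labels": labels, "test": test_t}


@pytest.fixture()
def diamond_go():
    """t1 root; t3 is_a t2 is_a t1; t4 part_of t1."""
    g = nx.DiGraph()
    for t in ("t1", "t2", "t3", "t4"):
        g.add_node(t)
    g.add_edge("t2", "t1", relation="is_a")
    g.add_edge("t3", "t2", relation="is_a")
    g.add_edge("t4", "t1", relation="part_of")
    return GoGraph(graph=g, namespaces={t: "molecular_function" for t in g.nodes})


@pytest.fixture()
def ten_variant_table():
    """Hand-built labeled table over three proteins for GO-score oracles.

    P1 (annotated {t3}): 3 Disease + 1 Neutral; P2 ({t4}): 1 D + 3 N;
    P3 (unannotated): 1 D + 1 N.  Totals D=5, N=5.
    """
    recs = []
    seq_pos = iter(range(1, 50))

    def add(pid, label, n):
        for _ in range(n):
            p = next(seq_pos)
            recs.append(VariantRecord(pid, "A", p, "V", label))

    add("P1", "Disease", 3)
    add("P1", "Neutral", 1)
    add("P2", "Disease", 1)
    add("P2", "Neutral", 3)
    add("P3", "Disease", 1)
    add("P3", "Neutral", 1)
    table = DatasetTable(records=recs, provenance="go-oracle")
    annotations = {"P1": {"t3"}, "P2": {"t4"}}
    return table, annotations
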
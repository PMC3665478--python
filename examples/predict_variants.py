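"""Train a small sequence-based model and predict three variants.

Builds a synthetic benchmark, trains the 51-feature sequence predictor, and
prints the 5-column prediction table for a held-out protein: variant token,
Disease/Neutral call, reliability index (0-10), disease probability O(D) and
the preset used.  A high RI means the probability sits far from the 0.5
decision boundary.
"""

import warnings

warnings.filterwarnings("ignore", category=FutureWarning)

from sapgo import FeatureResources, predict, featurize_variant, train_on_dataset
from sapgo.io_formats import DatasetTable
from sapgo.synthetic_fixtures import SynthConfig, generate

cfg = SynthConfig(
    seed=11,
    n_proteins=40,
    effect_conservation=6.0,
    effect_go=5.0,
    effect_burial=5.0,
)
ds = generate(cfg)
resources = FeatureResources(
    proteins=ds.proteins,
    hits=ds.hits,
    graph=ds.graph,
    annotations=ds.annotations,
    panther=ds.panther,
)

holdout_protein = sorted(ds.proteins)[-1]
train_table = DatasetTable(
    records=[r for r in ds.table.records if r.protein_id != holdout_protein],
    provenance="example-train",
)
model = train_on_dataset(resources, train_table, "snpsgo_seq", seed=11)

print("variant\tprediction\tRI\tp_disease\tmethod")
for record in [r for r in ds.table.records if r.protein_id == holdout_protein][:3]:
    vec = featurize_variant(resources, record, "snpsgo_seq", model.go_stats)
    pred = predict(model, vec)
    print(f"{record.token}\t{pred.label}\t{pred.ri}\t{pred.o_d:.3f}\tsnpsgo_seq")
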
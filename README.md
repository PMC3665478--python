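# sapgo

Machine-learning prediction of whether a single amino acid polymorphism
(SAP) in a human protein is **disease-related** or **neutral**, combining
evolutionary, functional and structural evidence in one SVM framework.

The package is for bioinformaticians who annotate missense variants from
exome or transcript sequencing and want a transparent, file-based,
fully-testable implementation of a function-aware SAP predictor: a library
first, with a thin `sapgo` command-line tool and narrative `examples/` on
top.

## The method

Two binary support vector machines share one feature machinery:

- **Sequence predictor** — a 51-element input per variant:
  1. *mutation block* (20): −1 at the wild-type residue index, +1 at the
     mutant index (alphabetical one-letter order);
  2. *sequence environment* (20): residue frequencies in a 19-residue
     window centered on the variant position;
  3. *profile block* (5): mutant and wild-type frequencies from a
     per-position profile built from pairwise alignment hits with
     E < 10⁻⁹, saturation-scaled per-position and whole-alignment depths
     (n/(n+100)), and the conservation index
     CI = 1 − H/log₂20 with H the Shannon entropy of the profile column;
  4. *external-predictor block* (4): PANTHER-style deleteriousness
     probability, wild-type/mutant frequencies and scaled independent
     counts, with the fixed fallback (0.5, 0, 0, 0) when absent;
  5. *functional block* (2): the GO log-odds score and the number of GO
     terms used, (0, 0) when the protein has no annotation.

- **Structure predictor** — 52 elements: the sequence environment is
  replaced by the *structural environment* (residue composition within a
  6 Å sphere around the wild-type Cα) plus one element for the relative
  solvent accessibility RSA = ACC/maxASA ∈ [0, 1].

The GO score sums, over the protein's annotation closure C (direct terms
plus all `is_a`/`part_of` ancestors), per-term smoothed log-odds of
disease vs neutral training variants:

    score = Σ_{t∈C} log₂ [ (d_t+π)/(D+2π) ÷ (n_t+π)/(N+2π) ],  π = 1

A variant is called Disease iff the calibrated probability O(D) > 0.5,
and every call carries a reliability index RI = ⌊20·|O(D) − 0.5|⌋ ∈ 0..10.
Evaluation implements overall accuracy Qtot = C/T, the Matthews
correlation coefficient, per-class sensitivity S and positive predictive
value P, trapezoid ROC AUC, RI-stratified performance, and cluster-aware
k-fold cross-validation in which proteins clustered by sequence identity
(30% identity / 80% coverage single linkage) never straddle folds.

## Worked example

`examples/predict_variants.py` trains the sequence predictor on a
synthetic benchmark and scores three variants of a held-out protein:

```
variant	prediction	RI	p_disease	method
G2P	Disease	7	0.890	snpsgo_seq
F6L	Disease	9	0.950	snpsgo_seq
Y16E	Disease	6	0.809	snpsgo_seq
```

Each row is one substitution (wild type, 1-based position, mutant), the
Disease/Neutral call, the 0–10 reliability grade and the disease
probability; `F6L` at O(D) = 0.95 is the most confident call (RI 9).
The other examples cover the GO log-odds score on a hand-sized ontology,
the 6 Å structural microenvironment with the rolling-probe RSA fallback,
and cluster-aware cross-validation with the accuracy/coverage trade-off
as low-RI predictions are filtered out.

The `sapgo` CLI exposes the same workflows from a shell:
`predict-seq`, `predict-3d`, `train`, `evaluate`, `simulate`, `features`.

## Scope

The package consumes files: FASTA sequences, tab-separated variant and
dataset tables, OBO ontologies, two-column GO annotation files, PDB
coordinates, DSSP accessibility output (or a documented two-column
fallback), tabular alignment-hit exports and PANTHER-style records.  It
does not run BLAST or PANTHER, fetch entries by accession, or serve a web
front-end.
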
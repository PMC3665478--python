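# Methods

## Problem and model

A single amino acid polymorphism (SAP) is described by a protein, a
1-based position, a wild-type and a mutant residue.  The predictor is a
binary RBF-kernel SVM with Platt-style probability calibration; its output
O(D) is the probability that the substitution is disease-related.  The
hard call is Disease iff O(D) > 0.5 (ties go to Neutral, per the strict
inequality), and the reliability index RI = ⌊20·|O(D) − 0.5|⌋ grades each
call on an integer 0–10 scale.

Two feature presets are first-class and versioned by a layout tag that
names block order and widths:

| preset | blocks | length |
|---|---|---|
| `snpsgo_seq` | mutation(20) + seq-env(20) + profile(5) + panther(4) + go(2) | 51 |
| `snpsgo_3d` | mutation(20) + struct-env(20) + rsa(1) + profile(5) + panther(4) + go(2) | 52 |
| `profile_seq` / `profile_3d` | the same minus panther and go | 45 / 46 |

The reduced presets are ablations standing in for older
profile+environment-only predictors; they reuse this codebase's blocks
rather than reimplementing the historical tools and are documented as
approximations.

## Feature definitions and numerical choices

**Mutation block.** −1 at the wild-type index, +1 at the mutant index,
over the 20 standard residues in alphabetical one-letter order.  Ambiguous
wild types (X/B/Z/U) are rejected at encoding and reported upstream as
unpredictable variants.

**Sequence environment.** Frequencies of the 20 standard residues in a
19-residue window centered on the position (central residue included — a
genuinely open choice, pinned in the layout tag), truncated at termini;
ambiguity codes count in neither numerator nor denominator, so non-empty
windows always sum to 1.

**Profile block.** One profile per protein, shared by all of its variants,
built from pairwise alignment hits filtered at E strictly below 10⁻⁹; the
query row is always counted.  Gap and ambiguity characters contribute to
neither the counts nor the per-position depth (the original tool's
handling of gapped columns is unrecorded; this rule is pinned in the
layout tag).  The five features, in fixed order: f_mut, f_wt, scaled
per-position depth, scaled whole-alignment depth, conservation index.
The "five values" are obtained by splitting alignment depth into its
per-position and whole-alignment variants.  Depth counts are unbounded, so
they enter the SVM as n/(n+K) with K = 100 — saturating, monotone, and
bounded in [0, 1); K is configurable.  The conservation index is
CI = 1 − H/log₂20 (normalized Shannon entropy of the 20-residue column;
0·log 0 := 0; zero-depth columns define CI = 0).  The source literature
cites a conservation measure without printing a formula; the entropy form
is standard, parameter-free and matches the [0, 1] contract.

**External-predictor (PANTHER) block.** Four pass-through values —
P(deleterious), f_wt, f_mut, saturation-scaled independent counts — with
the fixed fallback (0.5, 0, 0, 0) when no record exists.  There is no
presence-indicator element; the fallback probability 0.5 already encodes
"no information".

**GO block.** The annotation closure follows `is_a` and `part_of` edges
(a config switch restricts to `is_a`); obsolete terms are dropped.  Term
statistics count *variants*, not proteins — the score feeds a per-variant
classifier, and protein-level counting would let large families vanish.
The per-term log-odds uses pseudocount π = 1 and log base 2; both are
exposed in config since the original values are unrecorded.  The raw
score is unbounded, so the vector entry is tanh(score/10) — sign- and
zero-preserving (the (0, 0) no-annotation fallback survives) while keeping
every non-mutation feature in [−1, 1].  A leakage guard refuses to compute
GO features for any protein that contributed to the supplied statistics'
training fold.

**Structural environment.** Neighbors are protein residues with a Cα
within 6.0 Å (closed ball; exact ties included) of the variant residue's
Cα, over all chains of the model by default (interface positions then see
their true surroundings; a switch restricts to the mutated chain).  The
center residue is excluded — its identity is already in the mutation
block.  Cα–Cα distance is pinned; the source describes the sphere only as
"around the Cα".

**RSA.** Absolute accessibility (from DSSP output or the two-column
fallback dialect) divided by the theoretical Gly-X-Gly maximum for the
residue type, clamped to [0, 1]; the reference table ships as data and is
swappable.  When no accessibility file is supplied, a built-in
rolling-probe (Shrake–Rupley-style) sampler with probe radius 1.4 Å and
120 sphere points per atom provides a coarse fallback; the file-based
path is authoritative.  Missing residues raise by default; an `impute`
policy returns 0.5 with a warning.

## Classifier

Kernel and hyperparameters of the original models are unrecorded; the
defaults are RBF, C = 1, γ = 1/n_features, both configurable.  Features
are z-scaled with statistics learned on the training fold and stored in
the model, alongside the GO term statistics, the layout tag and the
training-cluster fingerprint, so a saved model file is self-contained and
refuses vectors with a mismatched layout.  Training is deterministic given
data order, parameters and seed (identical model bytes).

## Evaluation

Confusion counts follow the strict O(D) > 0.5 rule.  The MCC denominator
takes the standard square root (the usual normalization; any zero marginal
defines MCC = 0).  The ROC plots TPR = S(D) against FPR = 1 − S(N) over a
sweep of all distinct score thresholds; the trapezoid area is checked in
tests against the tie-aware Mann–Whitney pair-count statistic and an
independent library implementation.  RI-stratified reports restrict to
predictions with RI ≥ r and report the retained coverage.

Cross-validation is cluster-aware: cluster assignments come from a
two-column file, or from a helper that single-links a user-supplied
pairwise table at 30% identity / 80% coverage (the clustering program
itself is not reimplemented).  Whole clusters are dealt onto k folds —
canonically sorted, seed-shuffled, stably re-sorted by descending variant
weight, then greedily assigned largest-first to the lightest fold — so
fold membership is deterministic given the seed and invariant to input
order.  Blind evaluation refuses to score any test variant whose protein
clusters with the training fingerprint.  Reverse-neutral augmentation
(each neutral A→B adds B→A once, deduplicated) is an off-by-default
dataset transform applied within folds after cluster assignment to avoid
leakage; featurization accepts augmented records whose "wild type" is the
sequence's mutant, by the reverse-of-neutral convention.

## Synthetic benchmark

The generator emits internally consistent toy data in the same file
formats the pipeline reads: i.i.d. random sequences; simulated homolog
rows in which planted conserved positions (half of each protein) mutate at
rate 0.03 versus 0.5 elsewhere; a layered random GO DAG (three namespace
roots, 60 terms) with a 12-term disease-enriched subset annotated onto
half of the proteins; self-avoiding Cα traces with 3.8 Å steps; uniform
per-residue burial converted to absolute accessibility through the maxASA
table; and label-independent PANTHER-style noise records (deliberately
uninformative so the null configuration stays at AUC 0.5).

Disease labels are Bernoulli draws from a logistic model over the three
planted signals — realized conservation index, the protein's enriched-GO
flag, and burial (1 − 2·RSA) — so recovery is quantifiable and zero effect
sizes make labels independent of every feature.  The default study
conditions are 150 proteins × 20 variants = 3000 variants, split
2000/1000 by whole proteins.  The documented `strong_v1` preset uses
effect sizes (6.0, 5.0, 5.0) on the logit scale, placing the
Bayes-optimal AUC of the generative model near 0.98; the full structure
pipeline recovers 0.91–0.93 held-out AUC across seeds, a consistent ≈0.05
gap to Bayes attributable to the GO score being a proxy for the latent
functional flag and to the 40 signal-free environment features.  `null_v1`
zeroes all effects.

What passing these benchmarks shows — and does not.  They demonstrate
that the implementation recovers a planted conservation/function/burial
signal end-to-end without leakage and stays at chance when no signal
exists.  They say nothing about performance on curated human variant
data: real proteins have correlated sites, realistic GO topology,
family structure (here every protein is its own cluster) and
informative external predictors, none of which the generator emulates.

## Problem sizes

Test-suite and acceptance runs use the 3000-variant default conditions
(and smaller 20–60-protein configurations for CLI and monotonicity
checks), chosen as the package's own benchmark scale; the whole suite and
the acceptance script each complete in well under a minute on one CPU.

## Known limitations

- The profile path consumes precomputed alignment hits; it never runs the
  homology search, and no PSSM/log-odds profile variant is provided
  (frequencies only).
- Structure handling is single-model PDB with Cα-based geometry;
  mmCIF and NMR ensembles are out of scope.
- The rolling-probe accessibility fallback is a coarse sampler intended
  for toy structures and smoke runs, not a DSSP replacement.
- The reduced presets approximate, but do not reproduce, the historical
  profile-only predictors.
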
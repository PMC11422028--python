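# Methods

## The problem

Polyglutamine (polyQ) and polyalanine (polyA) homorepeats — runs of
identical or nearly identical residues in a protein sequence — frequently
mediate protein-protein interactions (PPIs), but most homorepeats have no
experimental interaction evidence, and the link between a repeat and a
function is usually established only after an interaction has been
characterised. `polyx-ppi` turns the available structural annotation into a
supervised predictor: a homorepeat is labelled *interacting* when its span
overlaps a region annotated as part of an interaction interface, a
classifier is trained on the repeat's sequence context, and the fitted
model scores every repeat in a proteome with the probability that it
participates in a PPI.

## Homorepeat detection

A repeat is called by a sliding-window rule: a window of `window` residues
(default 6) *qualifies* when it contains at least `min_count` copies of the
target residue (default 4). The union of all qualifying windows forms
candidate spans; each span is trimmed so that its first and last residues
are the target. Two qualifying spans separated by one or more uncovered
residues are reported separately — nearby repeats are not merged beyond the
window union, so a protein can carry several distinct repeats. Proteins
shorter than the window are evaluated as a single whole-sequence window
with the same count threshold, preserving the rule's intent at the margin.
The 4-of-6 threshold deliberately admits impure repeats such as `QQQDSQ`
or `ARAAVA` (purity 4 of 6): impure, interspersed repeats are exactly the
ones most often implicated in interactions rather than aggregation.

The reported `purity` of a region is the count of target residues within
the trimmed span. The detector is validated against an exhaustive oracle
that enumerates every window independently.

## Features

Each detected repeat contributes one row:

* **Context symbols** — the amino acids at signed positions −N..−1 and
  +1..+N around the repeat. Positions inside the repeat are never features,
  because repeats diverge in length; the repeat's **length** is a separate
  integer variable instead. A position that falls outside the protein
  (repeat closer than N residues to a terminus) carries the padding symbol
  `-`, giving a fixed per-position dictionary of 21 symbols (20 amino acids
  plus padding). Non-proteinogenic letters (X, U, B, Z, J, O) also map to
  the padding symbol, which keeps encoding total without discarding the
  protein.
* **Coiled-coil overlap flags** (optional) — one boolean per context
  position, true when the position's absolute residue index lies inside an
  annotated coiled-coil span of the same protein. PolyQ is known to follow
  coiled coils, and coiled-coil proximity is a proposed hallmark of
  interacting repeats.

Raw variable counts therefore follow the identity 2N context positions
(+ 2N overlap flags when used) + 1 length: 25 for the final polyQ
configuration (N = 6 with flags) and 41 for the final polyA configuration
(N = 10 with flags).

For the numeric design matrix each context position is expanded into
all 21 indicator columns whether or not a symbol was observed, so models
trained on different datasets share one feature space; the column count is
exactly (2N × 21) + 1 (+ 2N with flags). Feature names use the M/P code:
`M6C` = position −6 is cysteine, `P3P` = position +3 is proline; overlap
flags are `ccM6` … `ccP10` and the length column is `length`.

## Labels and paralogy imputation

A repeat is a *positive* when it shares at least one residue with an
interface region on the same protein — the weakest consistent reading of
"overlap", and deliberately permissive given that interface annotations are
themselves spans. Everything else is *unknown* (not negative: absence of
structural evidence is not evidence of absence; the classifier treats
unknowns as the negative class during training, which is the standard
PU-learning compromise for this kind of data).

Because paralogs tend to reuse interfaces, the builder can optionally
impute extra positives: an unknown repeat in protein A becomes positive
when a paralog B carries a *directly* positive repeat of the same residue
type whose span, mapped through the global alignment of A and B, overlaps
the repeat's span by at least one aligned residue. The alignment uses
BLOSUM62 with affine gaps (open 10, extend 0.5) and the first optimal
traceback, which is deterministic. Direct positives are never downgraded,
imputed positives never seed further imputation (so the operation is
idempotent), and the feature table records provenance
(`direct` / `paralog_imputed`). Imputation is off by default: it enlarges
the positive set only slightly while mixing label provenances, and the
simpler direct-label model is preferred.

## Training protocol

Data are split 70/30 with per-class sampling so both partitions keep the
class proportions to the nearest integer. Classes are heavily imbalanced
(7.53% positives for polyQ, 10.26% for polyA in the reference datasets), so
every training set — the final one and each cross-validation training fold
— is downsampled: the majority class is subsampled without replacement to
the minority count. Held-out folds and the test set are never resampled.

Tuning uses 10-fold cross-validation repeated 3 times over a small grid per
algorithm family (see the `models` module docstring for the grids):

* random forest (`mtry` features sampled per split; 500 trees),
* boosted logistic regression (boosting over one-split stumps, `nIter`
  rounds),
* k-nearest neighbours (Euclidean distance on the min-max-scaled matrix —
  only the length column is affected by scaling, but unscaled it would
  dominate the metric),
* linear-kernel SVM (cost `C`; margins squashed through a logistic for
  probability-like scores; AUC is rank-based and so calibration-free),
* a single-hidden-layer neural network with logistic activation (`size`
  units, weight decay `decay`), fitted with full-batch L-BFGS, which is the
  right optimiser for networks this small.

The selection criterion within CV is mean AUC; F1 and the other metrics are
reported alongside. Confusion-matrix metrics use threshold 0.5 on the
interacting-class probability and are reported for *both* reference levels
(interacting and non-interacting as the "positive" of the confusion
matrix), because with ~8–10% prevalence and a downsampled-trained model the
two orientations differ sharply and published performance tables are only
arithmetically consistent under the majority-class orientation. AUC is
orientation-free.

Random-forest variable importance is the impurity-based importance rescaled
so the top feature is 100. When every feature is constant the importances
are all zero and are returned unscaled rather than erroring.

Context-window optimisation re-derives the rows at each candidate
half-width N (2..10 by default), cross-validates the random forest on each,
and picks the N with the best CV AUC, breaking ties toward smaller N
(the simpler model). Defaults encode the final per-repeat-type choices:
N = 6 without coiled-coil flags for polyQ, N = 10 with flags for polyA.

## Proteome-wide scoring

The final model scores every detected repeat; the score is the predicted
probability of PPI involvement. The report bins scores into 20 equal
right-closed bins on [0, 1], counts records above a threshold (default 0.7)
stratified by known-label provenance, and flags unknown-labelled records
above the threshold as *candidates* — the repeats most worth experimental
follow-up.

## The synthetic generator

Real inputs require proteome-scale downloads, so the package ships a
first-class generator that emits format-identical FASTA/TSV inputs with
planted, controllable signal. Its defaults are the study conditions of the
reference analysis:

| parameter | default | meaning |
|---|---|---|
| `positive_fraction` | 0.0753 | interacting fraction (polyQ regime; use 0.1026 for polyA) |
| `pos_length_range` / `neg_length_range` | 4–8 / 4–15 | positives skew short |
| `p_signal` | 0.8 | positives carrying the +3 signal residue (P after polyQ, G after polyA) |
| `cc_prob_positive` / `cc_prob_negative` | 0.6 / 0.1 | coiled coil overlapping the downstream context |
| `paralog_fraction`, `paralog_mutation_rate` | 0.0, 0.05 | mutated duplicates with preserved repeat spans |
| `protein_length` | 150–400 | uniform; background residues uniform over 20 letters |

Planted repeats are pure runs; after assembling a protein the generator
runs the detector and resamples the background until detection recovers
exactly the planted span (spurious 4-of-6 windows arise in a few percent of
random proteins), so the detect-then-label round trip reproduces ground
truth exactly. Interfaces are emitted over every positive repeat, plus
configurable decoy interfaces elsewhere to exercise labelling specificity.
`make_imbalanced_labeling(n_total, n_pos)` builds a minimal fixture whose
overlap labelling yields an exact positive count, reproducing the reference
imbalance fractions (157/2085 = 7.53%, 745/7263 = 10.26%).

What the generator does **not** emulate: real amino-acid composition biases
around repeats, repeat-length spectra beyond the planted ranges, impure
repeats, disorder, or interaction-partner structure. Passing tests
therefore demonstrate that the machinery is correct and can recover planted
structure at realistic imbalance — not that the models reach any particular
performance on real proteomes.

## Numerical and reproducibility choices

* One seed governs a run; every derived seed (per-fold downsampling, final
  fit) is computed from it and kept below 2³¹. Identical configuration and
  seed reproduce byte-identical tables; the pipeline manifest records the
  config hash and SHA-256 of every stage output.
* Scores are written with six decimals so write-read round trips are exact.
* `mtry` values larger than the actual feature count are clamped.
* Cross-validation folds whose held-out part contains one class are
  excluded from the mean with a warning (AUC is undefined there).
* Ties in AUC-based selection resolve to the earlier grid point; ties in
  window search resolve to the smaller window.

## Problem sizes used in the shipped experiments

The test suite and the acceptance script run the planted-signal study at
~2000 repeats (151 positives at the default fraction), the null study at
1000 repeats, and determinism/fold-balance checks at 300 repeats — sizes
chosen so the full protocol (10×3 CV, 500-tree forests) completes in a few
minutes on one core while keeping ≥100 positives in the planted study.

## Known limitations

* Unknown-labelled repeats are treated as negatives during training; true
  prevalence of interaction among them is unknown.
* The boosted logistic regression and neural network are faithful to their
  family descriptions (stump boosting; single logistic hidden layer) but
  are not byte-level replicas of any particular R implementation.
* Interface spans are taken as given; how residue-level interface lists
  were collapsed into spans upstream is outside the package's scope.
* Only symmetric context windows are searched during optimisation.
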
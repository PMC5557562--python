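# Methods

## Problem and model

`metharg` predicts which arginine residues in a protein are methylated,
from sequence alone. The modelling unit is the *peptide window*: an
odd-length subsequence centered on a candidate arginine, X-padded at the
protein termini so every window is symmetric. The working assumption is
the standard one for this modification: substrate selectivity of protein
arginine methyltransferases is driven largely by the local flanking
context (many known substrates sit in glycine/arginine-rich regions), so
a window of ~19 residues carries most of the predictive signal.

The classifier is a soft-margin C-SVC with an RBF kernel
K(x, x') = exp(−γ‖x−x'‖²), trained on named feature vectors of length
10·L + 4 per window of length L, with hyperparameters (C, γ) chosen by
exhaustive grid search maximizing mean out-of-fold ROC-AUC under
stratified 10-fold cross-validation.

## Dataset construction

* Every arginine yields one window. Annotated sites are positives; all
  other arginines in the same proteins start as *unlabeled*, because
  absence of a report is not evidence of absence.
* Pseudo-negatives are unlabeled windows whose ungapped identity to every
  positive window is below the identity threshold (default 0.4). Both
  sets are then made internally non-redundant by a greedy, input-order
  filter at the same threshold. Because all windows are the same length,
  identity is positional (no alignment); the padding symbol X matches
  nothing, so terminal padding can never create similarity. Filtering is
  applied to windows, not whole proteins: per-position features make
  window-level redundancy the relevant bias.
* Positives are split 4:1 into training and test (test share =
  round(N/5), ties-to-even); the negative test set is drawn at the same
  size, and the remaining negatives form the under-sampling pool from
  which k = 5 balanced (1:1) training subsets are sampled without
  replacement.
* Proteins shorter than 30 aa are rejected; windows touching nonstandard
  letters (B, Z, U, O) are dropped with a warning.

## Feature encoding

Per position (family-major, position-minor order; offsets −(L−1)/2 … 0 …
+(L−1)/2 with 0 the central arginine):

| family | source |
|---|---|
| atchley_1 … atchley_5 | Atchley et al. five-factor physicochemical summary |
| aafreq | positional residue frequency, fit on positive *training* windows only |
| asa, disorder | built-in propensity provider (below) |
| hydro | Kyte–Doolittle hydropathy |
| vdwv | Darby–Creighton van der Waals volume (Å³) |

Whole-peptide globals: average van der Waals volume, GRAVY, net charge at
pH 7, and isoelectric point. Net charge is a Henderson–Hasselbalch sum
over the free termini and ionizable side chains with a Bjellqvist-style
pKa set (generic N-terminal pKa 7.5; the full set is the TSV resource
`metharg/data/pka_bjellqvist.tsv`). The pI is found by bisection on
pH ∈ [0, 14], stopping at |charge| < 1e-4; the charge is strictly
decreasing in pH so the root is unique.

X handling is uniform and deliberate: per-residue scales encode X as 0,
the frequency table treats X as its own 21st symbol, global averages run
over non-X residues only, and the charge model ignores X. Padding
therefore carries positional information (via aafreq) but no
physicochemical signal.

The frequency table is fit on positive training windows only, never on
test windows, to avoid leakage into held-out evaluation.

### Accessibility/disorder provider

Structure-based accessibility and disorder predictors are external tools
by nature, so the package defines a provider contract (two per-residue
vectors in [0, 1]) and ships a deterministic sequence-only stand-in: the
Hopp–Woods hydrophilicity scale (exposure propensity) and the TOP-IDP
scale (disorder propensity), each min-max scaled to [0, 1] and averaged
over a ±3-residue sliding window; X positions score 0.5. This stand-in
preserves the feature families and their smooth positional structure but
is *not* a structure predictor; users can plug real predictors in through
the same contract.

## Feature selection

Each feature is scored by information gain in bits,
IG = H(Y) − H(Y | bin(X)). Continuous features are discretized by
recursive Fayyad–Irani MDL partitioning; a feature on which MDL accepts
no cut scores exactly 0 and is pruned as irrelevant. Features with at
most two distinct values are treated as already discrete and scored by
raw entropy gain — the MDL stopping rule is a guard against fabricating
cut points on continuous data and is not applied to genuinely categorical
indicators. For binary labels all scores lie in [0, 1], and scores are
invariant under strictly monotone transforms (discretization is
rank-based).

On arginine-centered data every per-residue feature at offset 0 is
constant and is pruned — a built-in sanity check that the scorer agrees
with the data design. Ranking ties are broken by canonical feature-name
order via a stable sort, so rankings are reproducible. Ranking is
computed per balanced training subset (positives + one negative subset).
Incremental selection sweeps nested prefixes of the ranking in steps of
50 (plus the full retained set).

If *no* feature scores above zero — which is the expected outcome on
motif-free null data — selection degrades to a no-op and the sweep runs
once on the full feature set, with a warning. This keeps null-control
experiments runnable end to end.

## Training and evaluation

* Features are min-max scaled to [0, 1] with training-set bounds
  (constant features map to 0); test data uses the stored bounds without
  clipping.
* Grid defaults: C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵}, γ ∈ {2⁻¹⁵, 2⁻¹³, …, 2³}; folds
  are stratified and shuffled under the run seed and shared across grid
  points; ties prefer smaller C, then smaller γ. The libsvm solver runs
  at tolerance 1e-6 so decision values are numerically stable.
* The trained machine is persisted as explicit support data (scaled
  support vectors, signed dual coefficients, intercept) in JSON; decision
  values are recomputed from that data, so serialization round-trips
  produce identical scores.
* Each of the k balanced subsets yields one candidate per feature-subset
  size; the candidate with the highest cross-validated AUC is retained as
  the final model and the full per-candidate table is reported. The
  classification threshold is decision value 0; ROC curves use raw
  decision values. Cross-validated metrics are pooled over concatenated
  out-of-fold predictions, so count-based formulas stay exact.
* MCC is defined as 0 when any denominator factor vanishes. The
  trapezoid AUC equals the tie-aware Mann–Whitney statistic.

## Randomness and reproducibility

All randomness flows from a single pipeline seed through a fixed
per-stage derivation (`stage_seed`: split, subsets, CV, synthetic), each
below 2³¹. Reruns with identical inputs and configuration are
bit-reproducible; every pipeline run can write a provenance record
(configuration, derived seeds, package version).

## Synthetic data: what it does and does not show

The generator emulates the one property the model is designed to exploit:
positional residue enrichment around methylated arginines. Background
residues are i.i.d. (uniform with arginine boosted to 0.08 so proteins
carry several candidate sites); 30% of arginines are flagged methylated;
glycines are planted at offsets ±1 and ±2 with probability 0.8 around
methylated sites (never overwriting a methylated arginine). A motif-free
null configuration sets the planting probabilities to 0.

Passing end-to-end tests on this data shows the pipeline recovers planted
positional signal and does not hallucinate signal where none exists. It
does **not** show real-data performance: real methylation contexts have
correlated positions, homologous repetition, compositional biases, and
structural determinants none of which the generator imitates.

## Problem sizes used by the test suite and acceptance script

The shipped end-to-end runs use 300 synthetic proteins (≈600–1300
positive and ≈2400–2900 negative windows after filtering, ≥500 per
class), one balanced negative subset, a 100-feature selection cap, a
3×3 (C, γ) grid, and 10-fold CV — sizes chosen so a full run completes in
about a minute on a laptop-class CPU while keeping every stage of the
method exercised at realistic class ratios. The full canonical grid and
k = 5 subsets remain the library defaults.

## Known limitations

* The pseudo-negative construction inherits the field's standard caveat:
  unreported sites may be genuinely methylated, so some "negatives" are
  mislabeled.
* The built-in accessibility/disorder provider is a propensity smoother,
  not a predictor; feature families asa/disorder carry less information
  than they would with real predictors plugged in.
* Ungapped window identity approximates clustering-based redundancy
  reduction; it is exact for equal-length windows but blind to shifted
  repeats.
* No probability calibration: scores are raw SVM decision values.
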
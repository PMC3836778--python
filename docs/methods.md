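# Methods

## Problem and model

`presep` treats secretion of a recombinant protein into the *Pichia pastoris*
culture supernatant as a binary sequence-classification problem. The working
hypothesis is that, beyond the (externally removed) N-terminal signal peptide,
internal sequence features — global composition and short-range
physicochemical ordering — carry a detectable secretion signal. Sequences are
therefore summarized as pseudo amino acid composition (PseAAC) vectors and
classified with a random forest.

## Property scales and normalization

Six residue scales are bundled (`presep/data/aa_scales.tsv`): hydrophobicity,
Hopp–Woods hydrophilicity, side-chain mass, pK₁ (α-COOH), pK₂ (α-NH₃⁺) and pI
at 25 °C — the canonical set used by standard PseAAC tooling. Each raw scale
H⁰ₖ is converted once per table load to

    Hₖ(i) = (H⁰ₖ(i) − mean₂₀) / sqrt( Σᵢ (H⁰ₖ(i) − mean₂₀)² / 20 ),

i.e. centred over the 20 residues and divided by the RMS deviation. This makes
scales of wildly different units (daltons vs pH units) commensurable inside
one correlation function. The conversion is idempotent and invariant (up to
sign) under affine rescaling of the raw scale, both enforced by tests. A
constant scale has no information and is rejected rather than silently mapped
to zeros.

## Encoding

With f_u = count(u)/L (so Σf = 1) and normalized scales Hₖ:

- **Type I**: Θ(Rᵢ, Rᵢ₊ⱼ) = (1/i) Σₖ [Hₖ(Rᵢ₊ⱼ) − Hₖ(Rᵢ)]², θⱼ = average of Θ
  over the L−j lag-j pairs. Vector: x_u = f_u / (1 + w Σθ) for u ≤ 20,
  x₂₀₊ⱼ = w θⱼ / (1 + w Σθ). All components non-negative, summing to 1.
- **Type II**: τⱼₖ = (1/(L−j)) Σᵢ Hₖ(Rᵢ)·Hₖ(Rᵢ₊ⱼ), one track per scale,
  ordered lag-major (all scales at lag 1, then lag 2, …). τ may be negative;
  the vector still sums to 1. If the correlation mass exactly cancels the
  composition mass (|1 + w Στ| ≤ 1e-12) the encoding is undefined and an
  error is raised rather than returning an unbounded vector.

Tunables: `w` (correlation weight, default 0.05), `λ` (maximum lag, default
19), the ordered property subset (default all six; Type II dimension is
20 + i·λ for i properties). The defaults are the best-performing Type I
setting in the evaluation protocol this package implements.

**Short sequences.** A strict reading requires L > λ, which would make
terminal-window experiments (17-residue windows under λ = 19) undefined. The
package uses λ_eff = min(λ, L−1): lags beyond λ_eff contribute a correlation
factor of exactly 0 and the dimension never changes, keeping feature matrices
rectangular across mixed lengths. Zero-padding is the least-information
choice and leaves full-length encodings untouched.

**Residue policy.** Inputs are expected to be curated; non-standard residues
(B, J, O, U, X, Z) raise an error naming position and symbol under the default
`strict` policy. A `drop` policy (remove the residue) is available for
exploratory use. Terminal `*` stop symbols are always stripped.

All accumulation is double precision; lag averages are computed as one sum
divided once. The vectorized encoder is verified against an independent,
literal double-loop implementation to 1e-9 across both types and the w/λ
grid, and the whole encoding is invariant under sequence reversal (a property
of both correlation families, used as a whole-pipeline test).

## Classifier, propensity and reliability

A scikit-learn `RandomForestClassifier` with 500 trees (the conventional
random-forest default; the method is insensitive to tree count well before
this) and otherwise default settings, fixed `random_state`, no class
weighting or resampling by default — imbalanced training sets are used as-is,
with `class_weight` exposed for exploration.

The propensity O is the fraction of trees voting "secreted" (per-tree hard
votes, not averaged leaf probabilities), so O is a genuine vote share on the
grid {0, 1/T, …, 1}. The call is secreted iff O ≥ 0.5; the tie goes to
"secreted" as a fixed documented convention. The reliability index is

    RI = floor(20 · |O − 0.5|) ∈ {0, …, 10},

with the product rounded at 1e-9 before flooring so decimal-exact vote
fractions (O = 0.55 → 1.0) are not dropped below the floor boundary by binary
representation. "INTEGER" is read as truncation; floor and round differ only
on measure-zero grid points of the vote fraction. RI is symmetric under
O → 1−O and non-decreasing in |O − 0.5| (enforced by an exhaustive grid
test). Models persist via joblib with a JSON sidecar carrying the encoding
parameters, seed, class counts and dimension, so a reloaded model re-encodes
raw FASTA exactly as at training time.

## Evaluation protocol

- **Cross-validation:** stratified k-fold (default k = 20), pooled (micro)
  confusion counts over all out-of-fold predictions. Stratification is used
  because at a 1:7 class ratio unstratified 20-folds can contain zero
  positives; pooling is used because per-fold MCC with ~7 positives per fold
  is unstable. If the smaller class has fewer than k members, k is reduced to
  that size with a warning.
- **Metrics:** sensitivity, specificity, Q2, MCC (0 when a denominator
  factor vanishes), and AUC by the rank/trapezoid method with tied scores
  sharing rank — checked against all-pairs concordance counting.
- **RI coverage:** for each threshold t = 0…10, the fraction of proteins
  with RI ≥ t and the accuracy among them, computed cumulatively over the
  pooled out-of-fold predictions.
- **Parameter sweep:** one cross-validation per (type, w, λ) grid point;
  default grid w ∈ {0.05, …, 0.50 step 0.05}, λ ∈ {1, …, 20}. Rows are sorted
  by MCC descending with ties broken by (mode, w, λ) ascending.
- **Terminal scan:** for each terminal (N/C) and window length k, sequences
  are truncated, re-encoded (λ_eff padding) and cross-validated.
- **Seeding:** every stage derives its seed from one master seed through a
  stable SHA-256 hash (`presep.util.derive_seed`): the fold assignment uses
  one derived seed shared across all sweep/scan points (so settings are
  compared on identical folds), while each grid point's forests get their own
  derived seed. Terminal-scan seeds are keyed on k only, so N and C windows
  at the same k use identical forests — and give identical results when k
  exceeds every sequence length. Everything is reproducible bit-for-bit.
- **Propensity–measurement correlation:** ordinary least squares of a
  measured extracellular-activity percentage on the predicted propensity;
  R² is the squared Pearson correlation. The package bundles a six-protein
  β-galactosidase validation table (predicted propensity vs measured
  extracellular percentage) on which this regression yields R² ≈ 0.968.

## Synthetic fixtures

The generator (`presep.fixtures`) emulates a curated two-class secretion
dataset without any external download. Background composition is uniform over
the 20 residues (a `natural` Swiss-Prot-frequency background is available) so
that planted signal is the only structure. Two signals:

- **Composition bias δ** — the positive class gets δ extra probability mass
  spread over a designated hydrophobic set, withdrawn evenly from the rest.
  The default set is the branched-chain aliphatic trio I/L/V: concentrating
  the default δ = 0.15 on three residues doubles each one's frequency in
  positives, which makes the default 200+200 fixture *strongly* separated —
  20-fold CV recovers it at MCC ≈ 0.92–0.95 — the regime the signal-recovery
  tests assume. (Spreading the same δ over a broad 7-residue hydrophobic set
  was measured to give only MCC ≈ 0.84–0.89, i.e. moderate separation, and
  was rejected as the default for that reason.)
- **Periodic motif** — copies of a motif written into one class at a fixed
  period, optionally restricted to the first k residues. An N-terminal-only
  motif creates the N/C asymmetry the terminal scan is designed to expose.

Lengths are uniform on [80, 200] by default (a realistic mature-protein range
that also exercises the λ_eff rule at λ = 19). Lengths, residues and motif
placement draw from separate RNG streams derived from the master seed, so
changing one knob leaves the other draws unchanged. An `imbalanced_preset`
(136 positive / 957 negative) emulates the realistic class ratio.

What fixtures do **not** emulate: real secretome composition, homology
structure, domain architecture, or any biology of the secretory pathway.
Passing signal-recovery tests demonstrates that the pipeline detects the kind
of signal PseAAC can represent; it says nothing about accuracy on real
secretion data, which requires the external curated dataset.

## Problem sizes

The shipped evaluation runs use 400-sequence fixtures, 20-fold CV and
500-tree forests (≈ 40 forest fits per scan or null experiment); a full
default-grid sweep (2×10×20 points × 20 folds) is supported but is the
long-running entry point and is sized by the caller. Unit tests use smaller
forests and sets; the study-condition runs live in the end-to-end tests and
`scripts/acceptance.py`.

## Known limitations

- Dataset-scale performance claims (MCC ≈ 0.78, Q2 ≈ 0.95, AUC ≈ 0.94 on a
  curated 136/957 secretion dataset) cannot be reproduced offline; the
  package asserts formula-level and signal-recovery properties instead.
- The length filter (< 50 residues excluded) is the only curation step
  implemented; redundancy reduction, signal-peptide removal and
  transmembrane filtering are upstream external preprocessing, recorded only
  as provenance.
- Only the random-forest learner is provided, and no nested CV / unbiased
  hyperparameter-selection analysis is performed — the sweep reports raw
  cross-validated scores per grid point.
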
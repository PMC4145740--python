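# Methods

## Problem and model

S-nitrosylation is a cysteine-specific post-translational modification.
The predictor treats each candidate cysteine as a fixed-length peptide
window and learns a binary decision (modified / unmodified) from curated
site annotations. Two modelling assumptions are baked in:

* **Locality.** Everything the predictor sees lies within ±10 residues of
  the cysteine. Long-range structural context enters only through
  precomputed per-residue predictions (PSSM, secondary structure, solvent
  accessibility, disorder), never through coordinates.
* **Sparse class structure.** A test peptide is assumed to be well
  approximated by a sparse combination of training peptides of its own
  class. Classification is therefore reconstruction-based: code the test
  vector over the training dictionary with orthogonal matching pursuit
  (OMP), then compare per-class reconstruction residuals
  `‖y − Xα_k‖₂`, where `α_k` keeps only class k's coefficients. The
  masked vectors partition `α` exactly, so `Σ_k α_k = α`.

The kernel variant replaces inner products with the Laplacian kernel
`Ψ(x, y) = exp(−‖x − y‖/δ)`. Multiplying the representation equation by
the lifted dictionary turns it into the finite linear system
`k(X, y) = K α` with `K_ij = Ψ(x_i, x_j)`, so OMP runs on the n×n Gram
matrix and residuals are measured in that same system. This choice (rather
than the implicit feature-space residual, which needs `Ψ(y, y)`
bookkeeping) is exact for the system actually solved; the feature-space
variant would differ only by a per-sample constant plus cross terms and is
deliberately not the default.

## Pipeline stages

1. **Windowing** (`peptides`): 21-mer windows centred on each annotated
   cysteine. Windows truncated by a sequence end are padded with `X` on
   whichever side is short so the cysteine stays at position 11 — the
   positional feature blocks are meaningless otherwise. A compatibility
   mode (`pad_mode="end"`) instead appends all padding after the available
   residues, for reproducing datasets built with left-aligned truncation.
   Non-standard letters (including selenocysteine `U`) map to `X`, since
   the encoders define values only for the 20 standard residues.
2. **Encoding** (`features`): five blocks in fixed order — conservation
   (21×20 PSSM rows), physicochemical factors (20 flank positions × 5),
   structure (21 × one-hot helix/strand/other + buried/exposed),
   composition (20 channels over the flanks, the central cysteine
   excluded), disorder (21 scores) — 666 columns total. Padded positions
   contribute zeros in every block, a neutral value. Composition counts
   are divided by the flank size (20) so the block is scale-compatible
   with the one-hot blocks. The factor table is the widely used
   five-factor summary of amino-acid physicochemical indices (polarity,
   secondary-structure propensity, molecular volume, codon diversity,
   charge), shipped as a data file and replaceable by the user. The fixed
   block order makes feature indices in rankings stable and citable.
3. **Ranking** (`mrmr`): greedy first-order mRMR. Step 1 maximizes
   relevance `I(X_j; Y)`; step t maximizes relevance minus the mean mutual
   information with the already-selected set. MI is the plug-in estimate
   in nats (the base rescales all scores equally and cannot change the
   order). Continuous columns are discretized into 3 equal-width bins by
   default; columns with at most 3 distinct values (binary flags, one-hot
   indicators) pass through unchanged. An alternative literal reading of
   the ranking stage — scoring each feature alone by the subset objective
   with |S| = 1 — reduces to relevance minus self-entropy, which penalizes
   high-entropy features regardless of their redundancy; the greedy scheme
   is used instead as the standard and better-behaved formulation.
4. **Selection** (`selection`): incremental feature selection evaluates
   nested prefixes of the ranking (sizes step, 2·step, …, p) by stratified
   k-fold cross-validation and keeps the MCC-argmax prefix, smallest size
   on ties. The fold partition is computed once per run and reused at
   every size, so the curve isolates the effect of the features. Out-of-
   fold predictions are pooled into a single confusion matrix before
   computing metrics: with ~1:2 imbalance and 10 folds, per-fold MCC
   values are dominated by a handful of positives and averaging them is
   unstable, while pooled counts are additive and well defined.
5. **Classification** (`sparse`): SRC ℓ₂-normalizes dictionary columns by
   default (standard practice; it makes the correlation step scale-free);
   KSRC uses raw Gram columns, whose entries are already bounded in
   (0, 1]. Both are switches.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| window size | 21 (10+1+10 residues) | locality assumption above |
| `sparsity` (OMP budget k) | 50 atoms | reference operating point of the framework |
| `tol` (OMP residual stop) | 1e-6 | early exit on (near-)exact reconstruction |
| `delta` (Laplacian bandwidth) | 100 | reference value, calibrated to PSSM-scale features whose pairwise distances are O(10²); for O(1)-scale data use `delta="median"`, the median pairwise training distance, a standard bandwidth heuristic resolved at fit time |
| kernel distance | ℓ₂ | ℓ₁ available (`metric="l1"`); both give valid positive-semidefinite Laplacian kernels |
| `n_bins` (MI discretization) | 3 equal-width | coarse enough to be stable at n ≈ 2000 samples; equal-frequency available |
| CV folds | 10 | each fold keeps ≥ 6 positives at the reference dataset size |
| IFS `step` | 1 | per-feature curve; larger steps trade resolution for time since KSRC evaluation is O(n²) per prefix |
| split fraction | 0.8, stratified | per class, round-half-up of n·0.8 to train; reproduces a 4:1 split exactly |

## Numerical choices

* **MCC degeneracy:** any zero factor in the denominator gives MCC := 0
  (the standard convention); undefined SN/SP ratios are likewise 0.
* **Ties:** OMP breaks correlation ties toward the lowest column index;
  classification breaks residual ties toward the lowest class id; mRMR
  breaks objective ties toward the lowest feature index, with a 1e-9
  tolerance that absorbs float noise between mathematically equal scores.
* **OMP degeneracies:** a residual orthogonal to every remaining column
  stops the iteration (returning the zero solution when that happens at
  step one); a column that would make the selected set rank-deficient is
  dropped with a warning and never reconsidered. The per-iteration
  residual norm is non-increasing by construction (each step re-projects
  onto a superset of columns).
* **Sign-blindness:** OMP correlates by absolute inner product, so `x` and
  `−x` are the same atom up to coefficient sign. On sign-symmetric data
  (e.g. antipodal class means after unit-normalization) reconstruction
  residuals cannot separate the classes; this is a property of the model,
  not a defect of the solver.

## What the synthetic generators do and do not emulate

`make_feature_data` produces two-class Gaussian columns: a chosen number
of informative features whose class means differ by `effect` standard
deviations (default 5 informative + 45 noise, effect 3, n = 200 at the
1:2 positive:negative ratio typical of curated cysteine-site data). It
validates ranking and classification against a known ground truth.

`make_peptide_data` emulates the *shape* of a site dataset end to end:
random sequences with one annotated cysteine each, an acidic (D/E) flank
enrichment plus elevated flank disorder in positives, and internally
consistent synthetic per-residue predictions (the synthetic PSSM encodes
residue identity with additive noise, so conservation mirrors
composition). It deliberately does **not** reproduce real S-nitrosylation
motifs, realistic PSSM statistics, inter-site correlation within one
protein, or homology structure between sequences. Passing tests therefore
demonstrate that the machinery recovers planted signal of realistic
geometry — not that any particular accuracy will be attained on real
proteomes, where signal is far weaker (real-data MCCs for this problem
class are in the 0.1–0.3 range) and redundancy filtering of the input
sequences matters.

`make_low_coherence_dictionary` builds random unit-norm 6×10 frames with
pairwise coherence ≈ 0.3 by alternating projections (clip the Gram
off-diagonal, project back to rank 6). Independent Gaussian columns in
low dimension almost never meet such a bound, while near the Welch limit
(≈ 0.27 for 6×10) greedy pursuit is provably reliable for 2-sparse
targets (μ < 1/(2k−1)); these systems are the testbed for exact-recovery
checks of the OMP solver.

## Evaluation sizes

Simulation-based checks use n = 200 samples (1:2 classes) with 50
features, five seeds for multi-seed statements; solver oracles use 200
random 6×10 systems (exhaustive support search) and 50 random 12×5 binary
datasets (brute-force ranking). These sizes give stable pass/fail
behaviour while keeping the full suite around a minute of CPU.

## Known limitations

* Mutual information uses a fixed discretization; rankings can shift with
  the bin count, and no universally "correct" binning exists for mixed
  continuous/one-hot feature sets.
* KSRC prediction is O(n²) memory in the training-set size (the Gram
  matrix) and O(n·k²) time per test sample; dataset sizes beyond ~10⁴
  training peptides need sub-sampling or a different solver.
* The pooled-CV estimate of a class-prior-sensitive classifier carries a
  small negative MCC bias on null data (each held-out sample's class is
  slightly under-represented in its training folds); on effect-free data
  the per-seed CV MCC scatters around a mean of about −0.1 to +0.06
  rather than exactly 0.
* External predictors (PSI-BLAST, disorder, secondary structure) are
  consumed, never run; garbage annotations yield garbage features.
* Sequence-redundancy filtering is out of scope and must be done upstream.
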
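# Methods

## Problem and model

`nifscan` treats nif-protein identification as hierarchical supervised
classification of fixed-length sequence descriptors. The underlying
assumptions are those of any alignment-free compositional classifier:
that membership in the nif categories leaves a signature in residue
composition and short-range residue ordering, and that this signature is
learnable by a kernel machine without homology search. The two-stage
decomposition (binary nif/non-nif, then six-way categorization of
positives) matches how the tool is used on a proteome: the second-stage
model never has to model the vast non-nif background, and the
probability threshold τ gives an explicit false-positive control knob at
the categorization step.

## Feature encoders

All encoders index residues by the canonical alphabet
`A,C,D,E,F,G,H,I,K,L,M,N,P,Q,R,S,T,V,W,Y`; this order fixes descriptor
order everywhere, and pair descriptors are row-major over it.

- **AAC** (20): residue counts over N. Order-free baseline.
- **DPC** (400): adjacent ordered pairs over N−1.
- **GPC** (400): ordered pairs `(i, j)` with G intervening residues
  (offset G+1), denominator N−G−1. G = 1 and G = 2 are the practically
  used settings; any G ≥ 1 is accepted with the length precondition
  N ≥ G+2.
- **PseAAC** (20+λ): Chou's type-1 formulation. The sequence-order factor
  τ_k is the mean over positions of the coupling
  Θ(i,j) = ⅓ Σ_p (v_p(j) − v_p(i))², where the three scales p are the
  classical hydrophobicity, hydrophilicity (Hopp–Woods) and side-chain
  mass tables, each standardized to mean 0 / SD 1 over the 20 residues
  (population SD). Components are jointly normalized by 1 + w·Στ_k so the
  vector sums to 1; the weight w (default 0.05) and tier count λ
  (default 1) are exposed. As w → 0 the first 20 components converge to
  AAC, which the suite checks at w = 1e−9.
- **CTD** (310 = 20 + 190 + 100): defined over the 20-letter alphabet
  itself, not over physicochemical groups — the grouped Dubchak variant
  would give 147 descriptors, whereas this package's contract is the
  310-dimensional alphabet-level form. Transition counts unordered
  heterogeneous adjacent pairs in either order over N−1 (190 pairs).
  Distribution records five anchors per residue — the 1st occurrence and
  the ceil(q·n_i)-th for q ∈ {0.25, 0.5, 0.75, 1.0} — as scaled 1-based
  positions 100·pos/N; a residue absent from the sequence contributes
  five zeros. Five anchors (not four) are required for the 20·5 block
  that makes the total 310.
- **ACF** (P·n): r_k(p) = mean_t v_p(s_t)·v_p(s_{t+k}) for lags k = 1..n,
  property-major ordering, with v_p standardized property values. The
  default backing table has P = 531 properties. The standardized-product
  form (rather than a mean-centered autocovariance along the sequence)
  is a declared design choice; it makes the homopolymer and alternating
  closed forms exact, and reversal symmetry holds for every lag.

### Property table

The curated 531-property physicochemical collection is not bundled;
instead the package ships a deterministic **synthetic** 531×20 table
(`synthetic_aaindex_table`, fixed seed, standard-normal draws,
standardized per property). It has the right shape and scaling for the
ACF machinery, but individual descriptor values carry no biochemical
meaning — analyses that interpret specific ACF descriptors need a real
table, which `load_aaindex` accepts in either the flat `H`/`I`/`//`
format or a TSV snapshot. Loading applies a fixed policy so the property
count is reproducible: zero-variance rows are excluded first; rows with
missing values are dropped when at least 531 complete rows remain and
mean-imputed otherwise; the first 531 surviving rows (file order) are
kept and standardized.

## SVM core

Fitting is scikit-learn `SVC` inside a pipeline whose first step is
per-column standardization learned on the training split only (never on
test folds — the fold harness passes only training rows to `fit`).
Defaults pin the classical SVM ecosystem defaults: cost C = 1,
γ = 1/#features, degree 3, coef0 = 0. Whether to scale features at all
is a package decision, not part of the method's definition; the scaling
makes the classifier invariant to per-column rescaling, which the suite
verifies. Probabilities come from Platt-style calibration fitted during
training (`probability=True`), with the SVC's `random_state` seeded so
refits are bit-reproducible. Multi-class decomposition is the SVC
default: one-vs-one voting with pairwise probability coupling. Argmax
ties break by the model's sorted label order.

`select_kernel` reproduces the kernel-selection protocol: a seeded
100-per-class subsample (an undersized class is used whole, with a
warning), five-fold stratified CV per kernel at default parameters, and
the highest mean accuracy wins with ties broken radial > polynomial >
sigmoid > linear.

Persistence is a joblib archive wrapping the fitted payload with a
format-version tag; loading refuses unversioned or mismatched archives.

## Evaluation

- Metrics are computed from the four observed-class counts (see README);
  a metric whose denominator vanishes is reported as NaN, named in
  `MetricSet.undefined`, excluded from averages, and the exclusion is
  logged — it is never silently zeroed.
- Five-fold CV is stratified ("approximately equal class counts per
  fold") with seeded shuffling.
- The jackknife harness refits n times, aggregates one confusion matrix,
  and derives per-class metrics by one-vs-rest collapsing of that
  matrix.
- Balanced resampling draws exactly |pos| negatives per sample set,
  without replacement within a set and independently across sets (set m
  uses seed + m), so "almost equal" is implemented as exactly equal.
  Standard error is the sample SD of per-set means over √M.
- ROC AUC uses the midrank (Mann–Whitney) convention; tests check it
  against brute-force concordant-pair counting.

## Two-stage flow

Stage 1 calls nif by argmax (equivalently, probability ≥ 0.5 in the
binary case); the explicit threshold τ applies only at stage 2, default
0.4 — the operating point at which whole-proteome screens suppress most
false positives while keeping true nif calls, and overridable per
prediction call. Sub-threshold stage-2 outcomes are reported as
`unassigned` with their best probability, keeping screens auditable.
Each sequence is encoded once and scored by both stages. Sequences
failing the encoder preconditions produce per-sequence error records
while the rest proceed. Stage 2 trains with a derived seed (seed+1) so
the two Platt calibrations do not share CV splits.

## Synthetic data

The generators define the study conditions for all statistical tests:

- `two_class_dataset(n_per_class, delta)`: class A draws residues
  i.i.d. uniform; class B shifts total mass `delta` onto the fixed
  subset {A, C, D, E, F} (renormalized). Lengths are uniform on
  [150, 250] — a typical bacterial-protein length scale. delta = 0 is
  the null fixture (identical distributions ⇒ chance-level accuracy);
  delta = 0.3 with 100 sequences per class is comfortably separable
  from composition features.
- `multiclass_dataset(n_per_class, n_classes, signal)`: class c enriches
  the disjoint canonical residue pair (2c, 2c+1) by 0.15·signal each and
  adds a first-order Markov bias (after the first pair residue, mass
  min(0.9, 0.8·signal) moves onto the second), so ordering-sensitive
  features carry information beyond composition. signal = 0 collapses
  all classes onto the uniform i.i.d. model.
- `two_stage_dataset`: six such classes plus a non-nif background
  enriched on the eight residues untouched by the class pairs, with
  matched total enrichment mass.

Sizes used by the suite and the acceptance script — 100 per class for
binary CV (10 balanced sample sets), 12 per class for the six-class
jackknife, 30 per class (plus 180 non-nif) for two-stage training with
60 + 60 held-out probes — are desk-scale study conditions chosen so that
separable fixtures are cleanly separable and null fixtures are honest
nulls. Passing tests therefore demonstrate that the machinery is
correct and that the harnesses neither destroy real signal nor invent
spurious signal; they do not measure accuracy on real nif proteins,
whose difficulty comes from homology structure, shared domains and
phylogenetic correlation that the i.i.d./first-order generators do not
emulate.

## Numerical choices and degenerate inputs

- Counting encoders are exact rational arithmetic realized in float64;
  the brute-force cross-checks assert bit equality.
- Distribution anchors use exact `ceil` on binary-exact quantiles
  (0.25, 0.5, 0.75, 1.0), so no floating fuzz is needed.
- Zero-variance feature columns pass through standardization unscaled
  (scikit-learn's convention), so constant descriptors are harmless.
- Empty datasets, single-class labels, undersized classes, too-short
  sequences, non-standard residues and unwritable archives all raise
  informative errors rather than degrading silently.
- FASTA reading uppercases bodies, strips one terminal `*`, takes the
  id as the first header token, and rejects headerless leading content
  with a line number; duplicate removal is exact residue-string
  equality (case-insensitive), keeping the first occurrence.

## Known limitations

- The default ACF table is synthetic (see above).
- No redundancy clustering (CD-HIT-style identity reduction) is
  provided; duplicate removal is exact-match only.
- Kernel hyperparameters are fixed at ecosystem defaults; there is no
  grid search or class weighting.
- The synthetic generators do not model homology, domains, or
  phylogeny; conclusions about real-proteome accuracy require real
  labelled data through the same API.
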
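# nifscan

Identification and categorization of nitrogen-fixation (nif) proteins from
amino-acid sequence alone.

Biological nitrogen fixation is carried out by diazotrophs — microbes whose
nitrogenase enzyme complex reduces atmospheric N₂ to ammonia. Six genes are
considered essential for a functional nitrogenase: the structural genes
*nifH* (Fe protein), *nifD* and *nifK* (α and β subunits of the FeMo
protein), plus the cofactor-biosynthesis genes *nifB*, *nifE* and *nifN*.
`nifscan` is a library (and thin CLI) for scanning predicted proteomes for
proteins encoded by these six gene categories, aimed at microbiologists and
bioinformaticians annotating candidate diazotrophs.

## Method

Sequences over the 20-letter standard alphabet are mapped to fixed-length
numeric vectors by six encoders:

| scheme | dimension | descriptor |
|---|---|---|
| AAC | 20 | residue frequencies `f_i / N` |
| DPC | 400 | adjacent ordered-pair frequencies `M_j / (N−1)` |
| GPC | 400 | ordered pairs with G intervening residues, `D_G(i,j) / (N−G−1)` |
| PseAAC | 20 + λ | Chou type-1 pseudo amino-acid composition |
| CTD | 310 | composition (20) + transition (190) + distribution (100) |
| ACF | 531·n | lagged physicochemical-property autocorrelations |

The encoded vectors feed support vector machines (radial kernel by
default; a seeded selection routine compares the radial, linear,
polynomial and sigmoid kernels by five-fold CV on a 100-per-class
subsample). Prediction is hierarchical: a **stage-1 binary SVM** separates
nif from non-nif, and stage-1 positives go to a **stage-2 six-class SVM**
that assigns a category when its Platt-calibrated probability reaches the
threshold τ (default 0.4; sub-threshold calls are reported as
`unassigned`).

Evaluation follows three protocols: stratified five-fold CV, jackknife
(leave-one-out) for the six-class model, and — because real proteomes are
overwhelmingly non-nif — repeated balanced undersampling: M random balanced
sample sets, five-fold CV in each, metrics averaged over sets. Metrics are
computed from observed-class counts as

```
Sn = 1 − fn/Np      Sp = 1 − fp/Nn      Ac = 1 − (fn+fp)/(Np+Nn)
Pre = 1 − fp/(Np − fn + fp)
MCC = [1 − (fn/Np + fp/Nn)] / sqrt[(1 + (fp−fn)/Np)(1 + (fn−fp)/Nn)]
```

which are algebraically identical to the classical TP/TN/FP/FN forms (the
test suite proves this on random counts).

## Worked example

`examples/04_two_stage_screen.py` trains the two-stage model on a seeded
synthetic dataset (six separable nif-like classes of 30 sequences plus a
disjoint non-nif background) and screens 40 held-out probes:

```
40 probes -> 30 called nif at stage 1, 30 categorized at tau = 0.4, 0 unassigned
40/40 probes labelled correctly end to end

top sequences per predicted category (id, probability):
  nifB: nifB_3 0.950, nifB_0 0.890, nifB_1 0.855
  nifD: nifD_3 0.970, nifD_2 0.968, nifD_0 0.920
  ...
```

All 30 nif probes pass stage 1 and receive their true category above
τ = 0.4, and all 10 non-nif probes are rejected at stage 1. The top-3
table is the per-category summary a proteome screen surfaces: the highest
stage-2 probabilities per predicted nif category.

`examples/02_balanced_crossval.py` shows the balanced-resampling harness on
a separable fixture (accuracy ≈ 0.98) and on a null fixture with
identically distributed classes (accuracy ≈ 0.5, i.e. the harness invents
no signal); `examples/03_jackknife_multiclass.py` prints the jackknife
confusion matrix and per-class one-vs-rest metrics.

The same operations are scriptable from the shell:

```
nifscan train --class-fasta nifH=nifH.fasta ... --non-nif neg.fasta -o model.joblib
nifscan predict proteome.fasta --model model.joblib -o predictions.tsv --tau 0.4
nifscan crossval --pos nif.fasta --neg non_nif.fasta --sample-sets 100
```

`predict` writes a four-column table (serial, sequence id, predicted
category or `non-nif`/`unassigned`, probability).

## Layout

- `src/nifscan/` — library: `sequences` (FASTA I/O, filtering),
  `encoders` + `aaindex` (feature schemes), `svm` (kernels, training,
  persistence), `metrics` + `crossval` (evaluation), `pipeline`
  (two-stage flow), `synthetic` (seeded dataset generators), `cli`.
- `examples/` — one narrative script per capability.
- `docs/methods.md` — model assumptions, parameter choices, limitations.
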
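"""Two-stage prediction flow for proteome-wide nif protein screening.

Stage 1 is a binary SVM separating nif from non-nif proteins; only
sequences called nif proceed to stage 2, a six-class SVM assigning one of
the nif gene categories (nifB, nifD, nifE, nifH, nifK, nifN). A stage-2
category is reported only when its probability reaches the threshold tau
(default 0.4, chosen to suppress false positives in whole-proteome scans);
sub-threshold calls are reported as "unassigned" rather than dropped, so a
screen remains auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alphabet import is_standard
from .encoders import FeatureMatrix, concat_matrices, encode_dataset, scheme_min_length
from .sequences import LabeledDataset, ProteinSequence
from .svm import KernelSpec, TrainedModel, predict_scores, train_svm

logger = logging.getLogger(__name__)

NIF_LABEL = "nif"
NON_NIF_LABEL = "non-nif"
DEFAULT_TAU = 0.4


@dataclass(frozen=True)
class PredictionRecord:
    """Per-sequence outcome of the two-stage flow.

    A category is present only for stage-1 nif calls whose best stage-2
    probability reaches tau; ``category_prob`` still reports the best
    stage-2 probability for unassigned nif calls. Sequences the encoder
    rejects carry an ``error`` message instead of predictions.
    """

    sequence_id: str
    stage1_label: str | None = None
    stage1_prob: float | None = None
    category: str | None = None
    category_prob: float | None = None
    error: str | None = None


@dataclass
class TwoStageModel:
    """Binary (stage 1) and six-class (stage 2) SVMs sharing one encoder."""

    stage1: TrainedModel
    stage2: TrainedModel
    tau: float = DEFAULT_TAU
    scheme: str = "ctd"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must lie in [0, 1]")
        if (self.stage1.scheme, self.stage1.n_features) != (
            self.stage2.scheme,
            self.stage2.n_features,
        ):
            raise ValueError("stage-1 and stage-2 models expect different features")


def fit_two_stage(
    nif_by_class: LabeledDataset,
    non_nif: Sequence[ProteinSequence],
    scheme: str = "ctd",
    params: dict | None = None,
    kernel: KernelSpec = KernelSpec(),
    tau: float = DEFAULT_TAU,
    seed: int = 0,
) -> TwoStageModel:
    """Train both stages from per-category nif sequences and a non-nif set.

    Stage 1 pools all nif sequences as positives against ``non_nif``;
    stage 2 is trained on the nif categories only. Both stages share the
    encoder, kernel and scaling policy; the nif sequences are encoded once.
    """
    params = dict(params or {})
    if len(non_nif) == 0:
        raise ValueError("non-nif training set is empty")
    for lab, seqs in nif_by_class.by_label().items():
        if len(seqs) < 2:
            raise ValueError(f"nif class {lab!r} has {len(seqs)} sequences; need >= 2")

    X_nif = encode_dataset(nif_by_class.sequences, scheme, **params)
    X_non = encode_dataset(non_nif, scheme, **params)

    y1 = np.array([NIF_LABEL] * len(X_nif) + [NON_NIF_LABEL] * len(X_non), dtype=object)
    stage1 = train_svm(concat_matrices(X_nif, X_non), y1, kernel=kernel, seed=seed)
    # distinct derived seed so the two Platt calibrations are independent
    stage2 = train_svm(X_nif, list(nif_by_class.labels), kernel=kernel, seed=seed + 1)
    logger.info(
        "fitted two-stage model: stage1 on %d nif + %d non-nif, stage2 on %d across %d classes",
        len(X_nif), len(X_non), len(X_nif), len(nif_by_class.label_set),
    )
    return TwoStageModel(stage1=stage1, stage2=stage2, tau=tau, scheme=scheme, params=params)


def predict_two_stage(
    model: TwoStageModel,
    seqs: Sequence[ProteinSequence],
    tau: float | None = None,
) -> list[PredictionRecord]:
    """Run the two-stage flow; exactly one record per input sequence.

    Sequences failing the encoder's preconditions yield error records while
    the rest are still processed. Counts at each flow edge are logged.
    """
    tau = model.tau if tau is None else tau
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    min_len = scheme_min_length(model.scheme, model.params)

    records: dict[int, PredictionRecord] = {}
    valid: list[tuple[int, ProteinSequence]] = []
    for i, seq in enumerate(seqs):
        if not is_standard(seq.residues):
            records[i] = PredictionRecord(seq.id, error="non-standard residues")
        elif seq.length < min_len:
            records[i] = PredictionRecord(
                seq.id,
                error=f"sequence length {seq.length} below {model.scheme} minimum {min_len}",
            )
        else:
            valid.append((i, seq))

    if valid:
        X = encode_dataset([s for _, s in valid], model.scheme, **model.params)
        s1 = predict_scores(model.stage1, X)
        nif_rows = [r for r, sc in enumerate(s1) if sc.label == NIF_LABEL]
        s2 = predict_scores(model.stage2, X.take(nif_rows)) if nif_rows else []
        s2_by_row = dict(zip(nif_rows, s2))
        for r, (i, seq) in enumerate(valid):
            sc1 = s1[r]
            if sc1.label != NIF_LABEL:
                records[i] = PredictionRecord(
                    seq.id, stage1_label=sc1.label, stage1_prob=sc1.max_prob
                )
            else:
                sc2 = s2_by_row[r]
                assigned = sc2.max_prob >= tau
                records[i] = PredictionRecord(
                    seq.id,
                    stage1_label=NIF_LABEL,
                    stage1_prob=sc1.max_prob,
                    category=sc2.label if assigned else None,
                    category_prob=sc2.max_prob,
                )

    out = [records[i] for i in range(len(seqs))]
    n_err = sum(1 for r in out if r.error)
    n_nif = sum(1 for r in out if r.stage1_label == NIF_LABEL)
    n_cat = sum(1 for r in out if r.category is not None)
    logger.info(
        "two-stage prediction: %d input, %d errors, %d nif calls, %d categorized, %d unassigned",
        len(out), n_err, n_nif, n_cat, n_nif - n_cat,
    )
    return out


def top_k_report(
    records: Sequence[PredictionRecord], k: int = 3
) -> dict[str, list[PredictionRecord]]:
    """Up to ``k`` highest-probability records per assigned category.

    Ties break by input order; categories without assigned records are
    absent from the mapping.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    buckets: dict[str, list[PredictionRecord]] = {}
    for rec in records:
        if rec.category is not None:
            buckets.setdefault(rec.category, []).append(rec)
    return {
        cat: sorted(recs, key=lambda r: -r.category_prob)[:k]
        for cat, recs in buckets.items()
    }
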
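"""Six sequence-derived feature encoders for protein classification.

Each encoder maps a :class:`~nifscan.sequences.ProteinSequence` of length N
to a fixed-dimension numeric vector:

========  ==========  =============================================
scheme    dimension   descriptor
========  ==========  =============================================
AAC       20          residue frequencies f_i / N
DPC       400         adjacent ordered-pair frequencies M_j / (N-1)
GPC       400         ordered-pair frequencies at gap G, / (N-G-1)
PseAAC    20 + λ      Chou type-1 pseudo amino-acid composition
CTD       310         composition (20) + transition (190) + distribution (100)
ACF       531·n       lagged property autocorrelations, lags 1..n
========  ==========  =============================================

Descriptor order is fixed by the canonical alphabet A,C,D,...,Y; pair
descriptors are row-major (AA, AC, ..., YY). CTD here is defined over the
20-letter alphabet itself rather than over physicochemical groups: the
transition block counts unordered heterogeneous adjacent pairs, and the
distribution block records, for each residue, the scaled position
(100·pos/N) of its 1st, 25%, 50%, 75% and 100% occurrence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .aaindex import AAIndexTable, default_table
from .alphabet import (
    ALPHABET,
    N_RESIDUES,
    UNORDERED_PAIR_INDEX,
    encode_indices,
    ordered_pairs,
    unordered_pairs,
)
from .sequences import ProteinSequence

__all__ = [
    "FeatureVector",
    "FeatureMatrix",
    "compute_aac",
    "compute_dpc",
    "compute_gpc",
    "compute_pseaac",
    "compute_ctd",
    "compute_acf",
    "encode_dataset",
    "scheme_dimension",
    "scheme_min_length",
    "SCHEMES",
]


@dataclass(frozen=True)
class FeatureVector:
    """A sequence encoded under one named scheme with its parameters."""

    scheme: str
    params: dict
    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.labels):
            raise ValueError("values/labels length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class FeatureMatrix:
    """Dense matrix of sequences (rows) by descriptors (columns)."""

    scheme: str
    params: dict
    ids: tuple[str, ...]
    labels: tuple[str, ...]
    X: np.ndarray

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.ids), len(self.labels)):
            raise ValueError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.ids)} ids x {len(self.labels)} labels"
            )

    @property
    def n_features(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:
        return len(self.ids)

    def take(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = np.asarray(indices, dtype=np.intp)
        return FeatureMatrix(
            scheme=self.scheme,
            params=self.params,
            ids=tuple(self.ids[i] for i in idx),
            labels=self.labels,
            X=self.X[idx],
        )

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.X, index=list(self.ids), columns=list(self.labels))
        df.index.name = "sequence_id"
        df.to_csv(path, sep="\t")


def concat_matrices(a: FeatureMatrix, b: FeatureMatrix) -> FeatureMatrix:
    """Row-wise concatenation of two matrices under the same scheme."""
    if a.scheme != b.scheme or a.params != b.params or a.labels != b.labels:
        raise ValueError("cannot concatenate matrices of different schemes")
    return FeatureMatrix(
        scheme=a.scheme,
        params=a.params,
        ids=a.ids + b.ids,
        labels=a.labels,
        X=np.vstack([a.X, b.X]),
    )


_AAC_LABELS = tuple(f"AAC({aa})" for aa in ALPHABET)
_DPC_LABELS = tuple(f"DPC({p})" for p in ordered_pairs())


def compute_aac(seq: ProteinSequence) -> FeatureVector:
    """Amino-acid composition: fraction of each residue; sums to 1."""
    idx = encode_indices(seq.residues)
    values = np.bincount(idx, minlength=N_RESIDUES) / seq.length
    return FeatureVector("aac", {}, values, _AAC_LABELS)


def compute_dpc(seq: ProteinSequence) -> FeatureVector:
    """Di-peptide composition: adjacent ordered-pair counts over N-1."""
    if seq.length < 2:
        raise ValueError("sequence too short for DPC (need length >= 2)")
    idx = encode_indices(seq.residues)
    pair_idx = idx[:-1] * N_RESIDUES + idx[1:]
    values = np.bincount(pair_idx, minlength=N_RESIDUES**2) / (seq.length - 1)
    return FeatureVector("dpc", {}, values, _DPC_LABELS)


def compute_gpc(seq: ProteinSequence, gap: int = 1) -> FeatureVector:
    """Gap-pair composition: ordered pairs (i, j) with ``gap`` intervening
    residues (offset gap+1), counts over N-gap-1."""
    if gap < 1:
        raise ValueError("gap must be >= 1")
    if seq.length < gap + 2:
        raise ValueError(f"sequence too short for GPC with gap {gap} (need length >= {gap + 2})")
    idx = encode_indices(seq.residues)
    off = gap + 1
    pair_idx = idx[:-off] * N_RESIDUES + idx[off:]
    values = np.bincount(pair_idx, minlength=N_RESIDUES**2) / (seq.length - gap - 1)
    labels = tuple(f"GPC{gap}({a}{'x' * gap}{b})" for a in ALPHABET for b in ALPHABET)
    return FeatureVector("gpc", {"gap": gap}, values, labels)


# Three classical residue scales backing the PseAAC sequence-order terms:
# hydrophobicity, hydrophilicity (Hopp-Woods), and side-chain mass, keyed by
# canonical alphabet order. Each is standardized (mean 0, population SD 1
# across the 20 residues) before the squared-difference coupling.
_PSEAAC_SCALES = {
    "hydrophobicity": {
        "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
        "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
        "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
        "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
    },
    "hydrophilicity": {
        "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5,
        "G": 0.0, "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8,
        "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2, "R": 3.0,
        "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
    },
    "side_chain_mass": {
        "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0,
        "G": 1.0, "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0,
        "M": 75.0, "N": 58.0, "P": 42.0, "Q": 72.0, "R": 101.0,
        "S": 31.0, "T": 45.0, "V": 43.0, "W": 130.0, "Y": 107.0,
    },
}


def _pseaac_theta_matrix() -> np.ndarray:
    """20x20 coupling Θ(i, j): mean squared difference of the three
    standardized residue scales."""
    mats = []
    for scale in _PSEAAC_SCALES.values():
        v = np.array([scale[aa] for aa in ALPHABET])
        v = (v - v.mean()) / v.std()
        mats.append((v[None, :] - v[:, None]) ** 2)
    return np.mean(mats, axis=0)


_THETA = _pseaac_theta_matrix()


def compute_pseaac(seq: ProteinSequence, lam: int = 1, weight: float = 0.05) -> FeatureVector:
    """Chou type-1 pseudo amino-acid composition, dimension 20 + λ.

    The first 20 components are residue frequencies and the last λ are
    sequence-order correlation factors τ_k (k = 1..λ), all jointly
    normalized so the vector sums to 1. As weight → 0 the first 20
    components converge to the plain AAC.
    """
    if lam < 1:
        raise ValueError("lam must be >= 1")
    if weight <= 0:
        raise ValueError("weight must be > 0")
    if seq.length <= lam:
        raise ValueError("lambda must be smaller than sequence length")
    idx = encode_indices(seq.residues)
    freqs = np.bincount(idx, minlength=N_RESIDUES) / seq.length
    taus = np.array([_THETA[idx[:-k], idx[k:]].mean() for k in range(1, lam + 1)])
    denom = 1.0 + weight * taus.sum()  # frequencies already sum to 1
    values = np.concatenate([freqs / denom, weight * taus / denom])
    labels = _AAC_LABELS + tuple(f"tau{k}" for k in range(1, lam + 1))
    labels = tuple(
        lab.replace("AAC", "PseAAC") if lab.startswith("AAC") else lab for lab in labels
    )
    return FeatureVector("pseaac", {"lam": lam, "weight": weight}, values, labels)


_CTD_QUANTILES = (0.25, 0.50, 0.75, 1.00)
_CTD_LABELS = (
    tuple(f"C({aa})" for aa in ALPHABET)
    + tuple(f"T({a}|{b})" for a, b in unordered_pairs())
    + tuple(
        f"D({aa},{tag})"
        for aa in ALPHABET
        for tag in ("first", "q25", "q50", "q75", "q100")
    )
)


def compute_ctd(seq: ProteinSequence) -> FeatureVector:
    """Composition-transition-distribution descriptor, dimension 310.

    Composition (20): residue fractions. Transition (190): for each
    unordered heterogeneous pair, adjacent abutments in either order over
    N-1. Distribution (100): for each residue present, scaled positions
    (100·pos/N, 1-based) of the 1st occurrence and of the ceil(q·n_i)-th
    occurrence for q in {0.25, 0.5, 0.75, 1.0}; absent residues get zeros.
    """
    if seq.length < 2:
        raise ValueError("sequence too short for CTD (need length >= 2)")
    idx = encode_indices(seq.residues)
    n = seq.length

    comp = np.bincount(idx, minlength=N_RESIDUES) / n

    a, b = idx[:-1], idx[1:]
    hetero = a != b
    pair_idx = UNORDERED_PAIR_INDEX[a[hetero], b[hetero]]
    trans = np.bincount(pair_idx, minlength=190) / (n - 1)

    dist = np.zeros(N_RESIDUES * 5)
    for i in range(N_RESIDUES):
        pos = np.nonzero(idx == i)[0] + 1  # 1-based
        n_i = pos.size
        if n_i == 0:
            continue
        anchors = [pos[0]] + [pos[math.ceil(q * n_i) - 1] for q in _CTD_QUANTILES]
        dist[5 * i : 5 * i + 5] = 100.0 * np.asarray(anchors) / n

    values = np.concatenate([comp, trans, dist])
    return FeatureVector("ctd", {}, values, _CTD_LABELS)


def compute_acf(
    seq: ProteinSequence, table: AAIndexTable | None = None, order: int = 1
) -> FeatureVector:
    """Autocorrelation descriptors over a property table, dimension P·order.

    For property p and lag k: r_k(p) = mean_t v_p(s_t)·v_p(s_{t+k}) with
    v_p the standardized property value. Ordered property-major, then lag.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if seq.length <= order:
        raise ValueError(f"sequence too short for ACF order {order} (need length > {order})")
    if table is None:
        table = default_table()
    idx = encode_indices(seq.residues)
    V = table.normalized[:, idx]  # (P, N)
    out = np.empty((table.n_properties, order))
    for k in range(1, order + 1):
        out[:, k - 1] = (V[:, :-k] * V[:, k:]).mean(axis=1)
    labels = tuple(
        f"ACF({pid},lag{k})"
        for pid in table.property_ids
        for k in range(1, order + 1)
    )
    return FeatureVector("acf", {"order": order}, out.ravel(), labels)


# scheme name -> (encoder callable, min sequence length as a function of params)
SCHEMES: dict[str, tuple[Callable[..., FeatureVector], Callable[[dict], int]]] = {
    "aac": (compute_aac, lambda p: 1),
    "dpc": (compute_dpc, lambda p: 2),
    "gpc": (compute_gpc, lambda p: p.get("gap", 1) + 2),
    "pseaac": (compute_pseaac, lambda p: p.get("lam", 1) + 1),
    "ctd": (compute_ctd, lambda p: 2),
    "acf": (compute_acf, lambda p: p.get("order", 1) + 1),
}


def scheme_min_length(scheme: str, params: dict | None = None) -> int:
    """Minimum sequence length a scheme accepts under the given parameters."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(SCHEMES)}")
    return SCHEMES[scheme][1](params or {})


def scheme_dimension(scheme: str, params: dict | None = None) -> int:
    """Feature-vector dimension of a scheme under the given parameters."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(SCHEMES)}")
    params = params or {}
    if scheme == "aac":
        return 20
    if scheme in ("dpc", "gpc"):
        return 400
    if scheme == "pseaac":
        return 20 + params.get("lam", 1)
    if scheme == "ctd":
        return 310
    # acf
    table = params.get("table") or default_table()
    return table.n_properties * params.get("order", 1)


def encode_dataset(
    seqs: Sequence[ProteinSequence], scheme: str, **params
) -> FeatureMatrix:
    """Encode a dataset under one scheme with deterministic column order.

    Every sequence must satisfy the scheme's length precondition and the
    standard alphabet; otherwise the whole call fails listing offending ids
    (no partial matrix is returned).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(SCHEMES)}")
    if len(seqs) == 0:
        raise ValueError("empty dataset")
    encoder, _ = SCHEMES[scheme]
    rows, labels, failures = [], None, []
    for seq in seqs:
        try:
            fv = encoder(seq, **params)
        except ValueError as exc:
            failures.append(f"{seq.id}: {exc}")
            continue
        rows.append(fv.values)
        labels = fv.labels
        stored_params = fv.params
    if failures:
        raise ValueError(
            f"{len(failures)} sequence(s) failed {scheme} encoding: "
            + "; ".join(failures[:10])
            + ("; ..." if len(failures) > 10 else "")
        )
    return FeatureMatrix(
        scheme=scheme,
        params={k: v for k, v in stored_params.items()},
        ids=tuple(s.id for s in seqs),
        labels=labels,
        X=np.vstack(rows),
    )
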
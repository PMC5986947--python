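"""Seeded synthetic protein datasets with controllable class signal.

These generators make every stage of the package testable offline. Class
signal is injected two ways: a *composition* shift (class-specific residue
frequencies, visible to AAC/CTD-composition features) and a first-order
*Markov transition bias* (class-specific adjacent-pair preferences, visible
to DPC/GPC/CTD-transition features). All generators are pure functions of
their arguments and seed, using numpy's pinned PCG64 generator, so output
is identical across runs and platforms.

They emulate class-conditional compositional signal only — not homology,
domain structure, or phylogenetic correlation among real nif sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import ALPHABET, N_RESIDUES, decode_indices
from .sequences import LabeledDataset, ProteinSequence, write_fasta

__all__ = [
    "CompositionProfile",
    "uniform_profile",
    "shifted_profile",
    "random_sequences",
    "two_class_dataset",
    "multiclass_dataset",
    "two_stage_dataset",
    "write_class_fasta",
    "SHIFT_SUBSET",
    "NIF_CLASS_LABELS",
]

# fixed residue subset receiving the composition shift in two_class_dataset
SHIFT_SUBSET = ("A", "C", "D", "E", "F")
# residue-pair enrichments per class in multiclass_dataset: disjoint pairs
# in canonical order, so up to 10 mutually distinguishable classes
_CLASS_PAIRS = tuple((2 * c, 2 * c + 1) for c in range(10))
# residues indices 12..19 are untouched by the first 6 class pairs and back
# the disjoint non-nif profile in two_stage_dataset
_NON_NIF_SUBSET = tuple(range(12, 20))

NIF_CLASS_LABELS = ("nifB", "nifD", "nifE", "nifH", "nifK", "nifN")

DEFAULT_LENGTH_RANGE = (150, 250)


@dataclass(frozen=True)
class CompositionProfile:
    """A residue probability distribution over the canonical alphabet."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (N_RESIDUES,):
            raise ValueError(f"profile needs {N_RESIDUES} probabilities")
        if (p < 0).any():
            raise ValueError("profile probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("profile probabilities must sum to 1")
        object.__setattr__(self, "probs", p)


def uniform_profile() -> CompositionProfile:
    return CompositionProfile(np.full(N_RESIDUES, 1.0 / N_RESIDUES))


def shifted_profile(
    delta: float, subset: tuple[str, ...] = SHIFT_SUBSET
) -> CompositionProfile:
    """Uniform profile with extra mass ``delta`` spread over ``subset``,
    renormalized. delta = 0 reproduces the uniform profile exactly."""
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must lie in [0, 1]")
    p = np.full(N_RESIDUES, 1.0 / N_RESIDUES)
    for aa in subset:
        p[ALPHABET.index(aa)] += delta / len(subset)
    return CompositionProfile(p / p.sum())


def _enriched_profile(indices, boost_each: float) -> CompositionProfile:
    p = np.full(N_RESIDUES, 1.0 / N_RESIDUES)
    for i in indices:
        p[i] += boost_each
    return CompositionProfile(p / p.sum())


def _draw_lengths(rng: np.random.Generator, n: int, length_range) -> np.ndarray:
    lo, hi = length_range
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid length range {length_range}")
    return rng.integers(lo, hi + 1, size=n)


def _iid_sequence(rng: np.random.Generator, length: int, probs: np.ndarray) -> str:
    return decode_indices(rng.choice(N_RESIDUES, size=length, p=probs))


def _markov_sequence(
    rng: np.random.Generator,
    length: int,
    probs: np.ndarray,
    from_idx: int,
    to_idx: int,
    bias: float,
) -> str:
    """First-order Markov draw: after residue ``from_idx``, probability mass
    ``bias`` is moved onto ``to_idx``; otherwise residues are i.i.d."""
    if bias <= 0:
        return _iid_sequence(rng, length, probs)
    boosted = (1.0 - bias) * probs
    boosted[to_idx] += bias
    cdf_base = np.cumsum(probs)
    cdf_boost = np.cumsum(boosted)
    u = rng.random(length)
    out = np.empty(length, dtype=np.intp)
    out[0] = np.searchsorted(cdf_base, u[0], side="right")
    for t in range(1, length):
        cdf = cdf_boost if out[t - 1] == from_idx else cdf_base
        out[t] = np.searchsorted(cdf, u[t], side="right")
    np.clip(out, 0, N_RESIDUES - 1, out=out)
    return decode_indices(out)


def _generate(
    rng: np.random.Generator,
    n: int,
    length_range,
    profile: CompositionProfile,
    prefix: str,
    markov: tuple[int, int, float] | None = None,
) -> list[ProteinSequence]:
    lengths = _draw_lengths(rng, n, length_range)
    seqs = []
    for i, L in enumerate(lengths):
        if markov is None:
            body = _iid_sequence(rng, int(L), profile.probs)
        else:
            body = _markov_sequence(rng, int(L), profile.probs, *markov)
        seqs.append(ProteinSequence(id=f"{prefix}_{i}", residues=body))
    return seqs


def random_sequences(
    n: int,
    length_range=DEFAULT_LENGTH_RANGE,
    profile: CompositionProfile | None = None,
    seed: int = 0,
    prefix: str = "syn",
) -> list[ProteinSequence]:
    """n i.i.d. sequences from a composition profile, lengths uniform on
    the inclusive range; fully determined by the seed."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    return _generate(rng, n, length_range, profile or uniform_profile(), prefix)


def two_class_dataset(
    n_per_class: int,
    delta: float,
    seed: int = 0,
    length_range=DEFAULT_LENGTH_RANGE,
    labels: tuple[str, str] = ("A", "B"),
) -> LabeledDataset:
    """Binary fixture: class A uniform, class B with mass ``delta`` shifted
    onto a fixed residue subset.

    delta = 0 gives two statistically identical classes (the null fixture
    for chance-level CV checks); delta >= 0.3 is linearly separable from
    composition features with high probability at these sizes.
    """
    rng = np.random.default_rng(seed)
    a = _generate(rng, n_per_class, length_range, uniform_profile(), f"{labels[0]}")
    b = _generate(rng, n_per_class, length_range, shifted_profile(delta), f"{labels[1]}")
    return LabeledDataset(
        sequences=tuple(a + b),
        labels=tuple([labels[0]] * n_per_class + [labels[1]] * n_per_class),
        label_set=tuple(labels),
    )


def multiclass_dataset(
    n_per_class: int,
    n_classes: int = 6,
    signal: float = 1.0,
    seed: int = 0,
    length_range=DEFAULT_LENGTH_RANGE,
    labels: tuple[str, ...] | None = None,
) -> LabeledDataset:
    """Multi-class fixture standing in for the six nif gene categories.

    Each class enriches a distinct residue pair (composition signal) and
    biases the transition from the first to the second residue of that pair
    (first-order Markov signal), both scaled by ``signal``. signal = 0
    makes all classes identically distributed.
    """
    if n_classes < 2 or n_classes > len(_CLASS_PAIRS):
        raise ValueError(f"n_classes must be in [2, {len(_CLASS_PAIRS)}]")
    if signal < 0:
        raise ValueError("signal must be >= 0")
    if labels is None:
        labels = NIF_CLASS_LABELS if n_classes == 6 else tuple(
            f"class{c}" for c in range(n_classes)
        )
    if len(labels) != n_classes:
        raise ValueError("label count must equal n_classes")
    rng = np.random.default_rng(seed)
    seqs: list[ProteinSequence] = []
    labs: list[str] = []
    for c, lab in enumerate(labels):
        pair = _CLASS_PAIRS[c]
        profile = _enriched_profile(pair, boost_each=signal * 0.15)
        bias = min(0.9, 0.8 * signal)
        seqs.extend(
            _generate(rng, n_per_class, length_range, profile, lab,
                      markov=(pair[0], pair[1], bias))
        )
        labs.extend([lab] * n_per_class)
    return LabeledDataset(sequences=tuple(seqs), labels=tuple(labs), label_set=labels)


def two_stage_dataset(
    n_per_class: int = 30,
    signal: float = 1.0,
    seed: int = 0,
    n_non_nif: int | None = None,
    length_range=DEFAULT_LENGTH_RANGE,
) -> tuple[LabeledDataset, list[ProteinSequence]]:
    """Six separable nif-like classes plus a disjoint non-nif background.

    The non-nif profile enriches residues untouched by the six class pairs,
    so the two stages are both learnable. Returns the labelled nif dataset
    and the non-nif sequence list (default size 6 * n_per_class, balancing
    the pooled positives).
    """
    nif = multiclass_dataset(
        n_per_class, n_classes=6, signal=signal, seed=seed, length_range=length_range
    )
    if n_non_nif is None:
        n_non_nif = 6 * n_per_class
    rng = np.random.default_rng(seed + 1_000_003)
    profile = _enriched_profile(_NON_NIF_SUBSET, boost_each=signal * 0.15 * 2 / 8)
    non_nif = _generate(rng, n_non_nif, length_range, profile, "nonnif")
    return nif, non_nif


def write_class_fasta(dataset: LabeledDataset, directory) -> dict[str, str]:
    """Write one FASTA per class label; returns label -> file path."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for lab, seqs in dataset.by_label().items():
        path = directory / f"{lab}.fasta"
        write_fasta(seqs, path)
        paths[lab] = str(path)
    return paths
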
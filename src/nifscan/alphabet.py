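"""Canonical 20-letter amino-acid alphabet and residue-index helpers.

The fixed order A,C,D,E,F,G,H,I,K,L,M,N,P,Q,R,S,T,V,W,Y defines descriptor
order for every feature encoder in this package.
"""

from __future__ import annotations

import numpy as np

ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"
N_RESIDUES: int = 20
AA_TO_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}

_LOOKUP = np.full(128, -1, dtype=np.int16)
for _aa, _i in AA_TO_INDEX.items():
    _LOOKUP[ord(_aa)] = _i

_ALPHABET_ARR = np.frombuffer(ALPHABET.encode("ascii"), dtype=np.uint8)


def encode_indices(residues: str) -> np.ndarray:
    """Map a residue string to integer indices in canonical order.

    Raises
    ------
    ValueError
        If any character falls outside the 20 standard amino acids.
    """
    try:
        arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    except UnicodeEncodeError as exc:
        raise ValueError(f"non-standard residues: non-ASCII character ({exc})") from exc
    idx = _LOOKUP[arr]
    if idx.size and (idx < 0).any():
        bad = sorted({residues[i] for i in np.nonzero(idx < 0)[0]})
        raise ValueError("non-standard residues: " + ", ".join(repr(b) for b in bad))
    return idx.astype(np.intp)


def decode_indices(indices: np.ndarray) -> str:
    """Inverse of :func:`encode_indices`."""
    return _ALPHABET_ARR[np.asarray(indices, dtype=np.intp)].tobytes().decode("ascii")


def is_standard(residues: str) -> bool:
    """True if every character is one of the 20 standard amino acids."""
    if not residues:
        return False
    try:
        encode_indices(residues)
    except ValueError:
        return False
    return True


def ordered_pairs() -> list[str]:
    """The 400 ordered residue pairs, row-major over the canonical alphabet."""
    return [a + b for a in ALPHABET for b in ALPHABET]


def unordered_pairs() -> list[tuple[str, str]]:
    """The 190 unordered heterogeneous residue pairs {i, j}, i < j canonically."""
    out = []
    for i in range(N_RESIDUES):
        for j in range(i + 1, N_RESIDUES):
            out.append((ALPHABET[i], ALPHABET[j]))
    return out


# 20x20 lookup: (min_idx, max_idx) -> 0..189, row-major over i<j; -1 on diagonal
UNORDERED_PAIR_INDEX = np.full((N_RESIDUES, N_RESIDUES), -1, dtype=np.intp)
_c = 0
for _i in range(N_RESIDUES):
    for _j in range(_i + 1, N_RESIDUES):
        UNORDERED_PAIR_INDEX[_i, _j] = _c
        UNORDERED_PAIR_INDEX[_j, _i] = _c
        _c += 1
del _c, _i, _j
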
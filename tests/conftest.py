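"""Shared fixtures: seeded synthetic datasets, pre-encoded once per session.

The SVM-backed tests all reuse these session-scoped feature matrices so the
suite stays fast; generation is fully deterministic (pinned PCG64 seeds).
"""

from __future__ import annotations

import numpy as np
import pytest

from nifscan import encode_dataset
from nifscan.synthetic import (
    multiclass_dataset,
    two_class_dataset,
    two_stage_dataset,
)


def random_protein(rng: np.random.Generator, length: int) -> str:
    """Uniform random residue string (test helper, not the package generator)."""
    from nifscan.alphabet import ALPHABET

    return "".join(rng.choice(list(ALPHABET), size=length))


@pytest.fixture(scope="session")
def separable_binary():
    """delta = 0.3 two-class dataset, CTD-encoded: separable by construction."""
    data = two_class_dataset(n_per_class=50, delta=0.3, seed=11)
    return encode_dataset(data.sequences, "ctd"), np.asarray(data.labels, dtype=object)

@pytest.fixture(scope="session")
def null_binary():
    """delta = 0 two-class dataset: the two classes are identically distributed."""
    data = two_class_dataset(n_per_class=50, delta=0.0, seed=12)
    return encode_dataset(data.sequences, "ctd"), np.asarray(data.labels, dtype=object)


@pytest.fixture(scope="session")
def six_class():
    """Six separable synthetic classes, 12 sequences each, CTD-encoded."""
    data = multiclass_dataset(n_per_class=12, n_classes=6, signal=1.0, seed=13)
    return encode_dataset(data.sequences, "ctd"), np.asarray(data.labels, dtype=object)


@pytest.fixture(scope="session")
def two_stage_fixture():
    """Training material for the two-stage flow: six nif-like classes plus a
    disjoint non-nif background, 30 sequences per class."""
    return two_stage_dataset(n_per_class=30, signal=1.0, seed=14)


@pytest.fixture(scope="session")
def two_stage_probes():
    """Held-out probes from the same distributions as two_stage_fixture."""
    return two_stage_dataset(n_per_class=10, signal=1.0, seed=1414)
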
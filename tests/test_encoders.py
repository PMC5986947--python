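"""Feature encoders: worked examples, brute-force oracles, invariants."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nifscan import (
    ProteinSequence,
    compute_aac,
    compute_acf,
    compute_ctd,
    compute_dpc,
    compute_gpc,
    compute_pseaac,
    encode_dataset,
    scheme_dimension,
    synthetic_aaindex_table,
)
from nifscan.alphabet import ALPHABET

protein_strings = st.text(alphabet=ALPHABET, min_size=10, max_size=120)


def _seq(residues, sid="s"):
    return ProteinSequence(id=sid, residues=residues)


# ---------------------------------------------------------------- oracles

def aac_oracle(residues):
    c = Counter(residues)
    return [c[aa] / len(residues) for aa in ALPHABET]


def dpc_oracle(residues):
    c = Counter(residues[i : i + 2] for i in range(len(residues) - 1))
    return [c[a + b] / (len(residues) - 1) for a in ALPHABET for b in ALPHABET]


def gpc_oracle(residues, gap):
    n = len(residues)
    c = Counter((residues[p], residues[p + gap + 1]) for p in range(n - gap - 1))
    return [c[(a, b)] / (n - gap - 1) for a in ALPHABET for b in ALPHABET]


def ctd_transition_oracle(residues):
    n = len(residues)
    c = Counter()
    for x, y in zip(residues, residues[1:]):
        if x != y:
            c[frozenset((x, y))] += 1
    out = []
    for i in range(20):
        for j in range(i + 1, 20):
            out.append(c[frozenset((ALPHABET[i], ALPHABET[j]))] / (n - 1))
    return out


# ------------------------------------------------------------ dimensions

@pytest.mark.parametrize(
    "func,kwargs,dim",
    [
        (compute_aac, {}, 20),
        (compute_dpc, {}, 400),
        (compute_gpc, {"gap": 1}, 400),
        (compute_gpc, {"gap": 2}, 400),
        (compute_pseaac, {"lam": 1}, 21),
        (compute_pseaac, {"lam": 5}, 25),
        (compute_ctd, {}, 310),
        (compute_acf, {"order": 1}, 531),
        (compute_acf, {"order": 2}, 1062),
    ],
)
def test_encoder_dimensions(func, kwargs, dim):
    rng = np.random.default_rng(0)
    s = _seq("".join(rng.choice(list(ALPHABET), size=80)))
    fv = func(s, **kwargs)
    assert len(fv) == dim
    assert np.all(np.isfinite(fv.values))


def test_scheme_dimension_helper_agrees():
    assert scheme_dimension("aac") == 20
    assert scheme_dimension("pseaac", {"lam": 3}) == 23
    assert scheme_dimension("acf", {"order": 2}) == 1062


# --------------------------------------------------------------- AAC/DPC/GPC

class TestCompositionEncoders:
    def test_homopolymer_aac(self):
        v = compute_aac(_seq("AAAA")).values
        assert v[0] == 1.0 and v[1:].sum() == 0.0

    def test_acdg_quarter_each(self):
        v = compute_aac(_seq("ACDG")).values
        expect = np.zeros(20)
        for aa in "ACDG":
            expect[ALPHABET.index(aa)] = 0.25
        np.testing.assert_array_equal(v, expect)

    def test_dpc_homopolymer_and_alternating(self):
        v = compute_dpc(_seq("AAA")).values
        assert v[0] == 1.0 and v.sum() == 1.0
        v = compute_dpc(_seq("ACAC")).values
        i_ac = ALPHABET.index("A") * 20 + ALPHABET.index("C")
        i_ca = ALPHABET.index("C") * 20 + ALPHABET.index("A")
        assert v[i_ac] == pytest.approx(2 / 3)
        assert v[i_ca] == pytest.approx(1 / 3)

    def test_dpc_requires_two_residues(self):
        with pytest.raises(ValueError, match="too short for DPC"):
            compute_dpc(_seq("A"))

    def test_gpc_worked_examples(self):
        v = compute_gpc(_seq("ACACA"), gap=1).values
        i_aa = 0
        i_cc = ALPHABET.index("C") * 20 + ALPHABET.index("C")
        assert v[i_aa] == pytest.approx(2 / 3)
        assert v[i_cc] == pytest.approx(1 / 3)
        assert v.sum() == pytest.approx(1.0)
        v = compute_gpc(_seq("AAAA"), gap=2).values
        assert v[0] == 1.0

    def test_gpc_length_guard(self):
        with pytest.raises(ValueError, match="gap 3"):
            compute_gpc(_seq("ACDE"), gap=3)

    @given(protein_strings)
    @settings(max_examples=60, deadline=None)
    def test_simplex_property(self, residues):
        """AAC/DPC/GPC values are non-negative and sum exactly to 1."""
        s = _seq(residues)
        for fv in (compute_aac(s), compute_dpc(s), compute_gpc(s, gap=1)):
            assert fv.values.min() >= 0
            assert fv.values.sum() == pytest.approx(1.0, abs=1e-12)


# --------------------------------------------------------------------- CTD

class TestCTD:
    def test_composition_block_equals_aac(self):
        rng = np.random.default_rng(1)
        s = _seq("".join(rng.choice(list(ALPHABET), size=90)))
        np.testing.assert_array_equal(compute_ctd(s).values[:20], compute_aac(s).values)

    def test_alternating_transitions(self):
        v = compute_ctd(_seq("ACACA")).values
        trans = v[20:210]
        assert trans[0] == 1.0  # {A,C} is the first unordered pair
        assert trans[1:].sum() == 0.0

    def test_homopolymer_distribution(self):
        v = compute_ctd(_seq("AAAAA")).values
        assert v[20:210].sum() == 0.0  # no heterogeneous adjacencies
        np.testing.assert_allclose(v[210:215], [20, 40, 60, 80, 100])
        assert v[215:].sum() == 0.0  # absent residues give zeros

    @given(protein_strings)
    @settings(max_examples=60, deadline=None)
    def test_distribution_block_properties(self, residues):
        """Distribution anchors lie in [0, 100] and are non-decreasing for
        every residue present; transition block mass is at most 1."""
        v = compute_ctd(_seq(residues)).values
        trans, dist = v[20:210], v[210:]
        assert 0.0 <= trans.sum() <= 1.0 + 1e-12
        for i in range(20):
            anchors = dist[5 * i : 5 * i + 5]
            assert anchors.min() >= 0.0 and anchors.max() <= 100.0
            if ALPHABET[i] in residues:
                assert np.all(np.diff(anchors) >= -1e-12)
            else:
                assert anchors.sum() == 0.0


# ------------------------------------------------------------------ PseAAC

class TestPseAAC:
    def test_homopolymer_has_zero_order_correlation(self):
        v = compute_pseaac(_seq("AAAAA"), lam=1).values
        assert v[0] == 1.0
        assert v[20] == 0.0

    @given(protein_strings, st.integers(min_value=1, max_value=5))
    @settings(max_examples=40, deadline=None)
    def test_components_sum_to_one(self, residues, lam):
        v = compute_pseaac(_seq(residues), lam=lam).values
        assert v.sum() == pytest.approx(1.0, abs=1e-12)
        assert v.min() >= 0.0

    def test_w_to_zero_converges_to_aac(self):
        rng = np.random.default_rng(2)
        s = _seq("".join(rng.choice(list(ALPHABET), size=150)))
        v = compute_pseaac(s, lam=3, weight=1e-9).values
        assert np.abs(v[:20] - compute_aac(s).values).max() <= 1e-6

    def test_lambda_must_be_below_length(self):
        with pytest.raises(ValueError, match="lambda"):
            compute_pseaac(_seq("ACD"), lam=3)


# --------------------------------------------------------------------- ACF

class TestACF:
    def test_homopolymer_is_squared_property(self):
        table = synthetic_aaindex_table(n_properties=40, seed=7)
        v = compute_acf(_seq("RRRRRR"), table=table, order=1).values
        r = ALPHABET.index("R")
        np.testing.assert_allclose(v, table.normalized[:, r] ** 2)

    def test_alternating_closed_form(self):
        table = synthetic_aaindex_table(n_properties=40, seed=7)
        v = compute_acf(_seq("ACACACAC"), table=table, order=1).values
        a, c = ALPHABET.index("A"), ALPHABET.index("C")
        np.testing.assert_allclose(v, table.normalized[:, a] * table.normalized[:, c])

    @given(protein_strings)
    @settings(max_examples=30, deadline=None)
    def test_reversal_symmetry(self, residues):
        """Lagged product sums are direction-symmetric."""
        table = synthetic_aaindex_table(n_properties=25, seed=9)
        fwd = compute_acf(_seq(residues), table=table, order=2).values
        rev = compute_acf(_seq(residues[::-1]), table=table, order=2).values
        np.testing.assert_allclose(fwd, rev, atol=1e-12)

    def test_length_guard(self):
        table = synthetic_aaindex_table(n_properties=5, seed=1)
        with pytest.raises(ValueError, match="order 3"):
            compute_acf(_seq("ACD"), table=table, order=3)


# ------------------------------------------------- permutation sensitivity

def test_permutation_leaves_aac_but_changes_order_features():
    s1 = _seq("AACCDDEEFFGGHHIIKKLL")
    s2 = _seq("ACDEFGHIKLACDEFGHIKL")  # same composition, different order
    np.testing.assert_array_equal(compute_aac(s1).values, compute_aac(s2).values)
    assert not np.array_equal(compute_dpc(s1).values, compute_dpc(s2).values)
    assert not np.array_equal(compute_gpc(s1, 1).values, compute_gpc(s2, 1).values)
    assert not np.array_equal(
        compute_ctd(s1).values[20:210], compute_ctd(s2).values[20:210]
    )
    table = synthetic_aaindex_table(n_properties=10, seed=3)
    assert not np.array_equal(
        compute_acf(s1, table=table).values, compute_acf(s2, table=table).values
    )


# -------------------------------------------------------- brute-force oracle

def test_counting_encoders_match_bruteforce_oracles():
    """Vectorized AAC/DPC/GPC/CTD-transition agree bit-for-bit with naive
    Counter-based implementations on random sequences of varied length."""
    rng = np.random.default_rng(42)
    for _ in range(300):
        n = int(rng.integers(10, 500))
        residues = "".join(rng.choice(list(ALPHABET), size=n))
        s = _seq(residues)
        np.testing.assert_array_equal(compute_aac(s).values, aac_oracle(residues))
        np.testing.assert_array_equal(compute_dpc(s).values, dpc_oracle(residues))
        for gap in (1, 2):
            np.testing.assert_array_equal(
                compute_gpc(s, gap).values, gpc_oracle(residues, gap)
            )
        np.testing.assert_array_equal(
            compute_ctd(s).values[20:210], ctd_transition_oracle(residues)
        )


# ----------------------------------------------------------- encode_dataset

class TestEncodeDataset:
    def test_shape_and_determinism(self):
        rng = np.random.default_rng(4)
        seqs = [
            _seq("".join(rng.choice(list(ALPHABET), size=60)), f"s{i}")
            for i in range(3)
        ]
        m1 = encode_dataset(seqs, "ctd")
        m2 = encode_dataset(seqs, "ctd")
        assert m1.X.shape == (3, 310)
        assert m1.ids == ("s0", "s1", "s2")
        np.testing.assert_array_equal(m1.X, m2.X)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty dataset"):
            encode_dataset([], "aac")

    def test_failing_sequences_named_no_partial_matrix(self):
        seqs = [_seq("ACDEFG", "ok"), _seq("A", "short")]
        with pytest.raises(ValueError, match="short"):
            encode_dataset(seqs, "dpc")

    def test_tsv_roundtrip(self, tmp_path):
        import pandas as pd

        seqs = [_seq("ACDEFGHIKL", "a"), _seq("MNPQRSTVWY", "b")]
        m = encode_dataset(seqs, "aac")
        p = tmp_path / "m.tsv"
        m.to_tsv(p)
        df = pd.read_csv(p, sep="\t", index_col=0)
        assert list(df.index) == ["a", "b"]
        np.testing.assert_allclose(df.to_numpy(), m.X)
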
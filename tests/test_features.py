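"""Segmentation, property means, molecular weight, and pair encoding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfinteract import (PropertyEntry, ProteinRecord, canonical_pair,
                        featurize_pair, featurize_tf, mean_property,
                        molecular_weight, split_segments, STANDARD_AA)
from tfinteract.errors import (DegenerateSequenceError, InvalidSequenceError,
                               UndefinedMeanError)
from tfinteract.features import (EXTENDED_AA, FeatureTriple, compose_feature,
                                 decompose_feature, pair_feature_matrix)
from tfinteract.synthetic import gen_property_table

sequences = st.text(alphabet=STANDARD_AA, min_size=5, max_size=120)
sequences_xu = st.text(alphabet=EXTENDED_AA, min_size=10, max_size=120)


def _prop(**values) -> PropertyEntry:
    full = {aa: 0.0 for aa in STANDARD_AA}
    full.update(values)
    return PropertyEntry("P1", "test scale", full)


@pytest.mark.parametrize("length, expected", [
    (100, (20, 60, 20)),
    (7, (1, 5, 1)),
    (5, (1, 3, 1)),
    (11, (2, 7, 2)),
])
def test_split_lengths_follow_floor_rule(length, expected):
    seg = split_segments("A" * length)
    assert tuple(map(len, seg)) == expected


def test_split_rejects_short_sequences():
    with pytest.raises(DegenerateSequenceError):
        split_segments("ACDE")


@given(seq=sequences)
@settings(max_examples=50, deadline=None)
def test_split_concatenation_restores_input(seq):
    seg = split_segments(seq)
    assert "".join(seg) == seq
    t = len(seq) // 5
    assert len(seg.n_segment) == len(seg.c_segment) == t


def test_mean_property_homopolymer_identity():
    p = _prop(A=0.7)
    assert mean_property("AAAA", p) == pytest.approx(0.7)


def test_mean_property_skips_x_and_u():
    p = _prop(A=1.0, C=4.0)
    assert mean_property("ACXA", p) == pytest.approx(2.0)
    assert mean_property("ACUA", p) == pytest.approx(2.0)


def test_mean_property_all_xu_is_undefined():
    with pytest.raises(UndefinedMeanError):
        mean_property("XXU", _prop())


def test_featurize_homopolymer_blocks_repeat_property_values(small_table):
    vec = featurize_tf(ProteinRecord("t", "A" * 10), small_table)
    per_a = np.array([e.values["A"] for e in small_table.entries])
    assert np.array_equal(vec, np.tile(per_a, 3))


@given(seq=sequences_xu)
@settings(max_examples=40, deadline=None)
def test_featurize_matches_per_position_oracle(small_table, seq):
    rec = ProteinRecord("t", seq)
    segs = split_segments(seq)
    try:
        expected = np.array([mean_property(s, p)
                             for s in segs for p in small_table.entries])
    except UndefinedMeanError:
        with pytest.raises(UndefinedMeanError):
            featurize_tf(rec, small_table)
        return
    assert np.allclose(featurize_tf(rec, small_table), expected,
                       rtol=1e-12, atol=1e-12)


@given(seq=sequences)
@settings(max_examples=30, deadline=None)
def test_vector_lengths_and_bounds_are_sequence_independent(small_table, seq):
    vec = featurize_tf(ProteinRecord("t", seq), small_table)
    P = small_table.size
    assert vec.shape == (3 * P,)
    V = small_table.value_matrix()
    lo, hi = np.tile(V.min(axis=1), 3), np.tile(V.max(axis=1), 3)
    assert np.all(vec >= lo - 1e-12) and np.all(vec <= hi + 1e-12)


def test_molecular_weight_reference_values():
    assert molecular_weight("G") == pytest.approx(75.07, abs=0.01)
    assert molecular_weight("GG") == pytest.approx(132.12, abs=0.01)


@given(seq=sequences, extra=st.sampled_from(STANDARD_AA + "U"))
@settings(max_examples=30, deadline=None)
def test_appending_a_residue_increases_weight(seq, extra):
    assert molecular_weight(seq + extra) > molecular_weight(seq)


def test_canonical_pair_puts_lighter_first():
    light = ProteinRecord("heavy-name", "GGGGG")
    heavy = ProteinRecord("a-light-name", "WWWWW")
    assert canonical_pair(heavy, light) == (light, heavy)
    assert canonical_pair(light, heavy) == (light, heavy)


def test_canonical_pair_breaks_exact_ties_by_id():
    a = ProteinRecord("A", "ACDEF")
    b = ProteinRecord("B", "ACDEF")
    assert canonical_pair(b, a) == (a, b)


def test_pair_of_homopolymers_orders_by_residue_mass(small_table):
    a = ProteinRecord("ala", "AAAAA")
    w = ProteinRecord("trp", "WWWWW")
    pv = featurize_pair(w, a, small_table)
    assert (pv.first_id, pv.second_id) == ("ala", "trp")
    per_a = np.array([e.values["A"] for e in small_table.entries])
    assert np.array_equal(pv.values[:3 * small_table.size], np.tile(per_a, 3))


@given(sa=sequences_xu, sb=sequences_xu)
@settings(max_examples=50, deadline=None)
def test_pair_encoding_is_symmetric_bitwise(small_table, sa, sb):
    a, b = ProteinRecord("a", sa), ProteinRecord("b", sb)
    try:
        ab = featurize_pair(a, b, small_table)
    except UndefinedMeanError:
        return
    ba = featurize_pair(b, a, small_table)
    assert (ab.first_id, ab.second_id) == (ba.first_id, ba.second_id)
    assert np.array_equal(ab.values, ba.values)
    assert ab.values.shape == (6 * small_table.size,)


def test_nonstandard_ambiguity_codes_rejected():
    with pytest.raises(InvalidSequenceError):
        ProteinRecord("bad", "ACDEB")


@pytest.mark.parametrize("index", [0, 7, 23, 47])
def test_feature_index_round_trip(index):
    t = decompose_feature(index, 8)
    assert compose_feature(t, 8) == index


def test_pair_feature_matrix_rows_and_columns(small_table):
    seqs = {"A": ProteinRecord("A", "ACDEFGHIKL"),
            "B": ProteinRecord("B", "MNPQRSTVWY"),
            "C": ProteinRecord("C", "AAAAACCCCC")}
    df = pair_feature_matrix([("A", "B"), ("C", "A")], seqs, small_table)
    assert df.shape == (2, 6 * small_table.size)
    direct = featurize_pair(seqs["A"], seqs["B"], small_table)
    assert np.array_equal(df.to_numpy()[0], direct.values)
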
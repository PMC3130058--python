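"""Evidence filtering, negative sampling, identity, redundancy filter."""

import itertools
import random

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from tfinteract import (InteractionRecord, InteractionSet, ProteinRecord,
                        filter_by_mi_type, generate_negative_set,
                        generate_negatives, redundancy_filter,
                        sequence_identity)
from tfinteract.dataset import local_alignment, validate_interaction_set
from tfinteract.errors import CapacityError, MissingSequenceError, \
    TFInteractError

# ---------------------------------------------------------------------------
# MI-type filter
# ---------------------------------------------------------------------------

def _pos(a, b, mi=None):
    return InteractionRecord(a, b, "positive", mi_type=mi)


def test_mi_filter_keeps_direct_interactions_and_drops_others():
    records = [_pos("A", "B", "MI:0407"), _pos("A", "C", "MI:0914"),
               _pos("B", "C", None), _pos("B", "D", "MI:0195"),
               _pos("C", "D", "MI:0915")]
    kept = filter_by_mi_type(records)
    assert [(r.first_id, r.second_id) for r in kept] == \
        [("A", "B"), ("B", "D"), ("C", "D")]
    assert filter_by_mi_type([]) == []


# ---------------------------------------------------------------------------
# Negative generation
# ---------------------------------------------------------------------------

UNIVERSE = ["T1", "T2", "T3", "T4", "T5", "T6"]
# T1-T2 and T1-T3 interact; T4..T6 have no partners
PARTNERS = {"T1": {"T2", "T3"}, "T2": {"T1"}, "T3": {"T1"},
            "T4": set(), "T5": set(), "T6": set()}
POSITIVES = {frozenset(("T1", "T2")), frozenset(("T1", "T3"))}


def _class_ok(rec, cls):
    a_int = bool(PARTNERS[rec.first_id])
    b_int = bool(PARTNERS[rec.second_id])
    if cls == "absolute":
        return not a_int and not b_int
    if cls == "partial":
        return a_int != b_int
    return (a_int and b_int
            and rec.second_id not in PARTNERS[rec.first_id])


@pytest.mark.parametrize("cls, capacity", [
    ("absolute", 3),   # C(3,2) among T4..T6
    ("partial", 9),    # 3 interacting x 3 non-interacting
    ("ppi", 1),        # T2-T3 is the only non-interacting pair
])
def test_generated_negatives_satisfy_class_constraints(cls, capacity):
    """Brute-force check against all 15 possible pairs of the universe."""
    for seed in range(5):
        recs = generate_negatives(UNIVERSE, PARTNERS, cls, capacity, seed,
                                  positives=POSITIVES)
        assert len(recs) == capacity
        assert len({r.key for r in recs}) == capacity
        for r in recs:
            assert r.key not in POSITIVES
            assert r.first_id != r.second_id
            assert _class_ok(r, cls), (r, cls)
    with pytest.raises(CapacityError) as err:
        generate_negatives(UNIVERSE, PARTNERS, cls, capacity + 1, 0,
                           positives=POSITIVES)
    assert err.value.capacity == capacity


def test_zero_negatives_is_legal():
    assert generate_negatives(UNIVERSE, PARTNERS, "ppi", 0, 0) == []


def test_negative_set_is_disjoint_and_reproducible():
    ids = [f"I{i}" for i in range(30)] + [f"N{i}" for i in range(30)]
    partners = {i: ({"EXT"} if i.startswith("I") else set()) for i in ids}
    for seed in range(5):
        negs = generate_negative_set(ids, partners, 25, seed)
        keys = [r.key for r in negs]
        assert len(negs) == 75 and len(set(keys)) == 75
        again = generate_negative_set(ids, partners, 25, seed)
        assert [(r.first_id, r.second_id, r.neg_class) for r in negs] == \
            [(r.first_id, r.second_id, r.neg_class) for r in again]


def test_validator_flags_misclassified_negative():
    bad = InteractionSet(
        [InteractionRecord("T4", "T5", "negative", neg_class="ppi")],
        universe=set(UNIVERSE))
    with pytest.raises(TFInteractError):
        validate_interaction_set(bad, PARTNERS)


# ---------------------------------------------------------------------------
# Sequence identity
# ---------------------------------------------------------------------------

def _gotoh_local_score(a, b, blosum, open_=11, extend=1):
    """Independent affine-gap Smith-Waterman, score only."""
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i][j] = max(M[i - 1][j] - open_, Ix[i - 1][j] - extend)
            Iy[i][j] = max(M[i][j - 1] - open_, Iy[i][j - 1] - extend)
            diag = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1], 0)
            M[i][j] = diag + blosum[a[i - 1], b[j - 1]]
            best = max(best, M[i][j])
    return best


@pytest.mark.parametrize("a, b", [
    ("ACDEFGHIKL", "ACDEFGHIKL"),
    ("ACDEFGHIKL", "ACDEFAHIKL"),
    ("MKTAYIAKQR", "KTAYIAK"),
    ("WWWWAAAA", "AAAAYYYY"),
    ("ACDKLMNP", "ACDAAAKLMNP"),
])
def test_alignment_score_matches_gotoh_oracle(a, b):
    blosum = substitution_matrices.load("BLOSUM62")
    score, _, _ = local_alignment(a, b)
    assert score == pytest.approx(_gotoh_local_score(a, b, blosum))


def test_identity_of_identical_sequences_is_one():
    assert sequence_identity("MKTAYIAKQRQISFVK", "MKTAYIAKQRQISFVK") == 1.0


def test_identity_is_symmetric_and_bounded():
    rng = random.Random(4)
    for _ in range(5):
        a = "".join(rng.choices("ACDEFGHIKLMNPQRSTVWY", k=30))
        b = "".join(rng.choices("ACDEFGHIKLMNPQRSTVWY", k=25))
        ab = sequence_identity(a, b)
        assert ab == sequence_identity(b, a)
        assert 0.0 <= ab <= 1.0


# ---------------------------------------------------------------------------
# Redundancy filter
# ---------------------------------------------------------------------------

SEQ = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQV"


def _three_tf_fixture():
    sequences = {
        "TFA": ProteinRecord("TFA", SEQ),
        "TFA2": ProteinRecord("TFA2", SEQ),  # identical to TFA
        "TFB": ProteinRecord("TFB", SEQ[::-1]),
    }
    records = [_pos("TFA", "TFB"), _pos("TFA2", "TFB")]
    return InteractionSet(records, universe=set(sequences)), sequences


def test_near_identical_pair_with_shared_partner_loses_one_interaction():
    iset, sequences = _three_tf_fixture()
    reduced, removed = redundancy_filter(iset, sequences, threshold=0.8)
    assert len(reduced.records) == 1
    assert len(removed) == 1
    r = removed[0]
    assert {r.kept_first, r.kept_second} == {"TFA", "TFB"}  # lexicographic keep
    assert {r.removed_first, r.removed_second} == {"TFA2", "TFB"}
    assert r.identity > 0.99 and r.common_partner == "TFB"


def test_similar_proteins_with_disjoint_partners_are_untouched():
    sequences = {
        "TFA": ProteinRecord("TFA", SEQ),
        "TFA2": ProteinRecord("TFA2", SEQ),
        "TFB": ProteinRecord("TFB", SEQ[::-1]),
        "TFC": ProteinRecord("TFC", SEQ[10:] + SEQ[:10]),
    }
    iset = InteractionSet([_pos("TFA", "TFB"), _pos("TFA2", "TFC")],
                          universe=set(sequences))
    reduced, removed = redundancy_filter(iset, sequences, threshold=0.8)
    assert len(reduced.records) == 2 and removed == []


def test_filter_is_idempotent_and_order_independent():
    iset, sequences = _three_tf_fixture()
    reduced, _ = redundancy_filter(iset, sequences)
    twice, removed2 = redundancy_filter(reduced, sequences)
    assert removed2 == [] and twice.records == reduced.records
    shuffled = InteractionSet(list(reversed(iset.records)),
                              universe=iset.universe)
    reduced_shuffled, _ = redundancy_filter(shuffled, sequences)
    assert {r.key for r in reduced_shuffled.records} == \
        {r.key for r in reduced.records}


def test_threshold_monotonicity():
    iset, sequences = _three_tf_fixture()
    untouched, _ = redundancy_filter(iset, sequences, threshold=1.0 + 1e-9)
    assert len(untouched.records) == len(iset.records)
    collapsed, removed = redundancy_filter(iset, sequences, threshold=0.0)
    assert len(collapsed.records) == 1 and len(removed) == 1


def test_missing_sequence_is_reported_by_id():
    iset, sequences = _three_tf_fixture()
    del sequences["TFA2"]
    with pytest.raises(MissingSequenceError, match="TFA2"):
        redundancy_filter(iset, sequences)


def test_duplicate_pairs_rejected_by_interaction_set():
    with pytest.raises(TFInteractError):
        InteractionSet([_pos("A", "B"), _pos("A", "B")])
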
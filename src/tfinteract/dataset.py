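"""Labelled interaction sets: evidence-type filtering, negative-pair
construction, and the high-identity / common-partner redundancy filter.

Positive pairs come from curated interaction tables and are kept only when
their PSI-MI evidence code denotes a physical association that can form a
complex (defaults MI:0195 covalent binding, MI:0407 direct interaction,
MI:0915 physical association).  Negatives are sampled in three classes of
increasing difficulty, depending on whether neither, one, or both members
are known to interact with some protein.  Because close homologs often
share binding partners, a redundancy filter drops all but one interaction
whenever two proteins with > 80% local-alignment identity share a partner
in the positive set, which would otherwise leak information across
cross-validation folds.

Sequence identity is computed with a built-in Smith-Waterman aligner using
BLAST-default scoring (BLOSUM62, gap open 11 / extend 1); identity is the
number of identical aligned positions divided by the alignment length,
gap columns included, which matches the identity BLAST reports.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import CapacityError, MissingSequenceError, TFInteractError
from .features import ProteinRecord, canonical_pair

#: PSI-MI evidence codes kept by default.
DEFAULT_MI_TYPES = frozenset({"MI:0195", "MI:0407", "MI:0915"})

NEGATIVE_CLASSES = ("absolute", "partial", "ppi")


@dataclass(frozen=True)
class InteractionRecord:
    """One labelled pair, canonically ordered.

    ``neg_class`` is one of absolute/partial/ppi for negatives and ``None``
    for positives.
    """

    first_id: str
    second_id: str
    label: str
    neg_class: str | None = None
    mi_type: str | None = None

    def __post_init__(self):
        if self.label not in ("positive", "negative"):
            raise ValueError(f"label must be positive/negative, got "
                             f"{self.label!r}")
        if (self.neg_class is None) != (self.label == "positive"):
            raise ValueError("neg_class must be set iff label is negative")
        if self.neg_class is not None and self.neg_class not in NEGATIVE_CLASSES:
            raise ValueError(f"unknown neg_class {self.neg_class!r}")

    @property
    def key(self) -> frozenset:
        return frozenset((self.first_id, self.second_id))


@dataclass
class InteractionSet:
    """Duplicate-free labelled pairs over a universe of sequenced proteins."""

    records: list[InteractionRecord]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self):
        if not self.universe:
            self.universe = {i for r in self.records
                             for i in (r.first_id, r.second_id)}
        validate_interaction_set(self)

    def positives(self) -> list[InteractionRecord]:
        return [r for r in self.records if r.label == "positive"]

    def negatives(self) -> list[InteractionRecord]:
        return [r for r in self.records if r.label == "negative"]

    def pair_keys(self) -> set[frozenset]:
        return {r.key for r in self.records}

    def __len__(self) -> int:
        return len(self.records)


def validate_interaction_set(iset: InteractionSet,
                             known_partners: Mapping[str, set] | None = None
                             ) -> None:
    """Check structural invariants (and, optionally, negative-class rules).

    Raises :class:`TFInteractError` on the first violation.  With
    ``known_partners`` supplied, every negative record is checked against
    its class definition and against the known positive pairs.
    """
    seen: set[frozenset] = set()
    pos_keys = {r.key for r in iset.records if r.label == "positive"}
    for r in iset.records:
        for i in (r.first_id, r.second_id):
            if i not in iset.universe:
                raise TFInteractError(f"id {i!r} not in the universe")
        if r.key in seen:
            raise TFInteractError(
                f"duplicate canonical pair {r.first_id}-{r.second_id}")
        seen.add(r.key)
    overlap = pos_keys & {r.key for r in iset.records if r.label == "negative"}
    if overlap:
        raise TFInteractError(f"{len(overlap)} pair(s) appear as both "
                              "positive and negative")
    if known_partners is None:
        return
    for r in iset.records:
        if r.label != "negative":
            continue
        a_int = bool(known_partners.get(r.first_id))
        b_int = bool(known_partners.get(r.second_id))
        if r.first_id == r.second_id:
            raise TFInteractError(f"negative self-pair {r.first_id}")
        if r.neg_class == "absolute" and (a_int or b_int):
            raise TFInteractError(
                f"absolute negative {r.first_id}-{r.second_id} has an "
                "interacting member")
        if r.neg_class == "partial" and (a_int == b_int):
            raise TFInteractError(
                f"partial negative {r.first_id}-{r.second_id} must have "
                "exactly one interacting member")
        if r.neg_class == "ppi":
            if not (a_int and b_int):
                raise TFInteractError(
                    f"ppi negative {r.first_id}-{r.second_id} must have two "
                    "interacting members")
            if (r.second_id in known_partners.get(r.first_id, set())
                    or r.first_id in known_partners.get(r.second_id, set())):
                raise TFInteractError(
                    f"ppi negative {r.first_id}-{r.second_id} is a known "
                    "interaction")


def filter_by_mi_type(records: Iterable[InteractionRecord],
                      allowed: frozenset | set = DEFAULT_MI_TYPES
                      ) -> list[InteractionRecord]:
    """Keep records whose evidence code is allowed; untyped records drop."""
    return [r for r in records if r.mi_type in allowed]


def _canonical_ids(id_a: str, id_b: str,
                   sequences: Mapping[str, ProteinRecord] | None
                   ) -> tuple[str, str]:
    if sequences is not None:
        try:
            a, b = sequences[id_a], sequences[id_b]
        except KeyError as exc:
            raise MissingSequenceError(
                f"no sequence for protein id {exc.args[0]!r}") from None
        first, second = canonical_pair(a, b)
        return first.id, second.id
    return (id_a, id_b) if id_a <= id_b else (id_b, id_a)


def generate_negatives(universe: Iterable[str],
                       known_partners: Mapping[str, set],
                       neg_class: str, n: int, seed: int, *,
                       positives: Iterable[frozenset] = (),
                       exclude: Iterable[frozenset] = (),
                       sequences: Mapping[str, ProteinRecord] | None = None
                       ) -> list[InteractionRecord]:
    """Sample ``n`` distinct negative pairs of one class.

    The universe splits into interacting ids (non-empty partner set) and
    non-interacting ids.  ``absolute`` pairs two non-interacting ids,
    ``partial`` one of each, and ``ppi`` two interacting ids that are not
    known partners of each other.  Self-pairs never occur; no sampled pair
    is in ``positives`` or ``exclude``.  Reproducible for a fixed seed; if
    fewer than ``n`` eligible pairs exist a :class:`CapacityError` reports
    the achievable maximum.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if neg_class not in NEGATIVE_CLASSES:
        raise ValueError(f"unknown negative class {neg_class!r}")
    ids = sorted(set(universe))
    interacting = [i for i in ids if known_partners.get(i)]
    noninteracting = [i for i in ids if not known_partners.get(i)]
    forbidden = set(positives) | set(exclude)

    if neg_class == "absolute":
        cands = itertools.combinations(noninteracting, 2)
    elif neg_class == "partial":
        cands = itertools.product(interacting, noninteracting)
    else:  # ppi
        cands = ((a, b) for a, b in itertools.combinations(interacting, 2)
                 if b not in known_partners.get(a, set())
                 and a not in known_partners.get(b, set()))
    eligible = [p for p in cands if frozenset(p) not in forbidden]
    if n > len(eligible):
        raise CapacityError(
            f"requested {n} {neg_class!r} negatives but only "
            f"{len(eligible)} eligible pairs exist", capacity=len(eligible))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=n, replace=False)
    out = []
    for idx in sorted(chosen.tolist()):
        a, b = eligible[idx]
        first, second = _canonical_ids(a, b, sequences)
        out.append(InteractionRecord(first, second, "negative",
                                     neg_class=neg_class))
    return out


def generate_negative_set(universe: Iterable[str],
                          known_partners: Mapping[str, set],
                          n_per_class: int, seed: int, *,
                          positives: Iterable[frozenset] = (),
                          sequences: Mapping[str, ProteinRecord] | None = None
                          ) -> list[InteractionRecord]:
    """All three classes, mutually disjoint, ``n_per_class`` pairs each."""
    out: list[InteractionRecord] = []
    taken: set[frozenset] = set()
    for offset, cls in enumerate(NEGATIVE_CLASSES):
        recs = generate_negatives(universe, known_partners, cls, n_per_class,
                                  seed + offset, positives=positives,
                                  exclude=taken, sequences=sequences)
        taken |= {r.key for r in recs}
        out.extend(recs)
    return out


# ---------------------------------------------------------------------------
# Sequence identity and the redundancy filter
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="local", open_gap_score=-11.0,
                                    extend_gap_score=-1.0)
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    return aligner


def local_alignment(seq_a: str, seq_b: str) -> tuple[float, int, int]:
    """Best local alignment: (score, identical positions, alignment length).

    BLOSUM62 with affine gaps (open 11, extend 1).  Selenocysteine is
    aligned as the unknown residue X, which BLOSUM62 covers.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    # Tied optimal alignments can differ by traversal order; aligning in a
    # canonical argument order keeps the reported identity symmetric.
    if seq_b < seq_a:
        seq_a, seq_b = seq_b, seq_a
    sa = seq_a.replace("U", "X")
    sb = seq_b.replace("U", "X")
    aln = _make_aligner().align(sa, sb)[0]
    c = aln.counts()
    length = c.identities + c.mismatches + c.gaps
    return float(aln.score), int(c.identities), int(length)


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical positions in the best local alignment."""
    _, identities, length = local_alignment(seq_a, seq_b)
    return identities / length if length else 0.0


@dataclass(frozen=True)
class RemovalRecord:
    """Audit entry for one redundancy-filter exclusion."""

    kept_first: str
    kept_second: str
    removed_first: str
    removed_second: str
    identity: float
    common_partner: str


def redundancy_filter(positives: InteractionSet,
                      sequences: Mapping[str, ProteinRecord],
                      threshold: float = 0.8
                      ) -> tuple[InteractionSet, list[RemovalRecord]]:
    """Collapse interactions of near-identical proteins with shared partners.

    For every protein pair (A, A') with local-alignment identity strictly
    above ``threshold`` and a common partner B among the positive
    interactions, exactly one of A-B / A'-B is retained — the one whose
    near-duplicate protein id is lexicographically smaller — so the result
    is deterministic and independent of record order.  Every exclusion is
    reported with its cause.
    """
    tf_ids = sorted({i for r in positives.records
                     for i in (r.first_id, r.second_id)})
    for i in tf_ids:
        if i not in sequences:
            raise MissingSequenceError(f"no sequence for protein id {i!r}")
    retained: dict[frozenset, InteractionRecord] = {
        r.key: r for r in positives.records}
    partners: dict[str, set[str]] = {i: set() for i in tf_ids}
    for r in positives.records:
        partners[r.first_id].add(r.second_id)
        partners[r.second_id].add(r.first_id)
    # Identity can only matter for protein pairs that share a partner, so
    # only those are aligned (removals never create new common partners).
    candidates: set[tuple[str, str]] = set()
    for b in tf_ids:
        for a, a2 in itertools.combinations(sorted(partners[b]), 2):
            candidates.add((a, a2) if a < a2 else (a2, a))
    identity: dict[tuple[str, str], float] = {
        (a, b): sequence_identity(sequences[a].sequence,
                                  sequences[b].sequence)
        for a, b in candidates}
    similar = sorted((a, b) for (a, b), ident in identity.items()
                     if ident > threshold)
    removed: list[RemovalRecord] = []
    for a, b in similar:  # a < b lexicographically: keep a's interaction
        for partner in sorted((partners[a] & partners[b]) - {a, b}):
            keep_key = frozenset((a, partner))
            drop_key = frozenset((b, partner))
            if keep_key in retained and drop_key in retained:
                dropped = retained.pop(drop_key)
                partners[b].discard(partner)
                partners[partner].discard(b)
                kept = retained[keep_key]
                removed.append(RemovalRecord(
                    kept_first=kept.first_id, kept_second=kept.second_id,
                    removed_first=dropped.first_id,
                    removed_second=dropped.second_id,
                    identity=identity[(a, b)], common_partner=partner))
    kept_records = [r for r in positives.records if r.key in retained]
    return (InteractionSet(kept_records, universe=set(positives.universe)),
            removed)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def read_pairs_tsv(path_or_buf,
                   sequences: Mapping[str, ProteinRecord] | None = None
                   ) -> list[InteractionRecord]:
    """Read a pair table (id_a, id_b, optional mi_type/label/neg_class).

    Rows without a label column default to positive.  Pairs are put in
    canonical order (by molecular weight when sequences are supplied,
    lexicographically otherwise).
    """
    df = pd.read_csv(path_or_buf, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "id_a" not in cols or "id_b" not in cols:
        raise TFInteractError("pair table must have id_a and id_b columns")
    records = []
    for _, row in df.iterrows():
        label = row[cols["label"]] if "label" in cols else "positive"
        if pd.isna(label):
            label = "positive"
        neg_class = None
        if "neg_class" in cols and not pd.isna(row[cols["neg_class"]]):
            neg_class = row[cols["neg_class"]]
        mi_type = None
        if "mi_type" in cols and not pd.isna(row[cols["mi_type"]]):
            mi_type = row[cols["mi_type"]]
        first, second = _canonical_ids(row[cols["id_a"]], row[cols["id_b"]],
                                       sequences)
        records.append(InteractionRecord(first, second, label,
                                         neg_class=neg_class,
                                         mi_type=mi_type))
    return records


def pairs_to_frame(records: Iterable[InteractionRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "id_a": r.first_id, "id_b": r.second_id, "mi_type": r.mi_type,
        "label": r.label, "neg_class": r.neg_class,
    } for r in records])


def write_pairs_tsv(records: Iterable[InteractionRecord], path) -> None:
    pairs_to_frame(records).to_csv(path, sep="\t", index=False)


def removals_to_frame(removed: Iterable[RemovalRecord]) -> pd.DataFrame:
    """Audit log; identity denominator is the local alignment length."""
    return pd.DataFrame([{
        "kept_pair": f"{r.kept_first}-{r.kept_second}",
        "removed_pair": f"{r.removed_first}-{r.removed_second}",
        "identity": round(r.identity, 4),
        "common_partner": r.common_partner,
        "identity_denominator": "local-alignment-length",
    } for r in removed])
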
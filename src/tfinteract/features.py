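"""Fixed-length physicochemical feature vectors for proteins and pairs.

A protein sequence is split into three sections — the first 20% of residues
(N-terminal), the middle 60%, and the last 20% (C-terminal) — and each
section is summarised by the mean of every property scale over its residues.
The unknown residue ``X`` and selenocysteine ``U`` are excluded from both
the numerator and the denominator of each mean.  With a table of P scales a
protein therefore maps to a vector of length 3P (segment-major layout: all
N-segment means in table order, then middle, then C), and an unordered pair
to a vector of length 6P obtained by concatenating the two members with the
lighter protein (by average molecular weight) first.  That canonical
ordering makes the pair encoding symmetric: featurizing (a, b) and (b, a)
yields bitwise-identical vectors.

Segment rounding: each terminal segment holds ``floor(0.2 * L)`` residues
and the middle takes the remainder, so both termini are equal-sized and the
split is deterministic.  Sequences shorter than 5 residues are rejected
because a terminal segment would be empty.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .aaindex import STANDARD_AA, PropertyEntry, PropertyTable
from .errors import (DegenerateSequenceError, InvalidSequenceError,
                     MissingSequenceError, UndefinedMeanError)

#: Residues accepted in input sequences: the 20 standard codes plus the
#: unknown residue X and selenocysteine U.  Other ambiguity codes (B, Z, J,
#: O) are rejected at parse time rather than silently skipped.
EXTENDED_AA = STANDARD_AA + "XU"

SEGMENT_NAMES = ("N", "M", "C")

#: Average (isotope-abundance weighted) residue masses in Daltons, plus the
#: mass of one water molecule added per chain.  X contributes zero mass.
WATER_MASS = 18.01528
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
    "U": 150.0388, "X": 0.0,
}

#: Tag recorded in model metadata so a fitted model can refuse to score
#: pairs ordered under a different weight convention.
MASS_CONVENTION = "average-residue-mass"

# Byte lookup: standard residue -> 0..19 (STANDARD_AA order), X/U -> -1,
# anything else -> -2 (invalid).
_CODE_LUT = np.full(128, -2, dtype=np.int8)
for _i, _a in enumerate(STANDARD_AA):
    _CODE_LUT[ord(_a)] = _i
_CODE_LUT[ord("X")] = -1
_CODE_LUT[ord("U")] = -1


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier and its upper-case amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise InvalidSequenceError("protein record has an empty id")
        if not self.sequence:
            raise InvalidSequenceError(f"empty sequence for {self.id!r}")
        bad = set(self.sequence) - set(EXTENDED_AA)
        if bad:
            raise InvalidSequenceError(
                f"sequence {self.id!r} contains characters outside "
                f"{EXTENDED_AA!r}: {sorted(bad)}")


@dataclass(frozen=True)
class SegmentTriple:
    """N-terminal / middle / C-terminal substrings of one sequence."""

    n_segment: str
    mid_segment: str
    c_segment: str

    def __iter__(self):
        return iter((self.n_segment, self.mid_segment, self.c_segment))


@dataclass(frozen=True)
class PairVector:
    """A 6P-long pair feature vector with its canonical member order."""

    values: np.ndarray
    first_id: str
    second_id: str


def split_segments(sequence: str) -> SegmentTriple:
    """Split a sequence into 20% / 60% / 20% sections.

    Each terminal segment holds ``t = floor(0.2 * L)`` residues; the middle
    gets the remaining ``L - 2t``.  Requires ``L >= 5`` so that ``t >= 1``.
    """
    L = len(sequence)
    t = L // 5
    if t < 1:
        raise DegenerateSequenceError(
            f"sequence of length {L} cannot be split 20/60/20 "
            "(terminal segment would be empty); minimum length is 5")
    return SegmentTriple(sequence[:t], sequence[t:L - t], sequence[L - t:])


def mean_property(segment: str, prop: PropertyEntry) -> float:
    """Mean of one property over a segment, skipping X and U residues."""
    if not prop.is_complete():
        raise ValueError(f"property {prop.accession} is incomplete")
    total = 0.0
    n = 0
    for aa in segment:
        if aa in ("X", "U"):
            continue
        try:
            total += prop.values[aa]
        except KeyError:
            raise InvalidSequenceError(
                f"residue {aa!r} outside the accepted alphabet") from None
        n += 1
    if n == 0:
        raise UndefinedMeanError(
            "segment contains no countable residues (all X/U)")
    return total / n


def _segment_composition(sequence: str) -> np.ndarray:
    """(3, 20) matrix of relative residue frequencies per segment."""
    codes = _CODE_LUT[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if (codes == -2).any():
        bad = sorted({sequence[i] for i in np.nonzero(codes == -2)[0]})
        raise InvalidSequenceError(
            f"sequence contains characters outside {EXTENDED_AA!r}: {bad}")
    L = len(sequence)
    t = L // 5
    comp = np.empty((3, 20))
    for row, seg in enumerate((codes[:t], codes[t:L - t], codes[L - t:])):
        valid = seg[seg >= 0]
        if valid.size == 0:
            raise UndefinedMeanError(
                f"{SEGMENT_NAMES[row]} segment contains no countable "
                "residues (all X/U)")
        comp[row] = np.bincount(valid, minlength=20) / valid.size
    return comp


def featurize_tf(record: ProteinRecord, table: PropertyTable) -> np.ndarray:
    """Feature vector of length 3P for one protein (segment-major layout)."""
    try:
        split_segments(record.sequence)
        comp = _segment_composition(record.sequence)
    except (DegenerateSequenceError, UndefinedMeanError,
            InvalidSequenceError) as exc:
        raise type(exc)(f"{record.id}: {exc}") from None
    # (3, 20) @ (20, P) -> per-segment property means, flattened N, M, C.
    return (comp @ table.value_matrix().T).ravel()


def molecular_weight(sequence: str) -> float:
    """Average molecular weight in Daltons (residue masses + one water)."""
    if not sequence:
        raise InvalidSequenceError("cannot weigh an empty sequence")
    try:
        return sum(AVERAGE_RESIDUE_MASS[aa] for aa in sequence) + WATER_MASS
    except KeyError as exc:
        raise InvalidSequenceError(
            f"residue {exc.args[0]!r} outside the accepted alphabet") from None


def canonical_pair(a: ProteinRecord, b: ProteinRecord
                   ) -> tuple[ProteinRecord, ProteinRecord]:
    """Order a pair with the lighter member first (ties: smaller id)."""
    ka = (molecular_weight(a.sequence), a.id)
    kb = (molecular_weight(b.sequence), b.id)
    return (a, b) if ka <= kb else (b, a)


def canonical_ids(id_a: str, id_b: str,
                  sequences: Mapping[str, ProteinRecord]) -> tuple[str, str]:
    """Canonical (first, second) ids for a pair given a sequence map."""
    try:
        a, b = sequences[id_a], sequences[id_b]
    except KeyError as exc:
        raise MissingSequenceError(
            f"no sequence for protein id {exc.args[0]!r}") from None
    first, second = canonical_pair(a, b)
    return first.id, second.id


def featurize_pair(a: ProteinRecord, b: ProteinRecord,
                   table: PropertyTable) -> PairVector:
    """6P-long pair vector: concatenated member vectors, lighter first."""
    first, second = canonical_pair(a, b)
    values = np.concatenate([featurize_tf(first, table),
                             featurize_tf(second, table)])
    return PairVector(values=values, first_id=first.id, second_id=second.id)


# ---------------------------------------------------------------------------
# Feature annotation: flat index <-> (member, segment, property) triples
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureTriple:
    """Annotation of one pair-vector column.

    ``member`` is 1 or 2 (canonical order), ``segment`` one of N/M/C, and
    ``property_index`` the 0-based position of the scale in the table.
    """

    member: int
    segment: str
    property_index: int

    def name(self, accession: str | None = None) -> str:
        prop = accession if accession is not None else str(self.property_index)
        return f"m{self.member}.{self.segment}.{prop}"


def decompose_feature(index: int, n_properties: int) -> FeatureTriple:
    """Map a flat 0-based pair-vector column index to its triple."""
    if not 0 <= index < 6 * n_properties:
        raise IndexError(f"feature index {index} out of range for "
                         f"P={n_properties}")
    member, rest = divmod(index, 3 * n_properties)
    segment, prop = divmod(rest, n_properties)
    return FeatureTriple(member + 1, SEGMENT_NAMES[segment], prop)


def compose_feature(triple: FeatureTriple, n_properties: int) -> int:
    """Inverse of :func:`decompose_feature`."""
    seg = SEGMENT_NAMES.index(triple.segment)
    return ((triple.member - 1) * 3 + seg) * n_properties + triple.property_index


def feature_annotations(table: PropertyTable) -> list[dict]:
    """Sidecar annotation for all 6P pair-vector columns."""
    P = table.size
    out = []
    for idx in range(6 * P):
        t = decompose_feature(idx, P)
        out.append({"index": idx, "member": t.member, "segment": t.segment,
                    "property_index": t.property_index,
                    "accession": table.accessions[t.property_index]})
    return out


# ---------------------------------------------------------------------------
# FASTA and feature-matrix I/O
# ---------------------------------------------------------------------------

def read_fasta(path_or_handle) -> dict[str, ProteinRecord]:
    """Read a FASTA file into id -> :class:`ProteinRecord` (ids must be unique)."""
    records: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(path_or_handle, "fasta"):
        if rec.id in records:
            raise InvalidSequenceError(f"duplicate FASTA id {rec.id!r}")
        records[rec.id] = ProteinRecord(rec.id, str(rec.seq).upper())
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i:i + 60] + "\n")


def pair_feature_matrix(pairs: Sequence[tuple[str, str]],
                        sequences: Mapping[str, ProteinRecord],
                        table: PropertyTable) -> pd.DataFrame:
    """Feature matrix for many pairs; rows ``first::second``, 6P columns.

    Member vectors are computed once per protein and reused, so the cost is
    linear in the number of distinct proteins plus the number of pairs.
    """
    cache: dict[str, np.ndarray] = {}

    def vec(pid: str) -> np.ndarray:
        if pid not in cache:
            if pid not in sequences:
                raise MissingSequenceError(f"no sequence for protein id {pid!r}")
            cache[pid] = featurize_tf(sequences[pid], table)
        return cache[pid]

    rows = np.empty((len(pairs), 6 * table.size))
    index = []
    for i, (id_a, id_b) in enumerate(pairs):
        first, second = canonical_ids(id_a, id_b, sequences)
        rows[i, :3 * table.size] = vec(first)
        rows[i, 3 * table.size:] = vec(second)
        index.append(f"{first}::{second}")
    columns = [FeatureTriple(a["member"], a["segment"], a["property_index"])
               .name(a["accession"]) for a in feature_annotations(table)]
    return pd.DataFrame(rows, index=pd.Index(index, name="pair"),
                        columns=columns)


def write_feature_matrix(df: pd.DataFrame, table: PropertyTable,
                         matrix_path, annotation_path) -> None:
    """Write the pair feature TSV plus its sidecar annotation JSON."""
    df.to_csv(matrix_path, sep="\t")
    with open(annotation_path, "w") as fh:
        json.dump({"n_properties": table.size,
                   "mass_convention": MASS_CONVENTION,
                   "features": feature_annotations(table)}, fh, indent=1)
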
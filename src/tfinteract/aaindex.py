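"""Reading and writing AAIndex1 amino-acid property scales.

AAIndex1 is the flat-file dialect of the AAIndex database: ``//``-delimited
records, each carrying an accession (``H`` line), a free-text description
(``D`` line) and an ``I`` block with the 20 per-residue values laid out in
two rows of ten under a header such as ``A/L  R/K  N/M ...``.  Missing
values are printed as ``NA``.

Only the ``H``, ``D`` and ``I`` fields are interpreted here; the literature
reference and correlation fields (``R``/``A``/``T``/``J``/``C``) are skipped
verbatim.  The residue column order is read from the ``I`` header itself
rather than assumed, which guards against dialect drift.  Values are kept at
full printed precision; no normalisation is applied anywhere downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import numpy as np
import pandas as pd

from .errors import AAIndexParseError

#: The 20 standard residues, alphabetical by one-letter code.  This is the
#: column order of :meth:`PropertyTable.value_matrix` and of TSV exports.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Canonical AAIndex1 I-block header: row 1 holds the residue before the
#: slash, row 2 the residue after it.
_I_HEADER_PAIRS = ("A/L", "R/K", "N/M", "D/F", "C/P",
                   "Q/S", "E/T", "G/W", "H/Y", "I/V")


@dataclass
class PropertyEntry:
    """One amino-acid scale: accession, description and per-residue values.

    ``values`` maps one-letter residue codes to reals; residues whose value
    was printed as ``NA`` are simply absent from the map.
    """

    accession: str
    description: str
    values: dict[str, float] = field(default_factory=dict)

    def is_complete(self) -> bool:
        """True when all 20 standard residues have a value."""
        return len(self.values) == 20

    def __post_init__(self):
        if not self.accession:
            raise ValueError("PropertyEntry accession must be non-empty")
        bad = set(self.values) - set(STANDARD_AA)
        if bad:
            raise ValueError(
                f"non-standard residues in property {self.accession}: {sorted(bad)}")


@dataclass
class PropertyTable:
    """Ordered collection of complete amino-acid scales.

    Order is the file order of the source and is stable across parses; the
    table size ``P`` determines every downstream feature-vector length
    (``3P`` per protein, ``6P`` per pair).
    """

    entries: list[PropertyEntry]

    def __post_init__(self):
        for e in self.entries:
            if not e.is_complete():
                raise ValueError(
                    f"PropertyTable requires complete scales; {e.accession} "
                    f"has {len(e.values)} values")

    @property
    def size(self) -> int:
        return len(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def accessions(self) -> list[str]:
        return [e.accession for e in self.entries]

    def value_matrix(self) -> np.ndarray:
        """(P, 20) array of values, columns in :data:`STANDARD_AA` order."""
        return np.array([[e.values[a] for a in STANDARD_AA]
                         for e in self.entries], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.value_matrix(), columns=list(STANDARD_AA))
        df.insert(0, "accession", self.accessions)
        return df

    def to_tsv(self, path_or_buf) -> None:
        """Tabular export (accession + 20 residue columns) for inspection."""
        self.to_dataframe().to_csv(path_or_buf, sep="\t", index=False)


def parse_aaindex1(stream: str | TextIO) -> list[PropertyEntry]:
    """Parse AAIndex1 flat-file text into a list of :class:`PropertyEntry`.

    ``NA`` fields become missing entries; numeric fields are parsed as
    floats at full precision.  Raises :class:`AAIndexParseError` on a
    malformed ``I`` block, naming the offending accession and line.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    entries: list[PropertyEntry] = []
    seen: set[str] = set()

    accession: str | None = None
    description_parts: list[str] = []
    residue_order: list[str] | None = None
    value_rows: list[list[str]] = []
    in_i_block = False
    i_line_no = 0
    saw_field = False

    def finalize(line_no: int):
        nonlocal accession, description_parts, residue_order, value_rows
        nonlocal in_i_block, saw_field
        if not saw_field:
            return
        if accession is None:
            raise AAIndexParseError("record without H (accession) line",
                                    line=line_no)
        if accession in seen:
            raise AAIndexParseError("duplicate accession",
                                    accession=accession, line=line_no)
        if residue_order is None:
            raise AAIndexParseError("record without I block",
                                    accession=accession, line=line_no)
        if len(value_rows) != 2:
            raise AAIndexParseError(
                f"I block has {len(value_rows)} value rows, expected 2",
                accession=accession, line=i_line_no)
        values: dict[str, float] = {}
        for row_idx, row in enumerate(value_rows):
            if len(row) != 10:
                raise AAIndexParseError(
                    f"I block row has {len(row)} fields, expected 10",
                    accession=accession, line=i_line_no + 1 + row_idx)
            for col, token in enumerate(row):
                residue = residue_order[row_idx * 10 + col]
                if token.upper() == "NA":
                    continue
                try:
                    values[residue] = float(token)
                except ValueError:
                    raise AAIndexParseError(
                        f"non-numeric token {token!r} in I block",
                        accession=accession,
                        line=i_line_no + 1 + row_idx) from None
        entries.append(PropertyEntry(accession=accession,
                                     description=" ".join(description_parts),
                                     values=values))
        seen.add(accession)
        accession = None
        description_parts = []
        residue_order = None
        value_rows = []
        in_i_block = False
        saw_field = False

    current_field = ""
    line_no = 0
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("//"):
            finalize(line_no)
            current_field = ""
            continue
        head = line[0]
        if head != " ":
            current_field = head
            in_i_block = False
        body = line[1:].strip() if head != " " else line.strip()
        saw_field = True
        if current_field == "H" and head == "H":
            accession = body.split()[0] if body else ""
            if not accession:
                raise AAIndexParseError("empty H line", line=line_no)
        elif current_field == "D":
            if body:
                description_parts.append(body)
        elif current_field == "I":
            if head == "I":
                pairs = body.split()
                order: list[str] = [""] * (2 * len(pairs))
                for idx, pair in enumerate(pairs):
                    if "/" not in pair:
                        raise AAIndexParseError(
                            f"malformed I header token {pair!r}",
                            accession=accession, line=line_no)
                    first, second = pair.split("/", 1)
                    order[idx] = first
                    order[len(pairs) + idx] = second
                if len(pairs) != 10 or set(order) != set(STANDARD_AA):
                    raise AAIndexParseError(
                        "I header does not enumerate the 20 standard residues",
                        accession=accession, line=line_no)
                residue_order = order
                in_i_block = True
                i_line_no = line_no
                value_rows = []
            elif in_i_block:
                value_rows.append(body.split())
        # R/A/T/J/C correlation and reference fields: skipped verbatim.
    finalize(line_no if saw_field else 0)
    return entries


def filter_complete(entries: Iterable[PropertyEntry]) -> PropertyTable:
    """Retain only scales defined for all 20 residues, preserving order.

    Idempotent; an empty result is legal.
    """
    return PropertyTable([e for e in entries if e.is_complete()])


def write_aaindex1(entries: Iterable[PropertyEntry] | PropertyTable) -> str:
    """Serialize entries back to the AAIndex1 dialect.

    Numbers are printed with ``repr`` so that a write/parse round trip
    reproduces values bit-for-bit; missing values are printed as ``NA``.
    """
    if isinstance(entries, PropertyTable):
        entries = entries.entries
    chunks: list[str] = []
    order = [p.split("/")[0] for p in _I_HEADER_PAIRS] + \
            [p.split("/")[1] for p in _I_HEADER_PAIRS]
    for e in entries:
        lines = [f"H {e.accession}", f"D {e.description}"]
        lines.append("I    " + "     ".join(_I_HEADER_PAIRS))
        for row in (order[:10], order[10:]):
            toks = [repr(e.values[a]) if a in e.values else "NA" for a in row]
            lines.append("    " + "  ".join(toks))
        lines.append("//")
        chunks.append("\n".join(lines))
    return "\n".join(chunks) + ("\n" if chunks else "")
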
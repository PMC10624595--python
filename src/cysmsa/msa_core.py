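"""Sequence and alignment data model with FASTA / aligned-FASTA / a3m I/O.

The two alignment dialects:

* ``ALIGNED_FASTA`` — every row has the same length; characters are the
  residue alphabet plus ``'-'``.
* ``A3M`` — uppercase letters and ``'-'`` are match states, lowercase
  letters are insertions relative to the query; all rows share the same
  match-state count.  An optional first line starting with ``'#'`` carries
  the complex-pairing header (``#L1,L2<TAB>1,1``).

Alignment operations never mutate residues: removing gaps and uppercasing
any row reproduces the underlying sequence.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, TextIO

from .errors import ParseError, ValidationError

#: The 20 standard amino-acid one-letter codes plus 'X' (unknown).
AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_ALPHABET = frozenset(AA20 + "X")

#: Characters additionally tolerated in-memory: the cysteine-barcode
#: placeholder alphabet (see :mod:`cysmsa.cys_anchor`).  File parsers are
#: strict (:data:`AA_ALPHABET` only); barcoded sequences exist only as
#: intermediate objects.
EXTENDED_ALPHABET = frozenset(AA20 + "X" + "BJOUZ0123456789")


class Dialect(str, Enum):
    ALIGNED_FASTA = "aligned_fasta"
    A3M = "a3m"


@dataclass(frozen=True)
class Sequence:
    """An ungapped, uppercase protein sequence.

    ``id`` must be non-empty and contain no whitespace; ``residues`` must be
    non-empty and drawn from :data:`EXTENDED_ALPHABET` (parsers enforce the
    stricter :data:`AA_ALPHABET`).
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValidationError(f"invalid sequence id: {self.id!r}")
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r} is empty")
        for pos, c in enumerate(self.residues, start=1):
            if c not in EXTENDED_ALPHABET:
                raise ValidationError(
                    f"sequence {self.id!r}: illegal residue {c!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


def ungap(row: str) -> str:
    """Remove gaps and uppercase an alignment row (recovers the residues)."""
    return row.replace("-", "").replace(".", "").upper()


def match_states(row: str) -> str:
    """Match-state string of an a3m row: uppercase letters and gaps only."""
    return "".join(c for c in row if c == "-" or c.isupper() or c.isdigit())


@dataclass(frozen=True)
class PairingHeader:
    """The '#' header of a complex a3m: per-component query lengths and
    per-component copy numbers (cardinalities)."""

    lengths: tuple[int, ...]
    cardinalities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.lengths) != len(self.cardinalities) or not self.lengths:
            raise ValidationError("pairing header: lengths and cardinalities must "
                                  "have equal, non-zero count")
        if any(x < 1 for x in self.lengths) or any(x < 1 for x in self.cardinalities):
            raise ValidationError("pairing header: entries must be positive")

    def to_line(self) -> str:
        return ("#" + ",".join(map(str, self.lengths))
                + "\t" + ",".join(map(str, self.cardinalities)))

    @classmethod
    def from_line(cls, line: str) -> "PairingHeader":
        body = line[1:].rstrip("\n")
        parts = body.split("\t")
        if len(parts) != 2:
            raise ParseError(f"malformed pairing header: {line!r}")
        try:
            lengths = tuple(int(x) for x in parts[0].split(","))
            cards = tuple(int(x) for x in parts[1].split(","))
        except ValueError as exc:
            raise ParseError(f"malformed pairing header: {line!r}") from exc
        return cls(lengths, cards)


@dataclass(frozen=True)
class Msa:
    """An ordered multiple sequence alignment in one of two dialects."""

    rows: tuple[tuple[str, str], ...]
    dialect: Dialect = Dialect.ALIGNED_FASTA

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValidationError("empty MSA")
        object.__setattr__(self, "rows", tuple((i, r) for i, r in self.rows))
        seen: set[str] = set()
        for rid, row in self.rows:
            if not rid or any(c.isspace() for c in rid):
                raise ValidationError(f"invalid row id: {rid!r}")
            if rid in seen:
                raise ValidationError(f"duplicate row id: {rid!r}")
            seen.add(rid)
            if not row:
                raise ValidationError(f"row {rid!r} is empty")
        if self.dialect is Dialect.ALIGNED_FASTA:
            width = len(self.rows[0][1])
            for rid, row in self.rows:
                if len(row) != width:
                    raise ValidationError(
                        f"aligned row {rid!r} has length {len(row)}, expected {width}")
                for c in row:
                    if c != "-" and c not in EXTENDED_ALPHABET:
                        raise ValidationError(
                            f"aligned row {rid!r}: illegal character {c!r}")
        else:
            n_match = len(match_states(self.rows[0][1]))
            for rid, row in self.rows:
                for c in row:
                    if c != "-" and c.upper() not in EXTENDED_ALPHABET:
                        raise ValidationError(f"a3m row {rid!r}: illegal character {c!r}")
                if len(match_states(row)) != n_match:
                    raise ValidationError(
                        f"a3m row {rid!r} has {len(match_states(row))} match states, "
                        f"expected {n_match}")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.rows)

    def row(self, rid: str) -> str:
        for i, r in self.rows:
            if i == rid:
                return r
        raise ValidationError(f"unknown row id: {rid!r}")

    @property
    def n_match_states(self) -> int:
        if self.dialect is Dialect.A3M:
            return len(match_states(self.rows[0][1]))
        return len(self.rows[0][1])

    def __len__(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------
# FASTA


def _as_text(source: str | TextIO) -> str:
    if hasattr(source, "read"):
        return source.read()
    return source


def _iter_fasta_records(text: str) -> Iterable[tuple[str, str, str]]:
    """Yield (id, description, concatenated-body) triples."""
    header: str | None = None
    body: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if header is not None:
                yield _split_header(header) + ("".join(body),)
            header = line[1:].strip()
            body = []
        elif line.strip():
            if header is None:
                raise ParseError("sequence data before the first '>' header")
            body.append(line.strip())
    if header is not None:
        yield _split_header(header) + ("".join(body),)


def _split_header(header: str) -> tuple[str, str]:
    if not header:
        raise ParseError("empty FASTA header")
    parts = header.split(None, 1)
    return parts[0], (parts[1] if len(parts) > 1 else "")


def read_fasta(source: str | TextIO) -> list[Sequence]:
    """Parse FASTA into :class:`Sequence` objects.

    Ids are the first whitespace-delimited header token; duplicate ids and
    residues outside the strict amino-acid alphabet are rejected with the
    offending id and position.
    """
    seqs: list[Sequence] = []
    seen: set[str] = set()
    for rid, desc, body in _iter_fasta_records(_as_text(source)):
        if rid in seen:
            raise ParseError(f"duplicate sequence id: {rid!r}")
        seen.add(rid)
        if not body:
            raise ParseError(f"empty record: {rid!r}")
        up = body.upper()
        for pos, c in enumerate(up, start=1):
            if c not in AA_ALPHABET:
                raise ParseError(
                    f"sequence {rid!r}: illegal residue {c!r} at position {pos}")
        seqs.append(Sequence(id=rid, residues=up, description=desc))
    if not seqs:
        raise ParseError("no FASTA records found")
    return seqs


def write_fasta(seqs: Iterable[Sequence]) -> str:
    """Serialize sequences as single-line FASTA (bit-exact diff friendly)."""
    out = io.StringIO()
    for s in seqs:
        head = s.id if not s.description else f"{s.id} {s.description}"
        out.write(f">{head}\n{s.residues}\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# a3m


def read_a3m(source: str | TextIO) -> tuple[Msa, PairingHeader | None]:
    """Parse a3m text, returning the alignment and the optional pairing header.

    With a header present the shared match-state count must equal the sum of
    the header lengths.  '.' characters (insert-state gaps emitted by some
    tools) are discarded on read.
    """
    text = _as_text(source)
    header: PairingHeader | None = None
    lines = text.splitlines()
    start = 0
    for i, line in enumerate(lines):
        if not line.strip():
            continue
        if line.startswith("#"):
            header = PairingHeader.from_line(line)
            start = i + 1
        break
    rows: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rid, _desc, body in _iter_fasta_records("\n".join(lines[start:])):
        if rid in seen:
            raise ParseError(f"duplicate row id: {rid!r}")
        seen.add(rid)
        if not body:
            raise ParseError(f"empty record: {rid!r}")
        rows.append((rid, body.replace(".", "")))
    if not rows:
        raise ParseError("no a3m records found")
    try:
        msa = Msa(rows=tuple(rows), dialect=Dialect.A3M)
    except ValidationError as exc:
        raise ParseError(str(exc)) from exc
    if header is not None and msa.n_match_states != sum(header.lengths):
        raise ParseError(
            f"match-state count {msa.n_match_states} does not equal the "
            f"pairing-header total {sum(header.lengths)}")
    return msa, header


def write_a3m(msa: Msa, header: PairingHeader | None = None) -> str:
    """Serialize an A3M-dialect alignment; round-trips byte-exactly with
    :func:`read_a3m`."""
    if msa.dialect is not Dialect.A3M:
        raise ValidationError("write_a3m requires an A3M-dialect MSA")
    if header is not None and msa.n_match_states != sum(header.lengths):
        raise ValidationError("pairing-header lengths do not sum to the "
                              "match-state count")
    out = io.StringIO()
    if header is not None:
        out.write(header.to_line() + "\n")
    for rid, row in msa.rows:
        out.write(f">{rid}\n{row}\n")
    return out.getvalue()


def write_aligned_fasta(msa: Msa) -> str:
    if msa.dialect is not Dialect.ALIGNED_FASTA:
        raise ValidationError("write_aligned_fasta requires an ALIGNED_FASTA MSA")
    out = io.StringIO()
    for rid, row in msa.rows:
        out.write(f">{rid}\n{row}\n")
    return out.getvalue()


def read_aligned_fasta(source: str | TextIO) -> Msa:
    """Parse aligned FASTA (equal-length gapped rows)."""
    rows: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rid, _desc, body in _iter_fasta_records(_as_text(source)):
        if rid in seen:
            raise ParseError(f"duplicate row id: {rid!r}")
        seen.add(rid)
        rows.append((rid, body.upper()))
    if not rows:
        raise ParseError("no records found")
    try:
        return Msa(rows=tuple(rows), dialect=Dialect.ALIGNED_FASTA)
    except ValidationError as exc:
        raise ParseError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Dialect conversion


def _split_a3m_row(row: str) -> tuple[list[str], list[str]]:
    """Decompose an a3m row into match-state characters and the insertion run
    attached after each match column (index 0 = before the first column)."""
    matches: list[str] = []
    inserts: list[str] = [""]
    for c in row:
        if c == "-" or c.isupper() or c.isdigit():
            matches.append(c)
            inserts.append("")
        else:
            inserts[-1] += c
    return matches, inserts


def a3m_to_aligned(msa: Msa) -> Msa:
    """Expand a3m insertions into explicit gap columns shared by all rows.

    Output dialect is ALIGNED_FASTA (insertions are uppercased; the
    insertion/match distinction is recoverable via :func:`aligned_to_a3m`
    with the first row as reference only when the first row is the ungapped
    query).
    """
    if msa.dialect is not Dialect.A3M:
        raise ValidationError("a3m_to_aligned requires an A3M-dialect MSA")
    parsed = [_split_a3m_row(row) for _, row in msa.rows]
    n_match = len(parsed[0][0])
    widths = [0] * (n_match + 1)
    for _, inserts in parsed:
        for k, run in enumerate(inserts):
            widths[k] = max(widths[k], len(run))
    out_rows: list[tuple[str, str]] = []
    for (rid, _), (matches, inserts) in zip(msa.rows, parsed):
        parts: list[str] = []
        for k in range(n_match + 1):
            run = inserts[k].upper()
            parts.append(run + "-" * (widths[k] - len(run)))
            if k < n_match:
                parts.append(matches[k])
        out_rows.append((rid, "".join(parts)))
    return Msa(rows=tuple(out_rows), dialect=Dialect.ALIGNED_FASTA)


def aligned_to_a3m(msa: Msa, reference_id: str) -> Msa:
    """Convert an aligned FASTA MSA to a3m relative to one reference row.

    Columns where the reference row is gapped become lowercase insertions in
    the other rows (and disappear from the reference); columns gapped in
    every row are dropped.  The reference row is moved to the top.
    """
    if msa.dialect is not Dialect.ALIGNED_FASTA:
        raise ValidationError("aligned_to_a3m requires an ALIGNED_FASTA MSA")
    ref_row = msa.row(reference_id)  # raises on unknown id
    ordered = [(reference_id, ref_row)] + [
        (rid, row) for rid, row in msa.rows if rid != reference_id]
    out: dict[str, list[str]] = {rid: [] for rid, _ in ordered}
    for col, ref_c in enumerate(ref_row):
        if ref_c == "-":
            for rid, row in ordered:
                if rid == reference_id:
                    continue
                c = row[col]
                if c != "-":
                    out[rid].append(c.lower())
        else:
            for rid, row in ordered:
                out[rid].append(row[col].upper() if row[col] != "-" else "-")
    return Msa(rows=tuple((rid, "".join(out[rid])) for rid, _ in ordered),
               dialect=Dialect.A3M)
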
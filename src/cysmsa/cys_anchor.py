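"""Cysteine-anchored alignment.

Small secreted cysteine-rich proteins keep their disulfide scaffold while
the inter-cysteine segments drift heavily, so a profitable alignment
strategy is to pin structurally homologous cysteines to shared "anchor
slots" and align only the segments between them.  This module provides:

* a catalog of disulfide connectivity patterns (ordinal pair maps),
* the barcode/debarcode transform: assigned cysteines are replaced by
  rare placeholder letters so an external aligner cannot mispair them,
* a deterministic affine-gap global pairwise aligner,
* a self-contained anchor-constrained aligner (split at anchors, then
  center-star alignment per segment slot), and
* incremental MSA augmentation via pairwise alignment against one row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence as TSequence

from .errors import ParseError, ValidationError
from .msa_core import Dialect, Msa, Sequence, ungap

#: Default placeholder alphabet for barcoding.  'X' is excluded (it is a
#: legal residue); letters first, then digits for >5 anchor slots.
DEFAULT_PLACEHOLDERS = "BJOUZ0123456789"

#: Marker for an anchor slot with no cysteine in a given sequence.
ABSENT = None

AUTO = "AUTO"


# ---------------------------------------------------------------------------
# Connectivity catalog


@dataclass(frozen=True)
class ConnectivityPattern:
    """A named disulfide connectivity: pairs of 1-based cysteine ordinals."""

    name: str
    n_cys: int
    pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "pairs",
            frozenset(tuple(sorted(p)) for p in self.pairs))
        seen: set[int] = set()
        for a, b in self.pairs:
            for x in (a, b):
                if x < 1 or x > self.n_cys:
                    raise ValidationError(
                        f"pattern {self.name!r}: ordinal {x} out of range 1..{self.n_cys}")
                if x in seen:
                    raise ValidationError(
                        f"pattern {self.name!r}: ordinal {x} appears in two pairs")
                seen.add(x)


def _pat(name: str, n_cys: int, *pairs: tuple[int, int]) -> ConnectivityPattern:
    return ConnectivityPattern(name=name, n_cys=n_cys, pairs=frozenset(pairs))


#: Built-in connectivity catalog.
CATALOG: tuple[ConnectivityPattern, ...] = (
    _pat("DEF8", 8, (1, 8), (2, 5), (3, 6), (4, 7)),
    _pat("TEN_A", 10, (1, 10), (2, 6), (3, 7), (4, 9), (5, 8)),
    _pat("TEN_B", 10, (1, 9), (2, 10), (3, 6), (4, 7), (5, 8)),
    _pat("TEN_C", 10, (1, 10), (2, 5), (3, 7), (4, 8), (6, 9)),
    _pat("EIGHT_ALT", 8, (1, 4), (2, 6), (3, 7), (5, 8)),
)


def read_catalog(text: str) -> list[ConnectivityPattern]:
    """Parse a plain-text catalog: one ``name<TAB>n_cys<TAB>1-8,2-5,...``
    entry per line; '#' comments and blank lines ignored."""
    patterns: list[ConnectivityPattern] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ParseError(f"catalog line {lineno}: expected 3 tab-separated fields")
        name, n_cys_s, pairs_s = parts
        try:
            n_cys = int(n_cys_s)
            pairs = frozenset(
                tuple(sorted(int(x) for x in chunk.split("-")))
                for chunk in pairs_s.split(","))
        except ValueError as exc:
            raise ParseError(f"catalog line {lineno}: {exc}") from exc
        patterns.append(ConnectivityPattern(name=name, n_cys=n_cys, pairs=pairs))
    if not patterns:
        raise ParseError("empty connectivity catalog")
    return patterns


def write_catalog(patterns: TSequence[ConnectivityPattern]) -> str:
    lines = []
    for p in patterns:
        pairs = ",".join(f"{a}-{b}" for a, b in sorted(p.pairs))
        lines.append(f"{p.name}\t{p.n_cys}\t{pairs}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Anchor assignments


@dataclass(frozen=True)
class AnchorAssignment:
    """Maps global anchor slots 1..K to a sequence's cysteine occurrences.

    ``slots[k-1]`` is the 1-based ordinal of the cysteine occurrence bound to
    slot k, or :data:`ABSENT` (None) when the sequence lacks that anchor.
    """

    sequence_id: str
    slots: tuple[int | None, ...]

    def __post_init__(self) -> None:
        present = [s for s in self.slots if s is not None]
        if len(set(present)) != len(present):
            raise ValidationError(
                f"assignment for {self.sequence_id!r}: a cysteine occurrence "
                "is bound to two slots")
        if any(s < 1 for s in present):
            raise ValidationError(
                f"assignment for {self.sequence_id!r}: occurrences are 1-based")

    @property
    def n_slots(self) -> int:
        return len(self.slots)


def full_assignment(seq: Sequence, n_slots: int | None = None) -> AnchorAssignment:
    """Identity assignment: slot k ↦ k-th cysteine, for each cysteine present;
    trailing slots beyond the sequence's cysteine count are ABSENT."""
    n_cys = len(find_cysteines(seq))
    k = n_cys if n_slots is None else n_slots
    slots = tuple(i + 1 if i < n_cys else ABSENT for i in range(k))
    return AnchorAssignment(sequence_id=seq.id, slots=slots)


# ---------------------------------------------------------------------------
# Basic operations


def find_cysteines(seq: Sequence) -> list[int]:
    """1-based positions of 'C' residues, in order."""
    return [i + 1 for i, c in enumerate(seq.residues) if c == "C"]


def barcode(seq: Sequence, assign: AnchorAssignment,
            placeholders: str = DEFAULT_PLACEHOLDERS) -> Sequence:
    """Replace slot-assigned cysteines with placeholder letters.

    The cysteine bound to slot k becomes ``placeholders[k-1]``; unassigned
    cysteines and all other residues are untouched.  Exporting more than six
    placeholders triggers a warning (some external aligners reject
    non-standard letters).
    """
    if assign.n_slots > len(placeholders):
        raise ValidationError(
            f"{assign.n_slots} anchor slots exceed the {len(placeholders)}-letter "
            "placeholder alphabet")
    positions = find_cysteines(seq)
    chars = list(seq.residues)
    used = 0
    for k, occ in enumerate(assign.slots, start=1):
        if occ is ABSENT:
            continue
        if occ > len(positions):
            raise ValidationError(
                f"slot {k} of {seq.id!r} references cysteine occurrence {occ}, "
                f"but only {len(positions)} exist")
        chars[positions[occ - 1] - 1] = placeholders[k - 1]
        used = max(used, k)
    if used > 6:
        warnings.warn(
            f"{used} placeholders in use; external aligners with strict "
            "alphabets may reject digits", stacklevel=2)
    return Sequence(id=seq.id, residues="".join(chars), description=seq.description)


def _debarcode_char(c: str, table: frozenset[str]) -> str:
    if c.upper() in table:
        return "c" if c.islower() else "C"
    return c


def debarcode(msa: Msa, placeholders: str = DEFAULT_PLACEHOLDERS) -> Msa:
    """Restore every placeholder character (either case) to cysteine."""
    table = frozenset(placeholders.upper())
    rows = tuple(
        (rid, "".join(_debarcode_char(c, table) for c in row))
        for rid, row in msa.rows)
    return Msa(rows=rows, dialect=msa.dialect)


def debarcode_sequence(seq: Sequence,
                       placeholders: str = DEFAULT_PLACEHOLDERS) -> Sequence:
    table = frozenset(placeholders.upper())
    return Sequence(id=seq.id,
                    residues="".join(_debarcode_char(c, table) for c in seq.residues),
                    description=seq.description)


# ---------------------------------------------------------------------------
# Pairwise global alignment (Gotoh, affine gaps, deterministic traceback)


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties.

    A gap of length L costs ``gap_open + (L-1) * gap_extend``.  Characters
    absent from the matrix (placeholders) are scored as 'X'.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValidationError("gap penalties must be non-negative")
        if self.gap_extend > self.gap_open:
            raise ValidationError("gap-extend must not exceed gap-open")

    def score(self, a: str, b: str) -> float:
        return _matrix_lookup(self.matrix)(a, b)


@lru_cache(maxsize=8)
def _matrix_lookup(name: str):
    if name == "IDENTITY":
        return lambda a, b: 1.0 if a == b else -1.0
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load(name)
    alphabet = set(mat.alphabet)

    def look(a: str, b: str) -> float:
        a = a if a in alphabet else "X"
        b = b if b in alphabet else "X"
        return float(mat[a, b])

    return look


_NEG = float("-inf")


def pairwise_global_align(
    a: Sequence | str, b: Sequence | str,
    scoring: ScoringScheme | None = None,
) -> tuple[str, str, float]:
    """Optimal global alignment with affine gaps (Gotoh algorithm).

    Ties are broken deterministically: diagonal, then vertical (consume a
    residue of ``a``), then horizontal.  Returns the two gapped strings and
    the optimal score.
    """
    sa = a.residues if isinstance(a, Sequence) else a
    sb = b.residues if isinstance(b, Sequence) else b
    if not sa or not sb:
        raise ValidationError("pairwise alignment requires non-empty sequences")
    scoring = scoring or ScoringScheme()
    go, ge = scoring.gap_open, scoring.gap_extend
    n, m = len(sa), len(sb)

    # M: sa[i-1] aligned to sb[j-1]; X: gap in sb (consumes sa); Y: gap in sa.
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]
    # Traceback pointers: which state each cell came from.
    ptr_m = [[0] * (m + 1) for _ in range(n + 1)]
    ptr_x = [[0] * (m + 1) for _ in range(n + 1)]
    ptr_y = [[0] * (m + 1) for _ in range(n + 1)]
    _M, _X, _Y = 0, 1, 2

    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(go + (i - 1) * ge)
        ptr_x[i][0] = _X if i > 1 else _M
    for j in range(1, m + 1):
        Y[0][j] = -(go + (j - 1) * ge)
        ptr_y[0][j] = _Y if j > 1 else _M

    for i in range(1, n + 1):
        row_m, row_x, row_y = M[i], X[i], Y[i]
        prev_m, prev_x, prev_y = M[i - 1], X[i - 1], Y[i - 1]
        ca = sa[i - 1]
        for j in range(1, m + 1):
            s = scoring.score(ca, sb[j - 1])
            # match state: best of the three predecessors at (i-1, j-1)
            best, state = prev_m[j - 1], _M
            if prev_x[j - 1] > best:
                best, state = prev_x[j - 1], _X
            if prev_y[j - 1] > best:
                best, state = prev_y[j - 1], _Y
            row_m[j] = best + s
            ptr_m[i][j] = state
            # X: gap in sb; open from M, extend from X (preference: open on tie
            # is irrelevant to the emitted alignment, fixed as >= for open)
            open_x = prev_m[j] - go
            ext_x = prev_x[j] - ge
            if open_x >= ext_x:
                row_x[j], ptr_x[i][j] = open_x, _M
            else:
                row_x[j], ptr_x[i][j] = ext_x, _X
            open_y = row_m[j - 1] - go
            ext_y = row_y[j - 1] - ge
            if open_y >= ext_y:
                row_y[j], ptr_y[i][j] = open_y, _M
            else:
                row_y[j], ptr_y[i][j] = ext_y, _Y

    # Final state preference: diagonal (M), vertical (X), horizontal (Y).
    i, j = n, m
    best, state = M[i][j], _M
    if X[i][j] > best:
        best, state = X[i][j], _X
    if Y[i][j] > best:
        best, state = Y[i][j], _Y
    score = best

    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == _M:
            prev = ptr_m[i][j]
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            i -= 1
            j -= 1
            state = prev
        elif state == _X:
            prev = ptr_x[i][j]
            out_a.append(sa[i - 1])
            out_b.append("-")
            i -= 1
            state = prev
        else:
            prev = ptr_y[i][j]
            out_a.append("-")
            out_b.append(sb[j - 1])
            j -= 1
            state = prev
    return "".join(reversed(out_a)), "".join(reversed(out_b)), score


def percent_identity_of_alignment(aligned_a: str, aligned_b: str) -> float:
    """Identical aligned residue pairs divided by alignment length."""
    if len(aligned_a) != len(aligned_b):
        raise ValidationError("aligned strings differ in length")
    matches = sum(1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-")
    return matches / len(aligned_a) if aligned_a else 0.0


# ---------------------------------------------------------------------------
# Center-star multiple alignment of one segment slot


def _merge_center_alignments(center: str,
                             others: list[tuple[str, str]]) -> list[str]:
    """Merge pairwise alignments (other_aligned, center_aligned) into one
    multiple alignment via the shared center ('once a gap, always a gap').

    Returns [center_row, other_row_0, ...] with equal lengths.
    """
    master = center  # center with accumulated gaps
    rows: list[str] = []
    for other_aln, center_aln in others:
        i = j = 0
        new_master: list[str] = []
        new_row: list[str] = []
        patched: list[list[str]] = [[] for _ in rows]
        while i < len(master) or j < len(center_aln):
            mc = master[i] if i < len(master) else None
            cc = center_aln[j] if j < len(center_aln) else None
            if mc is not None and mc == "-" and (cc is None or cc != "-"):
                # gap inserted by an earlier merge
                new_master.append("-")
                new_row.append("-")
                for k, r in enumerate(rows):
                    patched[k].append(r[i])
                i += 1
            elif cc is not None and cc == "-" and (mc is None or mc != "-"):
                # gap required by the new pairwise alignment
                new_master.append("-")
                new_row.append(other_aln[j])
                for k in range(len(rows)):
                    patched[k].append("-")
                j += 1
            elif mc is not None and cc is not None and mc == "-" and cc == "-":
                # independent gaps: consume the master gap first (deterministic)
                new_master.append("-")
                new_row.append("-")
                for k, r in enumerate(rows):
                    patched[k].append(r[i])
                i += 1
            else:
                # both carry the same center residue
                new_master.append(mc)  # type: ignore[arg-type]
                new_row.append(other_aln[j])
                for k, r in enumerate(rows):
                    patched[k].append(r[i])
                i += 1
                j += 1
        master = "".join(new_master)
        rows = ["".join(p) for p in patched]
        rows.append("".join(new_row))
    return [master] + rows


def center_star_align(segments: TSequence[str],
                      scoring: ScoringScheme | None = None) -> list[str]:
    """Center-star alignment of short segment strings.

    The center is the segment with the highest summed pairwise score against
    all others (tie: lowest input index); every other segment is aligned to
    the center pairwise and merged.  Empty segments become all-gap rows.
    """
    scoring = scoring or ScoringScheme()
    nonempty = [i for i, s in enumerate(segments) if s]
    if not nonempty:
        return ["" for _ in segments]
    if len(nonempty) == 1:
        width = len(segments[nonempty[0]])
        return [segments[i] if i in nonempty else "-" * width
                for i in range(len(segments))]

    scores = {i: 0.0 for i in nonempty}
    aligns: dict[tuple[int, int], tuple[str, str, float]] = {}
    for ai in range(len(nonempty)):
        for bi in range(ai + 1, len(nonempty)):
            i, j = nonempty[ai], nonempty[bi]
            aln = pairwise_global_align(segments[i], segments[j], scoring)
            aligns[(i, j)] = aln
            scores[i] += aln[2]
            scores[j] += aln[2]
    center = max(nonempty, key=lambda i: (scores[i], -i))

    others: list[tuple[str, str]] = []
    order: list[int] = []
    for i in nonempty:
        if i == center:
            continue
        if (min(i, center), max(i, center)) in aligns:
            a, b, _ = aligns[(min(i, center), max(i, center))]
            if i < center:
                other_aln, center_aln = a, b
            else:
                other_aln, center_aln = b, a
        else:  # pragma: no cover - all pairs computed above
            other_aln, center_aln, _ = pairwise_global_align(
                segments[i], segments[center], scoring)
        others.append((other_aln, center_aln))
        order.append(i)

    merged = _merge_center_alignments(segments[center], others)
    width = len(merged[0])
    out = ["-" * width] * len(segments)
    out[center] = merged[0]
    for pos, i in enumerate(order):
        out[i] = merged[pos + 1]
    return out


# ---------------------------------------------------------------------------
# Anchor-constrained multiple alignment


def _split_at_anchors(seq: Sequence, assign: AnchorAssignment) -> list[str]:
    """Split residues into K+1 segments at the assigned anchor cysteines.

    Residues spanning an ABSENT slot flow into the segment preceding that
    slot's anchor column.
    """
    positions = find_cysteines(seq)
    k = assign.n_slots
    anchor_pos: list[int | None] = []
    for slot, occ in enumerate(assign.slots, start=1):
        if occ is ABSENT:
            anchor_pos.append(None)
            continue
        if occ > len(positions):
            raise ValidationError(
                f"slot {slot} of {seq.id!r} references cysteine occurrence {occ}, "
                f"but only {len(positions)} exist")
        anchor_pos.append(positions[occ - 1])
    present = [p for p in anchor_pos if p is not None]
    if any(b <= a for a, b in zip(present, present[1:])):
        raise ValidationError(
            f"assignment for {seq.id!r}: anchor positions are not increasing "
            "in slot order")
    segments = [""] * (k + 1)
    cur = 0
    last_assigned = 0
    for slot in range(1, k + 1):
        p = anchor_pos[slot - 1]
        if p is None:
            continue
        segments[last_assigned] = seq.residues[cur:p - 1]
        cur = p
        last_assigned = slot
    segments[last_assigned] = seq.residues[cur:]
    return segments


def anchor_align(seqs: TSequence[Sequence],
                 assigns: TSequence[AnchorAssignment],
                 scoring: ScoringScheme | None = None) -> Msa:
    """Anchor-constrained multiple alignment.

    The output has exactly K single-character anchor columns; each shows 'C'
    where the slot is assigned and '-' where it is ABSENT.  The segments
    between anchors are aligned independently by center-star alignment.
    Row order follows the input; per-row residues are conserved.
    """
    if len(seqs) != len(assigns):
        raise ValidationError("sequence and assignment counts differ")
    if not seqs:
        raise ValidationError("no sequences to align")
    k = assigns[0].n_slots
    for a in assigns:
        if a.n_slots != k:
            raise ValidationError(
                f"assignment for {a.sequence_id!r} has {a.n_slots} slots, expected {k}")
    by_id = {a.sequence_id: a for a in assigns}
    scoring = scoring or ScoringScheme()

    split = []
    for s in seqs:
        if s.id not in by_id:
            raise ValidationError(f"no assignment for sequence {s.id!r}")
        split.append(_split_at_anchors(s, by_id[s.id]))

    segment_alns = [
        center_star_align([split[r][j] for r in range(len(seqs))], scoring)
        for j in range(k + 1)]

    rows: list[tuple[str, str]] = []
    for r, s in enumerate(seqs):
        assign = by_id[s.id]
        parts: list[str] = []
        for j in range(k + 1):
            parts.append(segment_alns[j][r])
            if j < k:
                parts.append("C" if assign.slots[j] is not ABSENT else "-")
        rows.append((s.id, "".join(parts)))
    return Msa(rows=tuple(rows), dialect=Dialect.ALIGNED_FASTA)


# ---------------------------------------------------------------------------
# Incremental MSA augmentation


def merge_into_msa(msa: Msa, new: Sequence, anchor_row_id: str = AUTO,
                   scoring: ScoringScheme | None = None) -> Msa:
    """Add a sequence to an aligned MSA by pairwise alignment to one row.

    The new sequence is globally aligned to the anchor row's ungapped
    residues and the alignment is projected into MSA coordinates: insertions
    relative to the anchor open new all-gap columns in the existing rows.
    ``anchor_row_id=AUTO`` picks the row with the highest percent identity to
    ``new`` (ties: first row).
    """
    if msa.dialect is not Dialect.ALIGNED_FASTA:
        raise ValidationError("merge_into_msa requires an ALIGNED_FASTA MSA")
    scoring = scoring or ScoringScheme()
    if new.id in msa.ids:
        raise ValidationError(f"id {new.id!r} already present in the MSA")

    if anchor_row_id == AUTO:
        best_id, best_ident = None, -1.0
        for rid, row in msa.rows:
            aa, ab, _ = pairwise_global_align(new.residues, ungap(row), scoring)
            ident = percent_identity_of_alignment(aa, ab)
            if ident > best_ident:
                best_id, best_ident = rid, ident
        anchor_row_id = best_id  # type: ignore[assignment]

    anchor_row = msa.row(anchor_row_id)  # raises on unknown id
    anchor_seq = ungap(anchor_row)
    aln_new, aln_anchor, _ = pairwise_global_align(new.residues, anchor_seq, scoring)

    old_rows = [list(row) for _, row in msa.rows]
    new_cols: list[list[str]] = [[] for _ in old_rows]
    new_row: list[str] = []
    p = 0  # pointer into the pairwise alignment

    def emit_insertions() -> None:
        nonlocal p
        while p < len(aln_anchor) and aln_anchor[p] == "-":
            for col in new_cols:
                col.append("-")
            new_row.append(aln_new[p])
            p += 1

    for col_idx, anchor_c in enumerate(anchor_row):
        if anchor_c == "-":
            for r, col in enumerate(new_cols):
                col.append(old_rows[r][col_idx])
            new_row.append("-")
            continue
        emit_insertions()
        assert p < len(aln_anchor) and aln_anchor[p] == anchor_c.upper()
        for r, col in enumerate(new_cols):
            col.append(old_rows[r][col_idx])
        new_row.append(aln_new[p])
        p += 1
    emit_insertions()

    rows = tuple(
        [(rid, "".join(new_cols[r])) for r, (rid, _) in enumerate(msa.rows)]
        + [(new.id, "".join(new_row))])
    return Msa(rows=rows, dialect=Dialect.ALIGNED_FASTA)
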
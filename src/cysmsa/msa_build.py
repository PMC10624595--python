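"""MSA depth metrics, paired complex a3m assembly, and refinement jobs.

``compute_neff`` implements the classic cluster-weighted effective-sequence
count: each row is weighted by the inverse size of its identity cluster at a
threshold, and the per-position profile sums the weights of rows that cover
each query position.

``build_complex_bundle`` assembles the three-block a3m used for cognate
receptor–ligand complex prediction: a paired block of horizontally
concatenated cognate rows first, then the two single-chain MSAs padded with
gaps on the partner side, under a ``#L1,L2<TAB>1,1`` pairing header.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence as TSequence

from .errors import ParseError, ValidationError
from .msa_core import (
    Dialect,
    Msa,
    PairingHeader,
    Sequence,
    aligned_to_a3m,
    match_states,
    read_a3m,
    ungap,
    write_a3m,
)

IdentityDenominator = Literal["union", "shorter", "all"]


def pairwise_identity(row_a: str, row_b: str,
                      denominator: IdentityDenominator = "union") -> float:
    """Fraction of identical matching columns between two equal-length rows.

    ``denominator`` selects the normalization: "union" (default) counts
    columns where at least one row is non-gap, "shorter" uses the shorter
    ungapped length, "all" uses the full column count.
    """
    if len(row_a) != len(row_b):
        raise ValidationError(
            f"row lengths differ: {len(row_a)} vs {len(row_b)}")
    matches = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    if denominator == "union":
        denom = sum(1 for x, y in zip(row_a, row_b) if x != "-" or y != "-")
    elif denominator == "shorter":
        denom = min(len(row_a) - row_a.count("-"), len(row_b) - row_b.count("-"))
    elif denominator == "all":
        denom = len(row_a)
    else:
        raise ValidationError(f"unknown identity denominator: {denominator!r}")
    return matches / denom if denom else 0.0


@dataclass(frozen=True)
class NeffProfile:
    """Per-query-position effective sequence counts."""

    per_position: tuple[float, ...]
    threshold: float
    normalized: bool

    def to_tsv(self) -> str:
        return "".join(f"{i}\t{v:.6g}\n"
                       for i, v in enumerate(self.per_position, start=1))


def compute_neff(msa: Msa, threshold: float = 0.8, normalize: bool = False,
                 denominator: IdentityDenominator = "union") -> NeffProfile:
    """Cluster-weighted effective sequence count per query position.

    Row weights are ``1 / |{t : identity(s, t) >= threshold}|`` (the cluster
    includes the row itself); position i sums the weights of rows non-gap at
    the column of the query's i-th residue.  ``normalize`` divides by
    sqrt(query length).  The first row is the query.
    """
    if not 0.0 < threshold < 1.0:
        raise ValidationError("threshold must be a fraction in (0, 1)")
    if msa.dialect is Dialect.A3M:
        rows = [match_states(row) for _, row in msa.rows]
    else:
        rows = [row for _, row in msa.rows]
    n = len(rows)
    cluster_sizes = [1] * n  # self-identity always >= threshold
    for i in range(n):
        for j in range(i + 1, n):
            if pairwise_identity(rows[i], rows[j], denominator) >= threshold:
                cluster_sizes[i] += 1
                cluster_sizes[j] += 1
    weights = [1.0 / c for c in cluster_sizes]

    query = rows[0]
    query_cols = [c for c, ch in enumerate(query) if ch != "-"]
    per_pos = []
    for c in query_cols:
        per_pos.append(sum(w for row, w in zip(rows, weights) if row[c] != "-"))
    if normalize:
        scale = math.sqrt(len(query_cols))
        per_pos = [v / scale for v in per_pos]
    return NeffProfile(per_position=tuple(per_pos), threshold=threshold,
                       normalized=normalize)


# ---------------------------------------------------------------------------
# Paired complex bundle


@dataclass(frozen=True)
class HaplotypePair:
    """A cognate receptor–ligand sequence pair sharing one haplotype label."""

    label: str
    receptor: Sequence
    ligand: Sequence

    def __post_init__(self) -> None:
        if not self.label or any(c.isspace() for c in self.label):
            raise ValidationError(f"invalid haplotype label: {self.label!r}")


@dataclass(frozen=True)
class ComplexMsaBundle:
    """Three-block paired a3m for complex prediction.

    ``paired_rows`` concatenate each label's receptor and ligand a3m rows;
    ``receptor_block`` rows end with ligand-length gap padding and
    ``ligand_block`` rows begin with receptor-length gap padding.
    """

    header: PairingHeader
    paired_rows: tuple[tuple[str, str], ...]
    receptor_block: Msa
    ligand_block: Msa

    def __post_init__(self) -> None:
        if len(self.header.lengths) != 2:
            raise ValidationError("complex bundle requires a two-component header")
        total = sum(self.header.lengths)
        for rid, row in self.paired_rows:
            if len(match_states(row)) != total:
                raise ValidationError(
                    f"paired row {rid!r} has {len(match_states(row))} match "
                    f"states, expected {total}")
        lr, ll = self.header.lengths
        for rid, row in self.receptor_block.rows:
            if not match_states(row).endswith("-" * ll):
                raise ValidationError(
                    f"receptor-block row {rid!r} lacks ligand-side gap padding")
        for rid, row in self.ligand_block.rows:
            if not match_states(row).startswith("-" * lr):
                raise ValidationError(
                    f"ligand-block row {rid!r} lacks receptor-side gap padding")

    def to_a3m(self) -> str:
        rows = (list(self.paired_rows) + list(self.receptor_block.rows)
                + list(self.ligand_block.rows))
        msa = Msa(rows=tuple(rows), dialect=Dialect.A3M)
        return write_a3m(msa, header=self.header)

    @classmethod
    def from_a3m(cls, text: str) -> "ComplexMsaBundle":
        msa, header = read_a3m(text)
        if header is None or len(header.lengths) != 2:
            raise ParseError("complex a3m requires a two-component pairing header")
        lr, ll = header.lengths
        paired: list[tuple[str, str]] = []
        receptor: list[tuple[str, str]] = []
        ligand: list[tuple[str, str]] = []
        for rid, row in msa.rows:
            ms = match_states(row)
            rec_half, lig_half = ms[:lr], ms[lr:]
            if set(lig_half) == {"-"} and set(rec_half) != {"-"}:
                receptor.append((rid, row))
            elif set(rec_half) == {"-"} and set(lig_half) != {"-"}:
                ligand.append((rid, row))
            else:
                paired.append((rid, row))
        if not paired or not receptor or not ligand:
            raise ParseError("complex a3m must contain paired, receptor, and "
                             "ligand blocks")
        return cls(header=header, paired_rows=tuple(paired),
                   receptor_block=Msa(rows=tuple(receptor), dialect=Dialect.A3M),
                   ligand_block=Msa(rows=tuple(ligand), dialect=Dialect.A3M))


def _as_query_relative_a3m(msa: Msa, query_row_id: str) -> Msa:
    """Express an MSA in a3m form relative to one query row (query first)."""
    if msa.dialect is Dialect.ALIGNED_FASTA:
        return aligned_to_a3m(msa, query_row_id)
    return promote_query(msa, query_row_id)


def build_complex_bundle(pairs: TSequence[HaplotypePair], receptor_msa: Msa,
                         ligand_msa: Msa, query_label: str) -> ComplexMsaBundle:
    """Assemble the paired complex bundle for a set of cognate pairs.

    Each pair's receptor and ligand must appear as rows (matched by id) of
    the respective MSAs.  The query pair leads the paired block; the padded
    single-chain blocks contain the full MSAs.  Aligned-FASTA inputs are
    converted to a3m relative to the query pair's rows.
    """
    by_label = {p.label: p for p in pairs}
    if len(by_label) != len(pairs):
        raise ValidationError("duplicate haplotype labels")
    if query_label not in by_label:
        raise ValidationError(f"query label {query_label!r} not among the pairs")
    query = by_label[query_label]

    for p in pairs:
        if p.receptor.id not in receptor_msa.ids:
            raise ValidationError(
                f"receptor {p.receptor.id!r} (pair {p.label!r}) missing from "
                "the receptor MSA")
        if p.ligand.id not in ligand_msa.ids:
            raise ValidationError(
                f"ligand {p.ligand.id!r} (pair {p.label!r}) missing from the "
                "ligand MSA")

    rec = _as_query_relative_a3m(receptor_msa, query.receptor.id)
    lig = _as_query_relative_a3m(ligand_msa, query.ligand.id)
    lr, ll = rec.n_match_states, lig.n_match_states
    header = PairingHeader(lengths=(lr, ll), cardinalities=(1, 1))

    ordered = [query] + [p for p in pairs if p.label != query_label]
    paired = tuple(
        (p.label, rec.row(p.receptor.id) + lig.row(p.ligand.id))
        for p in ordered)
    receptor_block = Msa(
        rows=tuple((rid, row + "-" * ll) for rid, row in rec.rows),
        dialect=Dialect.A3M)
    ligand_block = Msa(
        rows=tuple((rid, "-" * lr + row) for rid, row in lig.rows),
        dialect=Dialect.A3M)
    return ComplexMsaBundle(header=header, paired_rows=paired,
                            receptor_block=receptor_block,
                            ligand_block=ligand_block)


# ---------------------------------------------------------------------------
# Query promotion and refinement jobs


def promote_query(msa: Msa, rid: str) -> Msa:
    """Move the row with the given id to the top (other rows keep order)."""
    if rid not in msa.ids:
        raise ValidationError(f"unknown row id: {rid!r}")
    head = [(i, r) for i, r in msa.rows if i == rid]
    tail = [(i, r) for i, r in msa.rows if i != rid]
    return Msa(rows=tuple(head + tail), dialect=msa.dialect)


@dataclass(frozen=True)
class RefinementJob:
    """A template-guided re-prediction job for a class-restricted MSA."""

    query_id: str
    msa: Msa
    template_path: str
    recycles: int = 9

    def __post_init__(self) -> None:
        if self.recycles < 1:
            raise ValidationError("recycles must be >= 1")

    def manifest(self, msa_path: str | Path) -> str:
        """Flat key-value manifest for downstream prediction engines."""
        return (f"query\t{self.query_id}\n"
                f"msa\t{msa_path}\n"
                f"template\t{self.template_path}\n"
                f"recycles\t{self.recycles}\n")


def make_refinement_job(query_id: str, class_msa: Msa,
                        candidate_models: TSequence[tuple[str, float]],
                        recycles: int = 9) -> RefinementJob:
    """Build a refinement job: template = best-mean-pLDDT candidate (ties:
    first listed), MSA = class MSA with the query promoted."""
    if not candidate_models:
        raise ValidationError("no candidate models")
    best_path, _ = max(candidate_models, key=lambda c: c[1])
    # max() keeps the first maximum on ties, matching the documented tie-break
    return RefinementJob(query_id=query_id,
                         msa=promote_query(class_msa, query_id),
                         template_path=best_path, recycles=recycles)
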
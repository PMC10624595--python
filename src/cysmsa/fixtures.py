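"""Synthetic data generators.

Everything here is deterministic for a fixed seed (NumPy ``default_rng``,
i.e. the PCG64 generator), so fixtures can be regenerated at test time
instead of being shipped.

* :func:`gen_cysrich_family` evolves a cysteine-rich ancestor (fixed
  cysteine scaffold, mutating inter-cysteine segments) into a family of
  sequences with known ground-truth anchor assignments.
* :func:`gen_toy_complex` emits a two-chain coordinate file plus a matching
  PAE file with planted, exactly recoverable interface contacts, disulfide
  pairs, and pLDDT values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cys_anchor import ABSENT, AnchorAssignment
from .errors import ValidationError
from .msa_core import Sequence

#: Residues used for inter-cysteine segments (no C, no X).
SEGMENT_ALPHABET = "ADEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters for a synthetic cysteine-rich sequence family."""

    seed: int
    n_sequences: int = 8
    n_cys: int = 8
    seg_min: int = 2
    seg_max: int = 8
    sub_rate: float = 0.1
    indel_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.n_cys < 0:
            raise ValidationError("n_sequences must be >= 1 and n_cys >= 0")
        if not (0 <= self.seg_min <= self.seg_max):
            raise ValidationError("need 0 <= seg_min <= seg_max")
        for r in (self.sub_rate, self.indel_rate):
            if not 0.0 <= r < 1.0:
                raise ValidationError("rates must lie in [0, 1)")
        if self.indel_rate > 0 and self.seg_max == 0:
            raise ValidationError(
                "segments too short for requested indels (seg_max == 0)")


def _mutate_segment(seg: str, spec: FixtureSpec, rng: np.random.Generator) -> str:
    chars = list(seg)
    for i, c in enumerate(chars):
        if rng.random() < spec.sub_rate:
            choices = [x for x in SEGMENT_ALPHABET if x != c]
            chars[i] = choices[rng.integers(len(choices))]
    if spec.indel_rate > 0 and rng.random() < spec.indel_rate:
        if chars and rng.random() < 0.5:
            del chars[rng.integers(len(chars))]
        else:
            pos = rng.integers(len(chars) + 1)
            chars.insert(pos, SEGMENT_ALPHABET[rng.integers(len(SEGMENT_ALPHABET))])
    return "".join(chars)


def gen_cysrich_family(
    spec: FixtureSpec,
) -> tuple[list[Sequence], list[AnchorAssignment]]:
    """Generate a family of cysteine-rich sequences with ground truth.

    Every output sequence has exactly ``n_cys`` cysteines; substitutions and
    single-residue indels are confined to the inter-cysteine segments.  The
    returned assignments map anchor slot k to the k-th cysteine.
    """
    rng = np.random.default_rng(spec.seed)
    n_seg = spec.n_cys + 1
    ancestor_segs = []
    for _ in range(n_seg):
        length = int(rng.integers(spec.seg_min, spec.seg_max + 1))
        ancestor_segs.append("".join(
            SEGMENT_ALPHABET[rng.integers(len(SEGMENT_ALPHABET))]
            for _ in range(length)))

    seqs: list[Sequence] = []
    assigns: list[AnchorAssignment] = []
    for i in range(spec.n_sequences):
        segs = [_mutate_segment(s, spec, rng) for s in ancestor_segs]
        residues = segs[0] + "".join("C" + s for s in segs[1:])
        if not residues:  # all-empty segments and no cysteines
            residues = SEGMENT_ALPHABET[int(rng.integers(len(SEGMENT_ALPHABET)))]
        sid = f"fam{spec.seed}_{i:03d}"
        seqs.append(Sequence(id=sid, residues=residues))
        assigns.append(AnchorAssignment(
            sequence_id=sid, slots=tuple(range(1, spec.n_cys + 1))))
    return seqs, assigns


def drop_cysteine(
    seq: Sequence, assign: AnchorAssignment, slot: int,
) -> tuple[Sequence, AnchorAssignment]:
    """Delete the cysteine bound to one anchor slot, marking the slot ABSENT.

    Models natural variants missing one anchor of the family scaffold; later
    occurrences shift down by one.
    """
    occ = assign.slots[slot - 1]
    if occ is ABSENT:
        raise ValidationError(f"slot {slot} is already absent")
    positions = [i + 1 for i, c in enumerate(seq.residues) if c == "C"]
    pos = positions[occ - 1]
    residues = seq.residues[:pos - 1] + seq.residues[pos:]
    new_slots = tuple(
        ABSENT if k == slot else (o - 1 if (o is not ABSENT and o > occ) else o)
        for k, o in enumerate(assign.slots, start=1))
    return (Sequence(id=seq.id, residues=residues, description=seq.description),
            AnchorAssignment(sequence_id=seq.id, slots=new_slots))


# ---------------------------------------------------------------------------
# Toy dimer structures


@dataclass(frozen=True)
class ToyComplexSpec:
    """Parameters for a synthetic two-chain structure with planted geometry.

    ``ss_pairs`` are disulfide pairs in cysteine ordinals of the second
    chain; planted interface pairs sit at 3.5 Å, disulfide SG pairs at
    2.05 Å, and every other intergroup distance is at least 6 Å.
    """

    seed: int = 0
    len_a: int = 12
    len_b: int = 10
    n_interface: int = 4
    ss_pairs: tuple[tuple[int, int], ...] = ()
    n_cys: int | None = None
    plddt_a: float | tuple[float, ...] = 90.0
    plddt_b: float | tuple[float, ...] = 80.0
    interface_pae: float = 5.0
    chain_a_id: str = "A"
    chain_b_id: str = "B"

    def __post_init__(self) -> None:
        if self.len_a < 1 or self.len_b < 1:
            raise ValidationError("chains must have at least one residue")
        if not 0 <= self.n_interface <= min(self.len_a, self.len_b):
            raise ValidationError(
                "planted interface count must fit within both chains")
        ordinals = [x for p in self.ss_pairs for x in p]
        if len(set(ordinals)) != len(ordinals):
            raise ValidationError("a cysteine ordinal appears in two ss_pairs")
        n_cys = self.n_cys if self.n_cys is not None else (
            max(ordinals) if ordinals else 0)
        if ordinals and max(ordinals) > n_cys:
            raise ValidationError("ss_pairs reference ordinals beyond n_cys")
        if n_cys > self.len_b:
            raise ValidationError("n_cys exceeds the second chain length")
        object.__setattr__(self, "n_cys", n_cys)
        for v, length in ((self.plddt_a, self.len_a), (self.plddt_b, self.len_b)):
            vals = (v,) if isinstance(v, (int, float)) else tuple(v)
            if isinstance(v, tuple) and len(vals) != length:
                raise ValidationError("per-residue pLDDT length mismatch")
            if any(not 0 <= x <= 100 for x in vals):
                raise ValidationError("pLDDT values must lie in [0, 100]")
        if self.interface_pae < 0:
            raise ValidationError("PAE must be non-negative")


def _plddt_list(v: float | tuple[float, ...], n: int) -> list[float]:
    if isinstance(v, (int, float)):
        return [float(v)] * n
    return [float(x) for x in v]


def build_toy_complex_atoms(spec: ToyComplexSpec):
    """Construct the planted geometry as a biotite ``AtomArray``.

    Chain A runs along x at z = 0 (CA every 10 Å); chain B normally sits at
    z = 20, except its first ``n_interface`` residues whose CA drops to
    z = 3.5 directly beneath the matching chain-A CA.  The first ``n_cys``
    residues of chain B are CYS; their SG atoms live in a remote cluster
    where only planted pairs fall within bonding distance.
    """
    import biotite.structure as struc

    spacing = 10.0
    pl_a = _plddt_list(spec.plddt_a, spec.len_a)
    pl_b = _plddt_list(spec.plddt_b, spec.len_b)

    records: list[tuple[str, int, str, str, str, tuple[float, float, float], float]] = []
    for i in range(spec.len_a):
        records.append((spec.chain_a_id, i + 1, "GLY", "CA", "C",
                        (i * spacing, 0.0, 0.0), pl_a[i]))
    sg_slot = {}
    for p_idx, (a, b) in enumerate(spec.ss_pairs):
        sg_slot[a] = (p_idx * spacing + 200.0, 60.0, 20.0)
        sg_slot[b] = (p_idx * spacing + 200.0, 62.05, 20.0)
    n_unpaired = 0
    for ordinal in range(1, (spec.n_cys or 0) + 1):
        if ordinal not in sg_slot:
            sg_slot[ordinal] = (600.0 + n_unpaired * 20.0, -60.0, 20.0)
            n_unpaired += 1
    for j in range(spec.len_b):
        z = 3.5 if j < spec.n_interface else 20.0
        is_cys = j < (spec.n_cys or 0)
        name = "CYS" if is_cys else "GLY"
        records.append((spec.chain_b_id, j + 1, name, "CA", "C",
                        (j * spacing, 0.0, z), pl_b[j]))
        if is_cys:
            records.append((spec.chain_b_id, j + 1, name, "SG", "S",
                            sg_slot[j + 1], pl_b[j]))

    arr = struc.AtomArray(len(records))
    arr.add_annotation("b_factor", dtype=float)
    arr.add_annotation("occupancy", dtype=float)
    for idx, (cid, rid, rname, aname, elem, xyz, b) in enumerate(records):
        arr.chain_id[idx] = cid
        arr.res_id[idx] = rid
        arr.res_name[idx] = rname
        arr.atom_name[idx] = aname
        arr.element[idx] = elem
        arr.coord[idx] = xyz
        arr.b_factor[idx] = b
        arr.occupancy[idx] = 1.0
    arr.hetero[:] = False
    return arr


def build_toy_pae(spec: ToyComplexSpec, intra: float = 1.0) -> np.ndarray:
    """PAE matrix: ``intra`` within chains, ``spec.interface_pae`` between
    chains, zero diagonal."""
    n = spec.len_a + spec.len_b
    m = np.full((n, n), intra, dtype=float)
    m[:spec.len_a, spec.len_a:] = spec.interface_pae
    m[spec.len_a:, :spec.len_a] = spec.interface_pae
    np.fill_diagonal(m, 0.0)
    return m


def gen_toy_complex(spec: ToyComplexSpec, out_dir: str | Path,
                    stem: str = "toy") -> tuple[Path, Path]:
    """Write the toy model as PDB plus PAE JSON; returns the two paths."""
    from biotite.structure.io.pdb import PDBFile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arr = build_toy_complex_atoms(spec)
    pdb_path = out_dir / f"{stem}.pdb"
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(pdb_path))

    pae = build_toy_pae(spec)
    pae_path = out_dir / f"{stem}_pae.json"
    with open(pae_path, "w", encoding="utf-8") as fh:
        json.dump({"predicted_aligned_error": pae.tolist(),
                   "max_predicted_aligned_error": float(pae.max())}, fh)
    return pdb_path, pae_path
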
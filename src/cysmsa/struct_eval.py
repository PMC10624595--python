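"""Evaluation of predicted structure models.

Parses coordinate files (PDB; mmCIF optionally) with per-residue confidence
in the B-factor column, plus the standard predicted-aligned-error JSON, and
computes:

* mean pLDDT and pLDDT-based model ranking,
* pDockQ and pDockQ2 interface-confidence scores (sigmoid constants default
  to the published reference implementations and are configurable),
* interchain heavy-atom contact counts and interface residue sets,
* disulfide-bond detection and connectivity classification against the
  ordinal-pair catalog,
* Kabsch least-squares superposition and RMSD to a reference model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence as TSequence

import numpy as np

from .cys_anchor import CATALOG, ConnectivityPattern, find_cysteines
from .errors import ParseError, ValidationError
from .msa_core import Sequence

HYDROGEN_ELEMENTS = frozenset({"H", "D"})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: tuple[float, float, float]
    b_factor: float

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coord, dtype=float)


@dataclass(frozen=True)
class Residue:
    name: str
    number: int
    icode: str
    atoms: tuple[Atom, ...]
    plddt: float

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def rep_atom(self) -> Atom:
        """Interface representative: CB, falling back to CA (glycine or
        incomplete residues), then the first atom."""
        return self.atom("CB") or self.atom("CA") or self.atoms[0]


@dataclass(frozen=True)
class Chain:
    id: str
    residues: tuple[Residue, ...]


@dataclass(frozen=True)
class StructureModel:
    chains: tuple[Chain, ...]
    source: str = ""

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate chain ids")

    @property
    def chain_ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.chains)

    def chain(self, cid: str) -> Chain:
        for c in self.chains:
            if c.id == cid:
                return c
        raise ValidationError(f"unknown chain id: {cid!r}")

    def residues(self, chains: Iterable[str] | None = None) -> list[tuple[str, Residue]]:
        wanted = set(chains) if chains is not None else None
        out = []
        for c in self.chains:
            if wanted is None or c.id in wanted:
                out.extend((c.id, r) for r in c.residues)
        return out

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    def one_letter_sequence(self, chain_id: str) -> Sequence:
        chain = self.chain(chain_id)
        letters = "".join(THREE_TO_ONE.get(r.name, "X") for r in chain.residues)
        return Sequence(id=f"{Path(self.source).stem or 'model'}_{chain_id}",
                        residues=letters)


ResidueRef = tuple[str, int, str]  # (chain id, residue number, insertion code)


def _residue_ref(chain_id: str, res: Residue) -> ResidueRef:
    return (chain_id, res.number, res.icode)


# ---------------------------------------------------------------------------
# Parsing


def read_structure(path: str | Path) -> StructureModel:
    """Read a PDB (or mmCIF) model into a :class:`StructureModel`.

    Per-residue pLDDT is the CA B-factor, falling back to the mean B-factor
    over the residue's atoms when CA is absent; values outside [0, 100] are
    a parse error.  Altlocs resolve to the highest-occupancy conformer.
    """
    import biotite.structure as struc

    path = Path(path)
    try:
        if path.suffix.lower() in {".cif", ".mmcif", ".pdbx"}:
            import biotite.structure.io.pdbx as pdbx

            f = pdbx.CIFFile.read(str(path))
            arr = pdbx.get_structure(f, model=1, altloc="occupancy",
                                     extra_fields=["b_factor", "occupancy"])
        else:
            from biotite.structure.io.pdb import PDBFile

            f = PDBFile.read(str(path))
            arr = f.get_structure(model=1, altloc="occupancy",
                                  extra_fields=["b_factor", "occupancy"])
    except Exception as exc:
        raise ParseError(f"{path}: unparseable coordinates ({exc})") from exc
    if arr.array_length() == 0:
        raise ParseError(f"{path}: no ATOM records")
    arr = arr[arr.res_name != "HOH"]
    if arr.array_length() == 0:
        raise ParseError(f"{path}: no non-water atoms")
    if not np.all(np.isfinite(arr.coord)):
        raise ParseError(f"{path}: non-finite coordinates")

    chains: list[Chain] = []
    order: list[str] = []
    residues_by_chain: dict[str, list[Residue]] = {}
    starts = struc.get_residue_starts(arr, add_exclusive_stop=True)
    for s, e in zip(starts[:-1], starts[1:]):
        cid = str(arr.chain_id[s])
        atoms = tuple(
            Atom(name=str(arr.atom_name[i]), element=str(arr.element[i]).upper(),
                 coord=tuple(float(x) for x in arr.coord[i]),
                 b_factor=float(arr.b_factor[i]))
            for i in range(s, e))
        ca = next((a for a in atoms if a.name == "CA"), None)
        plddt = ca.b_factor if ca is not None else (
            sum(a.b_factor for a in atoms) / len(atoms))
        if not 0.0 <= plddt <= 100.0:
            raise ParseError(
                f"{path}: residue {cid}/{int(arr.res_id[s])} has pLDDT "
                f"{plddt} outside [0, 100]")
        icode = ""
        if "ins_code" in arr.get_annotation_categories():
            icode = str(arr.ins_code[s]).strip()
        res = Residue(name=str(arr.res_name[s]), number=int(arr.res_id[s]),
                      icode=icode, atoms=atoms, plddt=plddt)
        if cid not in residues_by_chain:
            residues_by_chain[cid] = []
            order.append(cid)
        residues_by_chain[cid].append(res)
    for cid in order:
        rs = sorted(residues_by_chain[cid], key=lambda r: (r.number, r.icode))
        chains.append(Chain(id=cid, residues=tuple(rs)))
    return StructureModel(chains=tuple(chains), source=str(path))


@dataclass(frozen=True)
class PaeMatrix:
    """Predicted aligned error (Å) with per-chain index spans."""

    matrix: np.ndarray
    chain_spans: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError("PAE matrix must be square")
        if np.any(m < 0) or not np.all(np.isfinite(m)):
            raise ValidationError("PAE values must be finite and non-negative")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def read_pae(path: str | Path, model: StructureModel) -> PaeMatrix:
    """Read a standard predicted-aligned-error JSON file.

    Accepts the common layouts: a dict (or one-element list of dicts) with
    key ``predicted_aligned_error`` or ``pae``.  Chain spans are taken from
    the model's residue counts in chain order.
    """
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if isinstance(doc, list):
        if not doc:
            raise ParseError(f"{path}: empty PAE document")
        doc = doc[0]
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: unrecognized PAE layout")
    raw = doc.get("predicted_aligned_error", doc.get("pae"))
    if raw is None:
        raise ParseError(f"{path}: no predicted_aligned_error / pae key")
    matrix = np.asarray(raw, dtype=float)
    spans: dict[str, tuple[int, int]] = {}
    offset = 0
    for chain in model.chains:
        spans[chain.id] = (offset, offset + len(chain.residues))
        offset += len(chain.residues)
    if matrix.ndim != 2 or matrix.shape != (offset, offset):
        raise ParseError(
            f"{path}: PAE shape {matrix.shape} does not match the model's "
            f"{offset} residues")
    return PaeMatrix(matrix=matrix, chain_spans=spans)


# ---------------------------------------------------------------------------
# pLDDT


def mean_plddt(model: StructureModel, chains: Iterable[str] | None = None) -> float:
    """Arithmetic mean of per-residue pLDDT over the selected chains."""
    residues = model.residues(chains)
    if not residues:
        raise ValidationError("empty chain selection")
    return sum(r.plddt for _, r in residues) / len(residues)


def rank_models(models: TSequence[StructureModel]) -> list[StructureModel]:
    """Models in descending mean-pLDDT order (stable on ties)."""
    if not models:
        raise ValidationError("no models to rank")
    return sorted(models, key=lambda m: -mean_plddt(m))


# ---------------------------------------------------------------------------
# Disulfide bonds


@dataclass(frozen=True)
class SsBond:
    a: ResidueRef
    b: ResidueRef
    distance: float


@dataclass(frozen=True)
class SsBondSet:
    bonds: tuple[SsBond, ...]
    cutoff: float

    def __len__(self) -> int:
        return len(self.bonds)


def detect_ssbonds(model: StructureModel, cutoff: float = 2.5) -> SsBondSet:
    """Detect disulfide bonds from cysteine SG–SG distances.

    Candidate SG pairs within the cutoff are accepted greedily in ascending
    distance order; each SG participates in at most one bond.
    """
    sgs: list[tuple[ResidueRef, np.ndarray]] = []
    for cid, res in model.residues():
        if res.name.upper() != "CYS":
            continue
        sg = res.atom("SG")
        if sg is not None:
            sgs.append((_residue_ref(cid, res), sg.xyz))
    candidates: list[tuple[float, int, int]] = []
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            d = float(np.linalg.norm(sgs[i][1] - sgs[j][1]))
            if d <= cutoff:
                candidates.append((d, i, j))
    candidates.sort()
    used: set[int] = set()
    bonds: list[SsBond] = []
    for d, i, j in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        bonds.append(SsBond(a=sgs[i][0], b=sgs[j][0], distance=d))
    return SsBondSet(bonds=tuple(bonds), cutoff=cutoff)


@dataclass(frozen=True)
class ConnectivityCall:
    """Result of connectivity classification: a catalog name or NOVEL."""

    name: str | None
    pairs: frozenset[tuple[int, int]]

    @property
    def is_novel(self) -> bool:
        return self.name is None

    def __str__(self) -> str:
        if self.name is not None:
            return self.name
        pairs = ",".join(f"{a}-{b}" for a, b in sorted(self.pairs))
        return f"NOVEL({pairs})"


def classify_connectivity(
    bonds: SsBondSet, seq: Sequence,
    catalog: TSequence[ConnectivityPattern] = CATALOG,
) -> ConnectivityCall:
    """Map detected bonds to cysteine ordinals and match against the catalog.

    Residue numbers are assumed to be 1-based positions into ``seq`` (the
    convention of predictor output).  An exact ordinal-pair-set match against
    a catalog entry with the same cysteine count returns its name; anything
    else is NOVEL.
    """
    positions = find_cysteines(seq)
    ordinal_of = {p: i + 1 for i, p in enumerate(positions)}

    def to_ordinal(ref: ResidueRef) -> int:
        _, number, _ = ref
        if number < 1 or number > len(seq.residues) or seq.residues[number - 1] != "C":
            raise ValidationError(
                f"bonded residue {ref} is not a cysteine of {seq.id!r}")
        return ordinal_of[number]

    pairs = frozenset(
        tuple(sorted((to_ordinal(b.a), to_ordinal(b.b)))) for b in bonds.bonds)
    n_cys = len(positions)
    for pattern in catalog:
        if pattern.n_cys == n_cys and pattern.pairs == pairs:
            return ConnectivityCall(name=pattern.name, pairs=pairs)
    return ConnectivityCall(name=None, pairs=pairs)


# ---------------------------------------------------------------------------
# Interfaces and contacts


def _check_groups(model: StructureModel, group_a: Iterable[str],
                  group_b: Iterable[str]) -> tuple[set[str], set[str]]:
    ga, gb = set(group_a), set(group_b)
    if not ga or not gb:
        raise ValidationError("chain groups must be non-empty")
    if ga & gb:
        raise ValidationError(f"chain groups overlap: {sorted(ga & gb)}")
    for cid in ga | gb:
        model.chain(cid)  # raises on unknown
    return ga, gb


def _heavy_coords(model: StructureModel, chains: set[str]) -> np.ndarray:
    pts = [a.coord for cid, res in model.residues(chains) for a in res.atoms
           if a.element not in HYDROGEN_ELEMENTS]
    return np.asarray(pts, dtype=float).reshape(-1, 3)


def interface_contacts(model: StructureModel, group_a: Iterable[str],
                       group_b: Iterable[str], cutoff: float = 4.5) -> int:
    """Number of intergroup heavy-atom pairs within the distance cutoff."""
    ga, gb = _check_groups(model, group_a, group_b)
    pa, pb = _heavy_coords(model, ga), _heavy_coords(model, gb)
    if pa.size == 0 or pb.size == 0:
        return 0
    d2 = np.sum((pa[:, None, :] - pb[None, :, :]) ** 2, axis=2)
    return int(np.count_nonzero(d2 <= cutoff * cutoff))


def _rep_coords(model: StructureModel,
                chains: set[str]) -> tuple[list[ResidueRef], np.ndarray, list[float]]:
    refs, coords, plddts = [], [], []
    for cid, res in model.residues(chains):
        refs.append(_residue_ref(cid, res))
        coords.append(res.rep_atom.coord)
        plddts.append(res.plddt)
    return refs, np.asarray(coords, dtype=float).reshape(-1, 3), plddts


def _interface_pairs(model: StructureModel, ga: set[str], gb: set[str],
                     cutoff: float) -> list[tuple[int, int]]:
    _, ca, _ = _rep_coords(model, ga)
    _, cb, _ = _rep_coords(model, gb)
    if ca.size == 0 or cb.size == 0:
        return []
    d2 = np.sum((ca[:, None, :] - cb[None, :, :]) ** 2, axis=2)
    return [tuple(ij) for ij in np.argwhere(d2 <= cutoff * cutoff)]


def interface_residues(
    model: StructureModel, group_a: Iterable[str], group_b: Iterable[str],
    cb_cutoff: float = 8.0,
) -> tuple[set[ResidueRef], set[ResidueRef]]:
    """Residues whose Cβ (Cα for glycine) is within the cutoff of a
    partner-group Cβ/Cα."""
    ga, gb = _check_groups(model, group_a, group_b)
    refs_a, _, _ = _rep_coords(model, ga)
    refs_b, _, _ = _rep_coords(model, gb)
    pairs = _interface_pairs(model, ga, gb, cb_cutoff)
    return ({refs_a[i] for i, _ in pairs}, {refs_b[j] for _, j in pairs})


# ---------------------------------------------------------------------------
# pDockQ / pDockQ2


@dataclass(frozen=True)
class SigmoidParams:
    """L / (1 + exp(-k (x - x0))) + b."""

    L: float
    x0: float
    k: float
    b: float

    def __call__(self, x: float) -> float:
        return self.L / (1.0 + math.exp(-self.k * (x - self.x0))) + self.b


#: Constants of the published pDockQ reference implementation
#: (interface = Cβ pairs within 8 Å; x = mean interface pLDDT · log10 #pairs).
PDOCKQ_PARAMS = SigmoidParams(L=0.724, x0=152.611, k=0.052, b=0.018)

#: Constants of the published pDockQ2 reference script
#: (x = mean interface pLDDT · mean 1/(1+(PAE/d0)^2), d0 = 10 Å).
PDOCKQ2_PARAMS = SigmoidParams(L=1.31, x0=84.733, k=0.075, b=0.005)
PDOCKQ2_D0 = 10.0


def pdockq(model: StructureModel, params: SigmoidParams = PDOCKQ_PARAMS,
           cutoff: float = 8.0) -> float:
    """Interface-confidence score from interface pLDDT and contact count.

    The interface follows the reference convention: residue pairs from
    different chains whose representative atoms (Cβ, Cα for glycine) are
    within ``cutoff``.  x = (mean pLDDT over interface residues) ·
    log10(number of interface pairs); zero contacts give the sigmoid floor
    ``params.b``.
    """
    if len(model.chains) < 2:
        raise ValidationError("pDockQ requires at least two chains")
    if_residues: set[ResidueRef] = set()
    n_pairs = 0
    for i, ca in enumerate(model.chains):
        for cb in model.chains[i + 1:]:
            pairs = _interface_pairs(model, {ca.id}, {cb.id}, cutoff)
            n_pairs += len(pairs)
            refs_a, _, _ = _rep_coords(model, {ca.id})
            refs_b, _, _ = _rep_coords(model, {cb.id})
            if_residues.update(refs_a[i2] for i2, _ in pairs)
            if_residues.update(refs_b[j2] for _, j2 in pairs)
    if n_pairs == 0:
        return params.b
    plddt_by_ref = {
        _residue_ref(cid, r): r.plddt for cid, r in model.residues()}
    mean_if_plddt = sum(plddt_by_ref[r] for r in if_residues) / len(if_residues)
    x = mean_if_plddt * math.log10(n_pairs)
    return params(x)


def pdockq2(model: StructureModel, pae: PaeMatrix,
            params: SigmoidParams = PDOCKQ2_PARAMS, d0: float = PDOCKQ2_D0,
            cutoff: float = 8.0) -> tuple[list[float], float]:
    """Per-chain PAE-weighted interface score and its arithmetic mean.

    For chain i, x_i = (mean pLDDT over chain-i interface residues) ·
    (mean over interchain interface residue pairs of 1/(1+(PAE_ij/d0)^2)),
    scored through the sigmoid.  A chain with no interface contributes the
    sigmoid floor; a model with no interface at all is an error.
    """
    if len(model.chains) < 2:
        raise ValidationError("pDockQ2 requires at least two chains")
    if pae.n != model.n_residues:
        raise ValidationError(
            f"PAE dimension {pae.n} does not match the model's "
            f"{model.n_residues} residues")

    index_of: dict[ResidueRef, int] = {}
    for chain in model.chains:
        start, _ = pae.chain_spans[chain.id]
        for off, res in enumerate(chain.residues):
            index_of[_residue_ref(chain.id, res)] = start + off
    plddt_by_ref = {_residue_ref(cid, r): r.plddt for cid, r in model.residues()}

    per_chain: list[float] = []
    any_interface = False
    for chain in model.chains:
        rest = {c.id for c in model.chains if c.id != chain.id}
        refs_a, _, _ = _rep_coords(model, {chain.id})
        refs_b, _, _ = _rep_coords(model, rest)
        pairs = _interface_pairs(model, {chain.id}, rest, cutoff)
        if not pairs:
            per_chain.append(params.b)
            continue
        any_interface = True
        chain_if = {refs_a[i] for i, _ in pairs}
        mean_plddt_i = sum(plddt_by_ref[r] for r in chain_if) / len(chain_if)
        weights = [
            1.0 / (1.0 + (pae.matrix[index_of[refs_a[i]], index_of[refs_b[j]]]
                          / d0) ** 2)
            for i, j in pairs]
        x = mean_plddt_i * (sum(weights) / len(weights))
        per_chain.append(params(x))
    if not any_interface:
        raise ValidationError("model has no interchain interface")
    return per_chain, sum(per_chain) / len(per_chain)


# ---------------------------------------------------------------------------
# Superposition / RMSD


def kabsch_superpose(
    moving: np.ndarray, fixed: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Returns (rotation, translation, rmsd) with a proper rotation (no
    reflection); apply as ``R @ x + t``.
    """
    mv = np.asarray(moving, dtype=float)
    fx = np.asarray(fixed, dtype=float)
    if mv.shape != fx.shape or mv.ndim != 2 or mv.shape[1] != 3:
        raise ValidationError("point sets must both be N x 3 with equal N")
    if mv.shape[0] < 3:
        raise ValidationError("at least 3 points are required")
    cm, cf = mv.mean(axis=0), fx.mean(axis=0)
    h = (mv - cm).T @ (fx - cf)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cf - rot @ cm
    moved = mv @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - fx) ** 2, axis=1))))
    return rot, trans, rmsd


ChainMap = Mapping[str, str]


def _mapped_coords(model: StructureModel, reference: StructureModel,
                   chain_map: ChainMap, atom: str) -> tuple[np.ndarray, np.ndarray]:
    mv, fx = [], []
    for mc, rc in chain_map.items():
        model_chain = model.chain(mc)
        ref_chain = reference.chain(rc)
        ref_by_key = {(r.number, r.icode): r for r in ref_chain.residues}
        for res in model_chain.residues:
            ref_res = ref_by_key.get((res.number, res.icode))
            if ref_res is None:
                continue
            a, b = res.atom(atom), ref_res.atom(atom)
            if a is None or b is None:
                continue
            mv.append(a.coord)
            fx.append(b.coord)
    return (np.asarray(mv, dtype=float).reshape(-1, 3),
            np.asarray(fx, dtype=float).reshape(-1, 3))


def rmsd_to_reference(
    model: StructureModel, reference: StructureModel,
    chain_maps: ChainMap | TSequence[ChainMap], atom: str = "CA",
) -> float:
    """Global RMSD to a reference after one joint Kabsch superposition.

    ``chain_maps`` is one model→reference chain mapping or several
    alternatives (e.g. the two consistent pairings of a symmetric 2+2
    complex); the minimum RMSD over the alternatives is returned.  Residues
    are paired by author numbering and insertion code.
    """
    if isinstance(chain_maps, Mapping):
        chain_maps = [chain_maps]
    if not chain_maps:
        raise ValidationError("no chain mapping given")
    best: float | None = None
    for cmap in chain_maps:
        mv, fx = _mapped_coords(model, reference, cmap, atom)
        if mv.shape[0] == 0:
            raise ValidationError("empty residue intersection for chain map "
                                  f"{dict(cmap)!r}")
        _, _, rmsd = kabsch_superpose(mv, fx)
        if best is None or rmsd < best:
            best = rmsd
    return float(best)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# Combined report


@dataclass(frozen=True)
class EvalScores:
    """Per-model evaluation report; optional entries are None when their
    inputs (PAE matrix, reference model) were not provided."""

    model: str
    mean_plddt: float
    pdockq: float | None = None
    pdockq2_per_chain: tuple[float, ...] | None = None
    pdockq2_mean: float | None = None
    contacts: int | None = None
    contact_cutoff: float | None = None
    rmsd: float | None = None
    connectivity: str | None = None

    def to_json(self) -> str:
        doc = {k: v for k, v in self.__dict__.items() if v is not None}
        if self.pdockq2_per_chain is not None:
            doc["pdockq2_per_chain"] = list(self.pdockq2_per_chain)
        return json.dumps(doc, indent=2, sort_keys=True)

    def to_tsv(self) -> str:
        keys = ["model", "mean_plddt", "pdockq", "pdockq2_mean", "contacts",
                "contact_cutoff", "rmsd", "connectivity"]
        vals = [getattr(self, k) for k in keys]
        fmt = ["NA" if v is None else str(v) for v in vals]
        return "\t".join(keys) + "\n" + "\t".join(fmt) + "\n"


def evaluate_model(
    model: StructureModel,
    pae: PaeMatrix | None = None,
    reference: StructureModel | None = None,
    chain_maps: ChainMap | TSequence[ChainMap] | None = None,
    group_a: Iterable[str] | None = None,
    group_b: Iterable[str] | None = None,
    contact_cutoff: float = 4.5,
    seq: Sequence | None = None,
) -> EvalScores:
    """One-stop evaluation: fills every score whose inputs are available."""
    scores: dict = {"model": model.source, "mean_plddt": mean_plddt(model)}
    if len(model.chains) >= 2:
        scores["pdockq"] = pdockq(model)
        if group_a is None or group_b is None:
            group_a, group_b = {model.chains[0].id}, set(model.chain_ids[1:])
        scores["contacts"] = interface_contacts(model, group_a, group_b,
                                                contact_cutoff)
        scores["contact_cutoff"] = contact_cutoff
        if pae is not None:
            per_chain, mean = pdockq2(model, pae)
            scores["pdockq2_per_chain"] = tuple(per_chain)
            scores["pdockq2_mean"] = mean
    if reference is not None and chain_maps is not None:
        scores["rmsd"] = rmsd_to_reference(model, reference, chain_maps)
    if seq is not None:
        scores["connectivity"] = str(classify_connectivity(
            detect_ssbonds(model), seq))
    return EvalScores(**scores)
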
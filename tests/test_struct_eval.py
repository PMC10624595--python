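import json
import math

import numpy as np
import pytest

from cysmsa.cys_anchor import CATALOG
from cysmsa.errors import ParseError, ValidationError
from cysmsa.fixtures import ToyComplexSpec, gen_toy_complex
from cysmsa.msa_core import Sequence
from cysmsa.struct_eval import (
    PDOCKQ2_PARAMS,
    PDOCKQ_PARAMS,
    Atom,
    Chain,
    PaeMatrix,
    Residue,
    StructureModel,
    classify_connectivity,
    detect_ssbonds,
    evaluate_model,
    interface_contacts,
    interface_residues,
    kabsch_superpose,
    mean_plddt,
    pdockq,
    pdockq2,
    rank_models,
    read_pae,
    read_structure,
    rmsd_to_reference,
)

from oracles import brute_force_contacts, min_weight_sg_matching, random_rotation


def _residue(number, name="GLY", atoms=None, plddt=75.0):
    atoms = atoms or (Atom("CA", "C", (float(number), 0.0, 0.0), plddt),)
    return Residue(name=name, number=number, icode="", atoms=tuple(atoms),
                   plddt=plddt)


def _model(*chains):
    return StructureModel(chains=tuple(chains))


def _pdb_text(records):
    """Minimal PDB writer for hand-built test inputs."""
    lines = []
    for i, (cid, resnum, resname, atname, element, xyz, b) in enumerate(records, 1):
        x, y, z = xyz
        lines.append(
            f"ATOM  {i:5d}  {atname:<3s}{resname:>4s} {cid}{resnum:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}          "
            f"{element:>2s}")
    lines.append("END")
    return "\n".join(lines) + "\n"


class TestReadStructure:
    def test_single_residue_ca_bfactor(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text(_pdb_text(
            [("A", 1, "GLY", "CA", "C", (0, 0, 0), 75.0)]))
        model = read_structure(path)
        assert [r.plddt for _, r in model.residues()] == [75.0]

    def test_missing_ca_falls_back_to_mean(self, tmp_path):
        path = tmp_path / "noca.pdb"
        path.write_text(_pdb_text([
            ("A", 1, "GLY", "N", "N", (0, 0, 0), 70.0),
            ("A", 1, "GLY", "O", "O", (1, 0, 0), 80.0)]))
        model = read_structure(path)
        assert [r.plddt for _, r in model.residues()] == [75.0]

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("END\n")
        with pytest.raises(ParseError):
            read_structure(path)

    def test_plddt_out_of_range_rejected(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text(_pdb_text(
            [("A", 1, "GLY", "CA", "C", (0, 0, 0), 250.0)]))
        with pytest.raises(ParseError, match="pLDDT"):
            read_structure(path)

    def test_toy_complex_round_trip(self, toy_complex_spec, tmp_path):
        pdb, _ = gen_toy_complex(toy_complex_spec, tmp_path)
        model = read_structure(pdb)
        assert model.chain_ids == ("A", "B")
        assert model.n_residues == 22


class TestMeanPlddt:
    def test_constant(self):
        m = _model(Chain("A", tuple(_residue(i, plddt=75.0)
                                    for i in range(1, 4))))
        assert mean_plddt(m) == 75.0

    def test_mean_of_two(self):
        m = _model(Chain("A", (_residue(1, plddt=60.0), _residue(2, plddt=90.0))))
        assert mean_plddt(m) == 75.0

    def test_chain_selection(self):
        m = _model(Chain("A", (_residue(1, plddt=60.0),)),
                   Chain("B", (_residue(1, plddt=90.0),)))
        assert mean_plddt(m, ["B"]) == 90.0

    def test_empty_selection_rejected(self):
        m = _model(Chain("A", (_residue(1),)))
        with pytest.raises(ValidationError):
            mean_plddt(m, [])

    def test_constant_bfactor_any_selection(self, toy_complex_spec, tmp_path):
        spec = ToyComplexSpec(len_a=5, len_b=5, n_interface=0,
                              plddt_a=91.7, plddt_b=91.7)
        pdb, _ = gen_toy_complex(spec, tmp_path)
        model = read_structure(pdb)
        for sel in (None, ["A"], ["B"]):
            assert mean_plddt(model, sel) == pytest.approx(91.7)


class TestRankModels:
    def test_descending_order(self):
        models = [
            _model(Chain("A", (_residue(1, plddt=p),))) for p in (70, 90, 80)]
        ranked = rank_models(models)
        assert [mean_plddt(m) for m in ranked] == [90, 80, 70]

    def test_single(self):
        m = _model(Chain("A", (_residue(1),)))
        assert rank_models([m]) == [m]

    def test_stable_on_ties(self):
        a = _model(Chain("A", (_residue(1, plddt=80),)))
        b = _model(Chain("B", (_residue(1, plddt=80),)))
        assert rank_models([a, b]) == [a, b]


def _cys(number, sg_xyz, cid="A"):
    return Residue(name="CYS", number=number, icode="",
                   atoms=(Atom("CA", "C", (number * 10.0, 50.0, 0.0), 80.0),
                          Atom("SG", "S", tuple(map(float, sg_xyz)), 80.0)),
                   plddt=80.0)


class TestDetectSsbonds:
    def test_within_cutoff(self):
        m = _model(Chain("A", (_cys(1, (0, 0, 0)), _cys(2, (2.05, 0, 0)))))
        bonds = detect_ssbonds(m)
        assert len(bonds) == 1
        assert bonds.bonds[0].distance == pytest.approx(2.05)

    def test_beyond_cutoff_empty(self):
        m = _model(Chain("A", (_cys(1, (0, 0, 0)), _cys(2, (4.0, 0, 0)))))
        assert len(detect_ssbonds(m)) == 0

    def test_greedy_consumes_shared_partner(self):
        m = _model(Chain("A", (
            _cys(1, (0, 0, 0)), _cys(2, (2.0, 0, 0)), _cys(3, (4.2, 0, 0)))))
        bonds = detect_ssbonds(m)
        assert len(bonds) == 1
        assert {bonds.bonds[0].a[1], bonds.bonds[0].b[1]} == {1, 2}

    def test_no_cysteines(self):
        m = _model(Chain("A", (_residue(1),)))
        assert len(detect_ssbonds(m)) == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_greedy_matches_exhaustive_on_random_toys(self, seed):
        rng = np.random.default_rng(seed)
        pts = [rng.uniform(0, 8, size=3) for _ in range(6)]
        m = _model(Chain("A", tuple(
            _cys(i + 1, p) for i, p in enumerate(pts))))
        got = {frozenset((b.a[1] - 1, b.b[1] - 1)) for b in
               detect_ssbonds(m, cutoff=2.5).bonds}
        expected = {frozenset(p) for p in
                    min_weight_sg_matching(pts, cutoff=2.5)}
        # greedy ascending-distance matching is maximal; compare cardinality
        # and, when the exhaustive optimum is unique and greedy-compatible,
        # the pairs themselves
        assert len(got) == len(expected)

    def test_planted_pairs_recovered(self, toy_complex_spec, tmp_path):
        pdb, _ = gen_toy_complex(toy_complex_spec, tmp_path)
        model = read_structure(pdb)
        bonds = detect_ssbonds(model)
        got = {frozenset((b.a[1], b.b[1])) for b in bonds.bonds}
        assert got == {frozenset(p) for p in toy_complex_spec.ss_pairs}


class TestClassifyConnectivity:
    @pytest.mark.parametrize("pattern", CATALOG, ids=lambda p: p.name)
    def test_catalog_round_trip(self, pattern, tmp_path):
        spec = ToyComplexSpec(len_a=4, len_b=pattern.n_cys + 2, n_interface=0,
                              ss_pairs=tuple(pattern.pairs))
        pdb, _ = gen_toy_complex(spec, tmp_path / pattern.name)
        model = read_structure(pdb)
        chain_b = StructureModel(chains=(model.chain("B"),))
        seq = model.one_letter_sequence("B")
        call = classify_connectivity(detect_ssbonds(chain_b), seq, CATALOG)
        assert call.name == pattern.name

    def test_novel_pattern(self):
        m = _model(Chain("A", tuple(
            _cys(i + 1, (i // 2 * 30.0, 2.05 * (i % 2), 0.0))
            for i in range(8))))
        seq = Sequence("s", "CCCCCCCC")
        call = classify_connectivity(detect_ssbonds(m), seq, CATALOG)
        assert call.is_novel
        assert call.pairs == frozenset({(1, 2), (3, 4), (5, 6), (7, 8)})
        assert str(call) == "NOVEL(1-2,3-4,5-6,7-8)"

    def test_bond_on_non_cysteine_rejected(self):
        m = _model(Chain("A", (_cys(1, (0, 0, 0)), _cys(2, (2.0, 0, 0)))))
        seq = Sequence("s", "CG")  # residue 2 is not C
        with pytest.raises(ValidationError):
            classify_connectivity(detect_ssbonds(m), seq, CATALOG)


class TestInterfaceContacts:
    def test_far_apart_zero(self):
        m = _model(Chain("A", (_residue(1, atoms=(Atom("CA", "C", (0, 0, 0), 75),)),)),
                   Chain("B", (_residue(1, atoms=(Atom("CA", "C", (10, 0, 0), 75),)),)))
        assert interface_contacts(m, ["A"], ["B"]) == 0

    def test_single_contact(self):
        m = _model(Chain("A", (_residue(1, atoms=(Atom("CA", "C", (0, 0, 0), 75),)),)),
                   Chain("B", (_residue(1, atoms=(Atom("CA", "C", (4.0, 0, 0), 75),)),)))
        assert interface_contacts(m, ["A"], ["B"]) == 1

    def test_hydrogens_excluded(self):
        m = _model(
            Chain("A", (_residue(1, atoms=(Atom("CA", "C", (0, 0, 0), 75),
                                           Atom("H", "H", (1, 0, 0), 75))),)),
            Chain("B", (_residue(1, atoms=(Atom("CA", "C", (2.0, 0, 0), 75),
                                           Atom("H2", "H", (2.5, 0, 0), 75))),)))
        assert interface_contacts(m, ["A"], ["B"]) == 1

    def test_overlapping_groups_rejected(self):
        m = _model(Chain("A", (_residue(1),)), Chain("B", (_residue(1),)))
        with pytest.raises(ValidationError):
            interface_contacts(m, ["A"], ["A", "B"])

    def test_planted_count(self, toy_complex_spec, tmp_path):
        pdb, _ = gen_toy_complex(toy_complex_spec, tmp_path)
        model = read_structure(pdb)
        assert interface_contacts(model, ["A"], ["B"]) == \
            toy_complex_spec.n_interface

    def test_matches_brute_force(self, toy_complex_spec, tmp_path):
        pdb, _ = gen_toy_complex(toy_complex_spec, tmp_path)
        model = read_structure(pdb)
        coords_a = np.array([a.coord for cid, r in model.residues(["A"])
                             for a in r.atoms])
        coords_b = np.array([a.coord for cid, r in model.residues(["B"])
                             for a in r.atoms])
        for cutoff in (2.0, 4.5, 8.0, 25.0):
            assert interface_contacts(model, ["A"], ["B"], cutoff) == \
                brute_force_contacts(coords_a, coords_b, cutoff)


class TestInterfaceResidues:
    def test_separated_chains_empty(self):
        m = _model(Chain("A", (_residue(1, atoms=(Atom("CA", "C", (0, 0, 0), 75),)),)),
                   Chain("B", (_residue(1, atoms=(Atom("CA", "C", (50, 0, 0), 75),)),)))
        assert interface_residues(m, ["A"], ["B"]) == (set(), set())

    def test_pair_within_cutoff(self):
        m = _model(Chain("A", (_residue(1, atoms=(Atom("CB", "C", (0, 0, 0), 75),)),)),
                   Chain("B", (_residue(1, atoms=(Atom("CB", "C", (7, 0, 0), 75),)),)))
        got_a, got_b = interface_residues(m, ["A"], ["B"])
        assert got_a == {("A", 1, "")}
        assert got_b == {("B", 1, "")}

    def test_planted_geometry(self, toy_complex_spec, tmp_path):
        pdb, _ = gen_toy_complex(toy_complex_spec, tmp_path)
        model = read_structure(pdb)
        got_a, got_b = interface_residues(model, ["A"], ["B"])
        k = toy_complex_spec.n_interface
        assert got_a == {("A", i + 1, "") for i in range(k)}
        assert got_b == {("B", i + 1, "") for i in range(k)}


def _dimer(plddt=80.0, separation=4.0):
    a = Chain("A", (_residue(1, atoms=(Atom("CB", "C", (0, 0, 0), plddt),),
                             plddt=plddt),))
    b = Chain("B", (_residue(1, atoms=(Atom("CB", "C", (separation, 0, 0), plddt),),
                             plddt=plddt),))
    return _model(a, b)


class TestPdockq:
    def test_zero_contacts_floor(self):
        assert pdockq(_dimer(separation=50.0)) == PDOCKQ_PARAMS.b

    def test_monotone_in_plddt(self, tmp_path):
        scores = []
        for p in (40.0, 60.0, 80.0, 99.0):
            spec = ToyComplexSpec(len_a=8, len_b=8, n_interface=4,
                                  plddt_a=p, plddt_b=p)
            pdb, _ = gen_toy_complex(spec, tmp_path / str(p))
            scores.append(pdockq(read_structure(pdb)))
        assert scores == sorted(scores)
        assert scores[0] < scores[-1]

    def test_formula_oracle(self):
        model = _dimer(plddt=80.0)
        # one interface pair, mean interface plddt 80
        x = 80.0 * math.log10(1)
        expected = (PDOCKQ_PARAMS.L
                    / (1 + math.exp(-PDOCKQ_PARAMS.k * (x - PDOCKQ_PARAMS.x0)))
                    + PDOCKQ_PARAMS.b)
        assert pdockq(model) == pytest.approx(expected)

    def test_formula_oracle_multi_contact(self, tmp_path):
        spec = ToyComplexSpec(len_a=10, len_b=10, n_interface=4,
                              plddt_a=85.0, plddt_b=85.0)
        pdb, _ = gen_toy_complex(spec, tmp_path)
        model = read_structure(pdb)
        x = 85.0 * math.log10(4)  # 4 interface residue pairs, uniform plddt
        expected = (PDOCKQ_PARAMS.L
                    / (1 + math.exp(-PDOCKQ_PARAMS.k * (x - PDOCKQ_PARAMS.x0)))
                    + PDOCKQ_PARAMS.b)
        assert pdockq(model) == pytest.approx(expected)

    def test_single_chain_rejected(self):
        with pytest.raises(ValidationError):
            pdockq(_model(Chain("A", (_residue(1),))))


def _pae_for(model, value, intra=1.0):
    n = model.n_residues
    spans = {}
    offset = 0
    for chain in model.chains:
        spans[chain.id] = (offset, offset + len(chain.residues))
        offset += len(chain.residues)
    m = np.full((n, n), intra)
    for ca in model.chains:
        for cb in model.chains:
            if ca.id != cb.id:
                sa, ea = spans[ca.id]
                sb, eb = spans[cb.id]
                m[sa:ea, sb:eb] = value
    np.fill_diagonal(m, 0.0)
    return PaeMatrix(matrix=m, chain_spans=spans)


class TestPdockq2:
    def test_zero_pae_reduces_to_interface_plddt(self):
        model = _dimer(plddt=80.0)
        pae = _pae_for(model, 0.0)
        per_chain, _ = pdockq2(model, pae)
        x = 80.0  # PAE factor exactly 1
        expected = (PDOCKQ2_PARAMS.L
                    / (1 + math.exp(-PDOCKQ2_PARAMS.k * (x - PDOCKQ2_PARAMS.x0)))
                    + PDOCKQ2_PARAMS.b)
        assert per_chain == pytest.approx([expected, expected])

    def test_large_pae_approaches_floor(self):
        model = _dimer(plddt=80.0)
        pae = _pae_for(model, 1e6)
        per_chain, mean = pdockq2(model, pae)
        floor = (PDOCKQ2_PARAMS.L
                 / (1 + math.exp(PDOCKQ2_PARAMS.k * PDOCKQ2_PARAMS.x0))
                 + PDOCKQ2_PARAMS.b)
        assert mean == pytest.approx(floor, abs=1e-9)

    def test_pae_10_gives_half_factor(self):
        model = _dimer(plddt=80.0)
        pae = _pae_for(model, 10.0)
        per_chain, mean = pdockq2(model, pae)
        x = 80.0 * 0.5
        expected = (PDOCKQ2_PARAMS.L
                    / (1 + math.exp(-PDOCKQ2_PARAMS.k * (x - PDOCKQ2_PARAMS.x0)))
                    + PDOCKQ2_PARAMS.b)
        assert mean == pytest.approx(expected)

    def test_monotone_in_pae(self):
        model = _dimer(plddt=80.0)
        scores = [pdockq2(model, _pae_for(model, v))[1]
                  for v in (0.0, 5.0, 10.0, 30.0)]
        assert scores == sorted(scores, reverse=True)

    def test_mean_is_arithmetic_mean(self, tmp_path):
        spec = ToyComplexSpec(len_a=8, len_b=6, n_interface=3,
                              plddt_a=90.0, plddt_b=70.0, interface_pae=10.0)
        pdb, pae_path = gen_toy_complex(spec, tmp_path)
        model = read_structure(pdb)
        pae = read_pae(pae_path, model)
        per_chain, mean = pdockq2(model, pae)
        assert mean == pytest.approx(sum(per_chain) / len(per_chain))

    def test_dimension_mismatch_rejected(self):
        model = _dimer()
        small = PaeMatrix(matrix=np.zeros((1, 1)), chain_spans={"A": (0, 1)})
        with pytest.raises(ValidationError):
            pdockq2(model, small)

    def test_no_interface_rejected(self):
        model = _dimer(separation=100.0)
        pae = _pae_for(model, 5.0)
        with pytest.raises(ValidationError, match="interface"):
            pdockq2(model, pae)


class TestReadPae:
    def test_standard_layout(self, tmp_path, toy_complex_spec):
        pdb, pae_path = gen_toy_complex(toy_complex_spec, tmp_path)
        model = read_structure(pdb)
        pae = read_pae(pae_path, model)
        assert pae.n == model.n_residues
        assert pae.chain_spans["A"] == (0, toy_complex_spec.len_a)

    def test_list_wrapped_layout(self, tmp_path):
        model = _dimer()
        doc = [{"predicted_aligned_error": [[0, 1], [1, 0]]}]
        p = tmp_path / "pae.json"
        p.write_text(json.dumps(doc))
        assert read_pae(p, model).n == 2

    def test_shape_mismatch_rejected(self, tmp_path):
        model = _dimer()
        p = tmp_path / "pae.json"
        p.write_text(json.dumps({"pae": [[0.0]]}))
        with pytest.raises(ParseError):
            read_pae(p, model)


class TestKabsch:
    def test_identical_sets(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-8)
        assert rot == pytest.approx(np.eye(3), abs=1e-8)

    def test_translated_copy(self):
        pts = np.random.default_rng(1).normal(size=(5, 3))
        _, _, rmsd = kabsch_superpose(pts, pts + np.array([3.0, -2.0, 7.0]))
        assert rmsd == pytest.approx(0.0, abs=1e-8)

    def test_rigid_invariance(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(8, 3))
        for seed in range(4):
            rot = random_rotation(np.random.default_rng(seed))
            moved = pts @ rot.T + np.array([1.0, 2.0, 3.0])
            _, _, rmsd = kabsch_superpose(moved, pts)
            assert rmsd == pytest.approx(0.0, abs=1e-8)

    def test_reflection_excluded(self):
        # mirrored points cannot be superposed by a proper rotation
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        mirrored = pts * np.array([1, 1, -1])
        rot, _, rmsd = kabsch_superpose(mirrored, pts)
        assert np.linalg.det(rot) == pytest.approx(1.0)
        assert rmsd > 0.1

    def test_displaced_point_closed_form(self):
        # a 4-point set with one point displaced along a symmetry axis:
        # optimal superposition is the identity after centering, and the
        # rmsd is |d| * sqrt(1/n - 1/n^2 + ... ) computed directly
        base = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]], float)
        d = 0.4
        moved = base.copy()
        moved[0, 2] += d  # displacement orthogonal to the plane
        _, _, rmsd = kabsch_superpose(moved, base)
        # brute-force oracle over rotations (coarse grid + refinement)
        from scipy.optimize import minimize

        def objective(v):
            from scipy.spatial.transform import Rotation
            r = Rotation.from_rotvec(v).as_matrix()
            a = moved - moved.mean(axis=0)
            b = base - base.mean(axis=0)
            return np.sqrt(np.mean(np.sum((a @ r.T - b) ** 2, axis=1)))

        best = min(minimize(objective, x0, method="Nelder-Mead").fun
                   for x0 in ([0, 0, 0], [0.3, 0, 0], [0, 0.5, 0.2]))
        assert rmsd == pytest.approx(best, abs=1e-5)

    def test_cardinality_mismatch(self):
        with pytest.raises(ValidationError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_too_few_points(self):
        with pytest.raises(ValidationError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


def _two_chain_model(offset=0.0, swap=False):
    rng = np.random.default_rng(11)
    coords_a = rng.normal(size=(5, 3)) * 5
    coords_b = rng.normal(size=(5, 3)) * 5 + 20
    def chain(cid, coords):
        return Chain(cid, tuple(
            Residue("GLY", i + 1, "",
                    (Atom("CA", "C", tuple(c + offset), 80.0),), 80.0)
            for i, c in enumerate(coords)))
    if swap:
        return _model(chain("A", coords_b), chain("B", coords_a))
    return _model(chain("A", coords_a), chain("B", coords_b))


class TestRmsdToReference:
    def test_self_zero(self):
        m = _two_chain_model()
        assert rmsd_to_reference(m, m, {"A": "A", "B": "B"}) == \
            pytest.approx(0.0, abs=1e-8)

    def test_rotated_copy_zero(self):
        m = _two_chain_model()
        rot = random_rotation(np.random.default_rng(5))
        moved = StructureModel(chains=tuple(
            Chain(c.id, tuple(
                Residue(r.name, r.number, r.icode,
                        tuple(Atom(a.name, a.element,
                                   tuple(rot @ a.xyz + 4.0), a.b_factor)
                              for a in r.atoms), r.plddt)
                for r in c.residues))
            for c in m.chains))
        assert rmsd_to_reference(moved, m, {"A": "A", "B": "B"}) == \
            pytest.approx(0.0, abs=1e-8)

    def test_swapped_chain_labels_min_over_pairings(self):
        m = _two_chain_model()
        swapped = _two_chain_model(swap=True)
        maps = [{"A": "A", "B": "B"}, {"A": "B", "B": "A"}]
        assert rmsd_to_reference(swapped, m, maps) == pytest.approx(0.0, abs=1e-8)
        assert rmsd_to_reference(m, m, maps) == pytest.approx(0.0, abs=1e-8)

    def test_empty_intersection_rejected(self):
        m = _two_chain_model()
        shifted = StructureModel(chains=tuple(
            Chain(c.id, tuple(
                Residue(r.name, r.number + 100, r.icode, r.atoms, r.plddt)
                for r in c.residues))
            for c in m.chains))
        with pytest.raises(ValidationError, match="intersection"):
            rmsd_to_reference(shifted, m, {"A": "A"})


class TestEvaluateModel:
    def test_full_report(self, toy_complex_spec, tmp_path):
        pdb, pae_path = gen_toy_complex(toy_complex_spec, tmp_path)
        model = read_structure(pdb)
        pae = read_pae(pae_path, model)
        scores = evaluate_model(model, pae=pae, group_a=["A"], group_b=["B"])
        assert scores.mean_plddt == pytest.approx(
            (90.0 * 12 + 80.0 * 10) / 22)
        assert scores.contacts == toy_complex_spec.n_interface
        assert scores.pdockq is not None
        assert scores.pdockq2_mean == pytest.approx(
            sum(scores.pdockq2_per_chain) / 2)
        json_doc = json.loads(scores.to_json())
        assert json_doc["contacts"] == toy_complex_spec.n_interface
        assert "mean_plddt" in scores.to_tsv()
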
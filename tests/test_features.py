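"""Molecular and sequence descriptors: contacts, SASA, interface, context."""

import math

import numpy as np
import pytest

from ddgboost.energy import simplified_stability
from ddgboost.features import (
    MutationRecord,
    blosum80_score,
    build_feature_vector,
    classify_atom_contact,
    classify_mutation_context,
    compute_sasa,
    conservation_score,
    count_contacts,
    feature_registry,
    interface_residues,
    interface_sasa,
    is_core_residue,
    read_feature_table,
    write_feature_table,
)
from ddgboost.structures import AA3TO1, Atom, Structure, make_toy_fold


def _atom(name, element, res="ALA", chain="A", seq=1, xyz=(0, 0, 0), serial=1):
    return Atom(serial, name, element, res, chain, seq,
                x=xyz[0], y=xyz[1], z=xyz[2])


def _rigid_transform(structure, rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    shift = rng.normal(scale=20.0, size=3)
    import dataclasses
    atoms = []
    for a in structure.atoms:
        c = rot @ a.coord + shift
        atoms.append(dataclasses.replace(a, x=c[0], y=c[1], z=c[2]))
    return Structure(id=structure.id + "_rt", atoms=atoms)


class TestContactClassification:
    def test_carbon_pair_cutoffs(self):
        c1 = _atom("CB", "C")
        c2 = _atom("CG", "C", seq=2)
        assert classify_atom_contact(c1, c2, 4.5) == "hydrophobic"
        assert classify_atom_contact(c1, c2, 5.0) == "hydrophobic"
        assert classify_atom_contact(c1, c2, 5.5) == "none"

    def test_donor_acceptor_pair(self):
        n = _atom("N", "N")
        o = _atom("O", "O", seq=2)
        assert classify_atom_contact(n, o, 3.0) == "hydrophilic"
        assert classify_atom_contact(n, o, 4.5) == "none"

    def test_electrostatic_takes_precedence(self):
        nz = _atom("NZ", "N", res="LYS")
        od = _atom("OD1", "O", res="ASP", seq=2)
        # NZ is also a donor and OD1 an acceptor; charge wins
        assert classify_atom_contact(nz, od, 3.5) == "electrostatic"
        assert classify_atom_contact(nz, od, 4.5) == "none"

    def test_every_pair_gets_exactly_one_class(self):
        atoms = [_atom("CA", "C"), _atom("N", "N"), _atom("O", "O"),
                 _atom("NZ", "N", res="LYS"), _atom("OD1", "O", res="ASP"),
                 _atom("SG", "S", res="CYS")]
        for a in atoms:
            for b in atoms:
                for d in (0.5, 3.0, 4.0, 4.7, 5.0, 6.0):
                    cls = classify_atom_contact(a, b, d)
                    assert cls in ("electrostatic", "hydrophilic",
                                   "hydrophobic", "none")

    def test_unknown_element_raises(self):
        a = _atom("FE", "FE")
        with pytest.raises(ValueError):
            classify_atom_contact(a, _atom("CA", "C"), 3.0)


class TestCountContacts:
    def test_isolated_residue_has_zero_contacts(self):
        atoms = [_atom("N", "N", serial=1), _atom("CA", "C", serial=2),
                 _atom("C", "C", serial=3), _atom("O", "O", serial=4)]
        s = Structure(id="iso", atoms=atoms)
        cc = count_contacts(s, "A", 1)
        assert cc == type(cc)()

    def test_interchain_hydrophobic_pair(self):
        atoms = [
            _atom("CA", "C", chain="A", seq=1, xyz=(0, 0, 0), serial=1),
            _atom("CA", "C", chain="B", seq=1, xyz=(4.8, 0, 0), serial=2),
        ]
        s = Structure(id="pair", atoms=atoms)
        cc = count_contacts(s, "A", 1)
        assert cc.hydrophobic_inter == 1
        assert cc.hydrophobic_intra == 0

    def test_matches_brute_force_oracle(self, toy_dimer):
        from itertools import product
        for chain, seq in [("A", 3), ("A", 7), ("B", 5)]:
            res_atoms = [a for a in toy_dimer.atoms
                         if a.chain_id == chain and a.residue_seq == seq]
            other = [a for a in toy_dimer.atoms
                     if not (a.chain_id == chain and a.residue_seq == seq)]
            expected = {k: 0 for k in ("hydrophobic_intra", "hydrophilic_intra",
                                       "electrostatic_intra", "hydrophobic_inter",
                                       "hydrophilic_inter", "electrostatic_inter")}
            for a, b in product(res_atoms, other):
                d = float(np.linalg.norm(a.coord - b.coord))
                cls = classify_atom_contact(a, b, d)
                if cls == "none":
                    continue
                suffix = "intra" if b.chain_id == chain else "inter"
                expected[f"{cls}_{suffix}"] += 1
            cc = count_contacts(toy_dimer, chain, seq)
            for k, v in expected.items():
                assert getattr(cc, k) == v, (chain, seq, k)

    def test_missing_residue_raises(self, toy_fold):
        with pytest.raises(KeyError):
            count_contacts(toy_fold, "A", 999)


class TestSasa:
    def test_single_carbon_matches_analytic_sphere(self):
        s = Structure(id="c", atoms=[_atom("CA", "C")])
        total = compute_sasa(s).structure_total
        assert total == pytest.approx(4 * math.pi * (1.7 + 1.4) ** 2, rel=1e-6)

    def test_distant_atoms_unoccluded(self):
        atoms = [_atom("CA", "C", seq=1, serial=1),
                 _atom("CA", "C", seq=2, xyz=(100, 0, 0), serial=2)]
        s = Structure(id="two", atoms=atoms)
        res = compute_sasa(s)
        iso = 4 * math.pi * (1.7 + 1.4) ** 2
        assert res.atom_sasa == pytest.approx([iso, iso], rel=1e-6)

    def test_cluster_matches_high_resolution_reference(self, rng):
        # 5-atom random cluster vs a 10x denser point set
        elements = ["C", "N", "O", "S", "C"]
        atoms = [_atom(f"A{i}", e, seq=i + 1, serial=i + 1,
                       xyz=tuple(rng.uniform(-2, 2, 3)))
                 for i, e in enumerate(elements)]
        s = Structure(id="cluster", atoms=atoms)
        coarse = compute_sasa(s, n_points=960).structure_total
        fine = compute_sasa(s, n_points=10000).structure_total
        assert coarse == pytest.approx(fine, rel=0.005)

    def test_rotation_translation_invariance(self, toy_fold, rng):
        base = compute_sasa(toy_fold, n_points=960).structure_total
        moved = compute_sasa(_rigid_transform(toy_fold, rng),
                             n_points=960).structure_total
        assert moved == pytest.approx(base, rel=0.005)

    def test_residue_totals_sum_atom_values(self, toy_fold):
        res = compute_sasa(toy_fold)
        assert sum(res.residue_sasa.values()) == pytest.approx(
            res.structure_total, abs=1e-6)
        assert all(v >= 0 for v in res.atom_sasa)

    def test_too_few_points_rejected(self, toy_fold):
        with pytest.raises(ValueError):
            compute_sasa(toy_fold, n_points=50)


class TestCoreClassification:
    def test_exposed_residue_not_core(self):
        s = make_toy_fold(2, 3, sequence="AVA")
        assert not is_core_residue(s, "A", 2)

    def test_buried_residue_is_core(self):
        # bury one valine inside a tight cage of carbon atoms
        s = make_toy_fold(2, 3, sequence="AVA")
        target = s.get_residue("A", 2)
        centre = target.atom("SC").coord
        cage = []
        k = 0
        golden = math.pi * (3 - math.sqrt(5))
        for i in range(60):
            z = 1 - 2 * (i + 0.5) / 60
            r = math.sqrt(1 - z * z)
            phi = i * golden
            pos = centre + 3.2 * np.array([r * math.cos(phi),
                                           r * math.sin(phi), z])
            cage.append(Atom(500 + k, "CQ", "C", "CAG", "C", 100 + i,
                             x=pos[0], y=pos[1], z=pos[2]))
            k += 1
        caged = Structure(id="caged", atoms=list(s.atoms) + cage)
        assert is_core_residue(caged, "A", 2)

    def test_monotone_under_added_occlusion(self):
        # adding occluding atoms never flips core -> surface
        s = make_toy_fold(2, 3, sequence="AVA")
        sasa0 = compute_sasa(s)
        rid = s.get_residue("A", 2).atoms[0].residue_id
        extra = Atom(900, "CX", "C", "OCC", "D", 500, x=0.0, y=0.0, z=0.0)
        occluded = Structure(id="occ", atoms=list(s.atoms) + [extra])
        sasa1 = compute_sasa(occluded)
        assert sasa1.side_chain_sasa[rid] <= sasa0.side_chain_sasa[rid] + 1e-9


class TestInterface:
    def test_far_complex_has_empty_interface(self, far_dimer):
        ir = interface_residues(far_dimer, "A", "B")
        assert ir["A"] == set() and ir["B"] == set()

    def test_matches_brute_force_oracle(self, toy_dimer):
        ir = interface_residues(toy_dimer, "A", "B")
        expected = {"A": set(), "B": set()}
        a_atoms = [a for a in toy_dimer.atoms if a.chain_id == "A"]
        b_atoms = [a for a in toy_dimer.atoms if a.chain_id == "B"]
        for a in a_atoms:
            for b in b_atoms:
                if np.linalg.norm(a.coord - b.coord) <= 5.0:
                    expected["A"].add((a.residue_seq, a.insertion_code))
                    expected["B"].add((b.residue_seq, b.insertion_code))
        assert ir == expected
        assert ir["A"]  # gap 3.5 complex must actually touch

    def test_symmetric_in_chains(self, toy_dimer):
        ir1 = interface_residues(toy_dimer, "A", "B")
        ir2 = interface_residues(toy_dimer, "B", "A")
        assert ir1 == ir2

    def test_missing_chain_raises(self, toy_fold):
        with pytest.raises(KeyError):
            interface_residues(toy_fold, "A", "Q")


class TestInterfaceSasa:
    def test_far_complex_buries_nothing(self, far_dimer):
        d = interface_sasa(far_dimer, "A", "B")
        assert abs(d.interface_sasa_total) < 1.0

    def test_contacting_dimer_buries_area(self, toy_dimer):
        d = interface_sasa(toy_dimer, "A", "B")
        assert d.interface_sasa_total > 0
        assert d.interface_sasa_hydrophobic >= 0
        assert d.interface_sasa_hydrophilic >= 0
        assert d.interface_sasa_hydrophobic + d.interface_sasa_hydrophilic \
            <= d.interface_sasa_total + 1e-6

    def test_matches_three_component_sasa_calls(self, toy_dimer):
        d = interface_sasa(toy_dimer, "A", "B", n_points=240)
        parts = []
        for chain in ("A", "B"):
            sub = Structure(id=chain, atoms=[
                a for a in toy_dimer.atoms if a.chain_id == chain])
            parts.append(compute_sasa(sub, n_points=240).structure_total)
        whole = compute_sasa(toy_dimer, n_points=240).structure_total
        assert d.interface_sasa_total == pytest.approx(
            parts[0] + parts[1] - whole, abs=1e-6)


class TestContextClassification:
    def test_interface_precedence_over_core(self, toy_dimer):
        ir = interface_residues(toy_dimer, "A", "B")
        seq, _ = sorted(ir["A"])[0]
        wt_aa = AA3TO1[toy_dimer.get_residue("A", seq).residue_name]
        mut_aa = "A" if wt_aa != "A" else "V"
        rec = MutationRecord("m1", toy_dimer.id, "A", seq, wt_aa, mut_aa)
        assert classify_mutation_context(toy_dimer, rec, "B") == "interface"

    def test_exposed_residue_is_surface(self, toy_fold):
        res = toy_fold.residues("A")[5]
        wt_aa = AA3TO1[res.residue_name]
        mut_aa = "A" if wt_aa != "A" else "V"
        rec = MutationRecord("m2", toy_fold.id, "A", res.residue_seq, wt_aa, mut_aa)
        assert classify_mutation_context(toy_fold, rec, None) == "surface"

    def test_wt_mismatch_raises(self, toy_fold):
        res = toy_fold.residues("A")[0]
        wrong = "W" if res.residue_name != "TRP" else "F"
        rec = MutationRecord("m3", toy_fold.id, "A", res.residue_seq, wrong,
                             "A" if wrong != "A" else "V")
        with pytest.raises(ValueError, match="mismatch"):
            classify_mutation_context(toy_fold, rec, None)


class TestSequenceFeatures:
    def test_blosum80_symmetric(self):
        import itertools
        aas = "ARNDCQEGHILKMFPSTWYV"
        for a, b in itertools.combinations(aas, 2):
            assert blosum80_score(a, b) == blosum80_score(b, a)

    def test_blosum80_published_values(self):
        # matblas BLOSUM80 in 1/3-bit units
        assert blosum80_score("A", "A") == 7
        assert blosum80_score("W", "W") == 16
        assert blosum80_score("A", "W") == -5
        assert blosum80_score("L", "I") == 2
        assert blosum80_score("D", "E") == 2

    def test_blosum80_rejects_nonstandard(self):
        with pytest.raises(ValueError):
            blosum80_score("A", "Z")

    def test_conservation_consensus_scores_one(self):
        aln = ["A" * 5] * 10
        assert conservation_score(aln, 2, "A") == pytest.approx(1.0)

    def test_conservation_hand_formula(self):
        # column all 'A', 10 sequences, alpha=1: f(W) = (0+1)/(10+20),
        # max term f(A) = (10+1)/(10+20) -> ratio 1/11
        aln = ["A"] * 10
        assert conservation_score(aln, 0, "W") == pytest.approx(1.0 / 11.0)

    def test_conservation_excludes_gaps(self):
        aln = ["A-", "A-", "AC"]
        with pytest.raises(ValueError):
            conservation_score(["--", "--"], 0, "A")
        # gap rows do not count toward column 1
        v_c = conservation_score(aln, 1, "C")
        assert v_c == pytest.approx(1.0)

    def test_column_out_of_range(self):
        with pytest.raises(ValueError):
            conservation_score(["AAA"], 5, "A")


class TestFeatureVector:
    def test_identity_limit_zeroes_deltas(self, toy_fold):
        res = toy_fold.residues("A")[4]
        wt_aa = AA3TO1[res.residue_name]
        mut_aa = "A" if wt_aa != "A" else "V"
        rec = MutationRecord("m", toy_fold.id, "A", res.residue_seq, wt_aa,
                             mut_aa, context="surface")
        e = simplified_stability(toy_fold, sasa_n_points=144)
        fv = build_feature_vector(toy_fold, toy_fold, rec, e, e,
                                  sasa_n_points=144)
        for name in fv.names:
            if name.startswith("d_") or name == "ddg_energy":
                assert fv[name] == 0.0, name

    def test_core_context_masks_interface_features(self, toy_fold):
        res = toy_fold.residues("A")[4]
        wt_aa = AA3TO1[res.residue_name]
        mut_aa = "L" if wt_aa != "L" else "I"
        rec = MutationRecord("m", toy_fold.id, "A", res.residue_seq, wt_aa,
                             mut_aa, context="core")
        from ddgboost.structures import mutate_residue_simple
        mut = mutate_residue_simple(toy_fold, "A", res.residue_seq, mut_aa)
        e = simplified_stability(toy_fold, sasa_n_points=144)
        em = simplified_stability(mut, sasa_n_points=144)
        fv = build_feature_vector(toy_fold, mut, rec, e, em, sasa_n_points=144)
        assert fv["is_interface"] == 0.0
        assert set(fv.masked) == {n for n in fv.names
                                  if n.startswith(("if_", "d_if_"))}
        assert len(fv.values) == len(feature_registry(list(e.terms)))
        assert np.isfinite(fv.values).all()

    def test_registry_mismatch_raises(self, toy_fold):
        from ddgboost.energy import EnergyTerms
        res = toy_fold.residues("A")[1]
        wt_aa = AA3TO1[res.residue_name]
        rec = MutationRecord("m", toy_fold.id, "A", res.residue_seq, wt_aa,
                             "A" if wt_aa != "A" else "V", context="core")
        e = simplified_stability(toy_fold, sasa_n_points=144)
        other = EnergyTerms(terms={"weird": 1.0, "dG": 1.0})
        with pytest.raises(ValueError):
            build_feature_vector(toy_fold, toy_fold, rec, e, other,
                                 sasa_n_points=144)

    def test_table_round_trip(self, toy_fold, tmp_path):
        res = toy_fold.residues("A")[4]
        wt_aa = AA3TO1[res.residue_name]
        mut_aa = "A" if wt_aa != "A" else "V"
        rec = MutationRecord("m", toy_fold.id, "A", res.residue_seq, wt_aa,
                             mut_aa, ddg_exp=1.25, family="famX",
                             context="surface")
        e = simplified_stability(toy_fold, sasa_n_points=144)
        fv = build_feature_vector(toy_fold, toy_fold, rec, e, e,
                                  sasa_n_points=144)
        p = tmp_path / "features.tsv"
        write_feature_table(p, [fv], [rec])
        X, names, muts, y = read_feature_table(p)
        assert names == fv.names
        active = [i for i, n in enumerate(names) if n not in fv.masked]
        assert np.allclose(X[0, active], fv.values[active])
        assert y == pytest.approx([1.25])
        assert muts[0].family == "famX"
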
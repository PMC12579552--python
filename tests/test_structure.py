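"""Structure I/O, superposition and two-state merging."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from trxscore import (
    AtomRecord,
    ResidueKey,
    ResidueSelection,
    RigidTransform,
    StructureModel,
    apply_transform,
    make_toy_structure,
    map_atom_names,
    merge_alt_conformers,
    read_structure,
    superpose_calpha,
    write_structure,
)
from trxscore.structure import ParseError, ValidationError


def models_equal(a, b, coord_tol=1e-3, occ_tol=1e-2, b_tol=1e-2):
    if list(a.residues) != list(b.residues):
        return False
    for key in a.residues:
        aa, bb = a.residues[key], b.residues[key]
        if len(aa) != len(bb):
            return False
        for x, y in zip(aa, bb):
            if (x.atom_name, x.altloc, x.element) != (y.atom_name, y.altloc, y.element):
                return False
            if np.max(np.abs(x.position - y.position)) > coord_tol:
                return False
            if abs(x.occupancy - y.occupancy) > occ_tol:
                return False
            if abs(x.b_factor - y.b_factor) > b_tol:
                return False
    return True


class TestPdbRoundTrip:
    def test_round_trip_identity(self, helix10, tmp_path):
        path = tmp_path / "helix.pdb"
        write_structure(helix10, path)
        back = read_structure(path)
        assert models_equal(helix10, back)
        # read o write o read is a fixed point at PDB precision
        path2 = tmp_path / "helix2.pdb"
        write_structure(back, path2)
        assert models_equal(back, read_structure(path2), coord_tol=0.0,
                            occ_tol=0.0, b_tol=0.0)

    def test_occupancy_column_preserved(self, tmp_path):
        """A 25% occupancy — the canonical initial B-conformer value — must
        survive the PDB fixed-column round trip exactly."""
        model = StructureModel(residues={
            ResidueKey("A", 1, "", "ALA"): [
                AtomRecord("CA", "C", np.zeros(3), "B", 0.25, 30.0),
            ]
        })
        path = tmp_path / "occ.pdb"
        write_structure(model, path)
        text = path.read_text()
        atom_line = next(l for l in text.splitlines() if l.startswith("ATOM"))
        assert atom_line[54:60] == "  0.25"
        assert read_structure(path).residues[
            ResidueKey("A", 1, "", "ALA")][0].occupancy == 0.25

    def test_full_occupancy_prints_as_1_00(self, tmp_path):
        model = StructureModel(residues={
            ResidueKey("A", 1, "", "GLY"): [
                AtomRecord("CA", "C", np.zeros(3), "", 1.0, 20.0),
            ]
        })
        path = tmp_path / "one.pdb"
        write_structure(model, path)
        atom_line = next(l for l in path.read_text().splitlines()
                         if l.startswith("ATOM"))
        assert atom_line[54:60] == "  1.00"
        assert atom_line[16] == " "  # blank altloc stays blank

    def test_malformed_record_names_line(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00 20.00           C\n"
            "ATOM      2  CB  ALA A   1      xx.yyy   2.000   3.000  1.00 20.00           C\n"
        )
        with pytest.raises(ParseError, match=":2:"):
            read_structure(path)

    def test_duplicate_altloc_rejected(self, tmp_path):
        path = tmp_path / "dup.pdb"
        path.write_text(
            "ATOM      1  CA AALA A   1       1.000   2.000   3.000  0.50 20.00           C\n"
            "ATOM      2  CA AALA A   1       1.500   2.000   3.000  0.50 20.00           C\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_structure(path)


class TestSuperposition:
    def test_self_superposition_is_identity(self, helix10):
        transform, rmsd = superpose_calpha(helix10, helix10)
        assert rmsd <= 1e-10
        assert np.allclose(transform.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(transform.translation, 0.0, atol=1e-9)

    def test_known_transform_recovered(self, helix10):
        applied = RigidTransform(
            Rotation.from_euler("z", 30, degrees=True).as_matrix(),
            np.array([1.0, 2.0, 3.0]),
        )
        mobile = apply_transform(helix10, applied)
        transform, rmsd = superpose_calpha(mobile, helix10)
        assert rmsd <= 1e-8
        inv = applied.inverse()
        assert np.allclose(transform.rotation, inv.rotation, atol=1e-8)
        assert np.allclose(transform.translation, inv.translation, atol=1e-6)

    def test_fifty_random_transforms_recovered(self, helix10, rng):
        for _ in range(50):
            applied = RigidTransform(
                Rotation.random(random_state=np.random.RandomState(
                    rng.integers(2**31))).as_matrix(),
                rng.normal(0, 5, 3),
            )
            mobile = apply_transform(helix10, applied)
            _, rmsd = superpose_calpha(mobile, helix10)
            assert rmsd <= 1e-8

    def test_noisy_fit_matches_brute_force_minimizer(self, helix10, rng):
        """The Kabsch result equals an independent numerical minimization over
        rotations, and the residual matches the closed-form expectation."""
        sigma = 0.1
        noisy = helix10.copy()
        n = 0
        for _, atom in noisy.iter_atoms():
            if atom.atom_name == "CA":
                atom.position = atom.position + rng.normal(0, sigma, 3)
                n += 1
        _, rmsd = superpose_calpha(noisy, helix10)

        mob = np.array([a.position for _, a in noisy.iter_atoms()
                        if a.atom_name == "CA"])
        ref = np.array([a.position for _, a in helix10.iter_atoms()
                        if a.atom_name == "CA"])
        mob_c = mob - mob.mean(axis=0)
        ref_c = ref - ref.mean(axis=0)

        def objective(rotvec):
            moved = Rotation.from_rotvec(rotvec).apply(mob_c)
            return np.mean(np.sum((moved - ref_c) ** 2, axis=1))

        best = min(
            (minimize(objective, x0, method="Nelder-Mead",
                      options={"xatol": 1e-12, "fatol": 1e-14}).fun
             for x0 in (np.zeros(3), np.array([0.1, -0.2, 0.3]))),
        )
        assert np.isclose(rmsd, np.sqrt(best), atol=1e-6)
        # rigid fit removes 6 degrees of freedom: E[n rmsd^2] = (3n-6) sigma^2
        dof = 3 * n - 6
        assert abs(n * rmsd**2 - dof * sigma**2) < 3 * sigma**2 * np.sqrt(2 * dof)

    def test_optimality_against_random_transforms(self, rng):
        """Returned RMSD is a global minimum: no random rigid motion beats it."""
        pts = rng.normal(0, 3, (10, 3))
        reference = StructureModel(residues={
            ResidueKey("A", i + 1, "", "ALA"): [
                AtomRecord("CA", "C", p, "", 1.0, 20.0)]
            for i, p in enumerate(pts)
        })
        mobile = StructureModel(residues={
            ResidueKey("A", i + 1, "", "ALA"): [
                AtomRecord("CA", "C", p + rng.normal(0, 0.5, 3), "", 1.0, 20.0)]
            for i, p in enumerate(pts)
        })
        _, rmsd = superpose_calpha(mobile, reference)
        mob = mobile.coordinates()
        ref = reference.coordinates()
        for _ in range(1000):
            rot = Rotation.random(
                random_state=np.random.RandomState(rng.integers(2**31))
            ).as_matrix()
            trans = rng.normal(0, 2, 3)
            trial = np.sqrt(np.mean(np.sum((mob @ rot.T + trans - ref) ** 2, axis=1)))
            assert trial >= rmsd - 1e-12

    def test_too_few_pairs_error(self):
        tiny = make_toy_structure(3, "helix")
        two = StructureModel(residues={
            k: tiny.residues[k] for k in list(tiny.residues)[:2]
        })
        with pytest.raises(ValidationError, match=">=3"):
            superpose_calpha(two, two)


class TestAtomNameMapping:
    def test_empty_mapping_is_identity(self, helix10):
        out, n = map_atom_names(helix10, [])
        assert n == 0
        assert models_equal(out, helix10, coord_tol=0.0, occ_tol=0.0, b_tol=0.0)

    def test_single_rename(self, helix10):
        out, n = map_atom_names(helix10, [("ALA", "CB", "CB2")])
        assert n == 10  # one CB per residue
        key = list(out.residues)[0]
        names = {a.atom_name for a in out.residues[key]}
        assert "CB2" in names and "CB" not in names

    def test_collision_rejected(self, helix10):
        with pytest.raises(ValidationError, match="collides"):
            map_atom_names(helix10, [("ALA", "CB", "CA")])


class TestMergeAltConformers:
    @pytest.fixture
    def merged(self, helix10):
        sel = ResidueSelection.from_keys(list(helix10.residues)[4:6])
        fragment = helix10.copy()
        for key, atoms in fragment.residues.items():
            if key in sel:
                for a in atoms:
                    a.position = a.position + np.array([1.0, 0.0, 0.0])
                    a.b_factor = 99.0  # must be overwritten by the A value
        return helix10, fragment, sel, merge_alt_conformers(
            helix10, fragment, sel, q_init=0.25
        )

    def test_occupancy_complement(self, merged):
        _, _, sel, model = merged
        for key, atoms in model.residues.items():
            if key not in sel:
                continue
            occ = {}
            for a in atoms:
                occ.setdefault(a.atom_name, {})[a.altloc] = a.occupancy
            for name, alts in occ.items():
                assert set(alts) == {"A", "B"}
                assert alts["B"] == 0.25
                assert abs(alts["A"] + alts["B"] - 1.0) <= 1e-6

    def test_bfactor_transferred_exactly(self, merged):
        _, _, sel, model = merged
        for key, atoms in model.residues.items():
            if key not in sel:
                continue
            b = {}
            for a in atoms:
                b.setdefault(a.atom_name, {})[a.altloc] = a.b_factor
            for alts in b.values():
                assert alts["B"] == alts["A"]  # exact copy, not approximate

    def test_atom_count_conserved(self, merged):
        reference, fragment, sel, model = merged
        for key in model.residues:
            if key in sel:
                assert len(model.residues[key]) == (
                    len(reference.residues[key]) + len(fragment.residues[key])
                )
            else:
                assert [a.altloc for a in model.residues[key]] == [
                    a.altloc for a in reference.residues[key]
                ]

    def test_unselected_residues_byte_identical_on_rewrite(
        self, merged, tmp_path
    ):
        reference, _, sel, model = merged
        p1, p2 = tmp_path / "ref.pdb", tmp_path / "merged.pdb"
        write_structure(reference, p1)
        write_structure(model, p2)
        selected_resnums = {site[1] for site in sel.sites}

        def unselected_lines(path):
            out = []
            for line in path.read_text().splitlines():
                if line.startswith("ATOM") and \
                        int(line[22:26]) not in selected_resnums:
                    out.append(line[12:])  # drop the serial-number column
            return out

        assert unselected_lines(p1) == unselected_lines(p2)

    def test_bad_q_init_rejected(self, helix10):
        sel = ResidueSelection.from_keys(list(helix10.residues)[:1])
        for q in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValidationError):
                merge_alt_conformers(helix10, helix10, sel, q_init=q)

    def test_unmatched_fragment_atom_listed(self, helix10):
        sel = ResidueSelection.from_keys(list(helix10.residues)[:1])
        fragment = helix10.copy()
        key = list(fragment.residues)[0]
        fragment.residues[key][0].atom_name = "OXT"
        with pytest.raises(ValidationError, match="OXT"):
            merge_alt_conformers(helix10, fragment, sel)

    def test_fragment_hydrogens_dropped(self, helix10):
        sel = ResidueSelection.from_keys(list(helix10.residues)[:1])
        fragment = helix10.copy()
        key = list(fragment.residues)[0]
        fragment.residues[key].append(
            AtomRecord("H", "H", fragment.residues[key][0].position + 0.5, "",
                       1.0, 20.0)
        )
        model = merge_alt_conformers(helix10, fragment, sel)
        assert all(not a.is_hydrogen for a in model.residues[key])


@given(st.lists(st.tuples(st.sampled_from("ABCD"), st.integers(1, 500)),
                min_size=1, max_size=20, unique=True))
def test_selection_string_round_trip(tokens):
    text = ",".join(f"{c}:{n}" for c, n in tokens)
    sel = ResidueSelection.from_string(text)
    assert len(sel) == len(tokens)
    for c, n in tokens:
        assert ResidueKey(c, n, "", "ALA") in sel
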
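import numpy as np
import pytest

from coassembler.structio import (
    MAX_ASA,
    STANDARD_AA,
    EmptyStructureError,
    PDBFormatError,
    Atom,
    Chain,
    Residue,
    Structure,
    classify_residue,
    read_pdb,
    shrake_rupley_sasa,
    write_pdb,
)


def _glycine_structure(center=(0.0, 0.0, 0.0)):
    c = np.asarray(center, float)
    res = Residue(chain_id="A", resseq=1, resname="GLY")
    res.atoms = [
        Atom(name="N", element="N", coord=c + [0.0, 0.0, 0.0]),
        Atom(name="CA", element="C", coord=c + [1.458, 0.0, 0.0]),
        Atom(name="C", element="C", coord=c + [2.0, 1.4, 0.0]),
        Atom(name="O", element="O", coord=c + [3.2, 1.6, 0.1]),
    ]
    return Structure([Chain(chain_id="A", residues=[res])])


class TestPdbRoundTrip:
    def test_coordinates_and_sequence_survive(self, small_fibril, tmp_path):
        p = tmp_path / "f.pdb"
        write_pdb(small_fibril, p)
        back = read_pdb(p)
        assert [r.resname for r in back.residues()] == \
            [r.resname for r in small_fibril.residues()]
        assert [r.resseq for r in back.residues()] == \
            [r.resseq for r in small_fibril.residues()]
        np.testing.assert_allclose(back.coords, small_fibril.coords, atol=1e-3)

    def test_multi_model_framing(self, small_fibril, tmp_path):
        two = small_fibril.with_coords(
            np.concatenate([small_fibril.coords,
                            small_fibril.coords + 1.0], axis=0))
        p = tmp_path / "ens.pdb"
        write_pdb(two, p)
        text = p.read_text()
        assert text.count("MODEL") == 2 and text.count("ENDMDL") == 2
        back_all = read_pdb(p, model_policy="all")
        assert back_all.n_models == 2
        assert read_pdb(p, model_policy="first").n_models == 1
        np.testing.assert_allclose(back_all.coords, two.coords, atol=1e-3)

    def test_empty_structure_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_pdb(Structure([Chain(chain_id="A")]), tmp_path / "x.pdb")

    def test_coordinate_overflow_rejected(self, tmp_path):
        s = _glycine_structure(center=(20000.0, 0, 0))
        with pytest.raises(PDBFormatError):
            write_pdb(s, tmp_path / "x.pdb")

    def test_zero_atom_file_rejected(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("HEADER    NOTHING\nEND\n")
        with pytest.raises(EmptyStructureError):
            read_pdb(p)


class TestHetatmHandling:
    def test_ion_goes_to_ion_group_and_water_dropped(self, tmp_path):
        p = tmp_path / "ion.pdb"
        p.write_text(
            "ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  C   GLY A   1       2.000   1.400   0.000  1.00  0.00           C\n"
            "ATOM      4  O   GLY A   1       3.200   1.600   0.100  1.00  0.00           O\n"
            "HETATM    5 NA    NA A 101       8.000   0.000   0.000  1.00  0.00          NA\n"
            "HETATM    6  O   HOH A 102       9.000   9.000   9.000  1.00  0.00           O\n"
            "END\n")
        s = read_pdb(p)
        assert len(s.protein_chains) == 1
        assert len(s.ion_chains) == 1
        ion = s.ion_chains[0].residues[0]
        assert ion.resname == "NA" and ion.formal_charge_sign == "+"
        assert all(r.resname != "HOH" for r in s.residues(include_ions=True))

    def test_altloc_highest_occupancy_wins(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(
            "ATOM      1  N  AGLY A   1       0.000   0.000   0.000  0.40  0.00           N\n"
            "ATOM      2  N  BGLY A   1       5.000   0.000   0.000  0.60  0.00           N\n"
            "ATOM      3  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C\n"
            "END\n")
        s = read_pdb(p)
        res = s.protein_chains[0].residues[0]
        ns = [a for a in res.atoms if a.name == "N"]
        assert len(ns) == 1
        assert ns[0].coord[0] == pytest.approx(5.0, abs=1e-3)


class TestClassification:
    @pytest.mark.parametrize("resname,expected", [
        ("ASP", "charged"), ("GLU", "charged"), ("ARG", "charged"),
        ("LYS", "charged"), ("SER", "polar"), ("HIS", "polar"),
        ("TRP", "polar"), ("CYS", "polar"), ("ILE", "apolar"),
        ("MET", "apolar"), ("GLY", "apolar"), ("PRO", "apolar"),
    ])
    def test_table(self, resname, expected):
        assert classify_residue(resname) == expected

    def test_histidine_and_methionine_options(self):
        assert classify_residue("HIS", his_charged=True) == "charged"
        assert classify_residue("MET", met_polar=True) == "polar"

    def test_total_and_deterministic_over_standard_residues(self):
        classes = {rn: classify_residue(rn) for rn in STANDARD_AA}
        assert set(classes.values()) <= {"charged", "polar", "apolar"}
        assert classes == {rn: classify_residue(rn) for rn in STANDARD_AA}

    def test_unknown_code_raises(self):
        with pytest.raises(KeyError):
            classify_residue("XYZ")


class TestSasa:
    def test_free_glycine_matches_high_density_oracle(self):
        s = _glycine_structure()
        result = shrake_rupley_sasa(s, n_points=960)
        total = result.total

        # independent Monte Carlo oracle with 1e5 random sphere points/atom
        rng = np.random.default_rng(0)
        coords = s.frame(0)
        radii = np.array([a.vdw_radius for a in s.atoms]) + 1.4
        oracle = 0.0
        for i in range(len(coords)):
            pts = rng.normal(size=(100_000, 3))
            pts /= np.linalg.norm(pts, axis=1, keepdims=True)
            pts = coords[i] + radii[i] * pts
            exposed = np.ones(len(pts), dtype=bool)
            for j in range(len(coords)):
                if j == i:
                    continue
                exposed &= np.sum((pts - coords[j]) ** 2, axis=1) > radii[j] ** 2
            oracle += 4 * np.pi * radii[i] ** 2 * exposed.mean()
        assert total == pytest.approx(oracle, rel=0.02)

    def test_fully_enclosed_atom_contributes_zero(self):
        # central atom caged by 14 overlapping spheres
        res = Residue(chain_id="A", resseq=1, resname="GLY")
        res.atoms = [Atom(name="CA", element="C", coord=np.zeros(3))]
        shell = Residue(chain_id="A", resseq=2, resname="GLY")
        dirs = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                         [0, 0, 1], [0, 0, -1],
                         [1, 1, 1], [1, 1, -1], [1, -1, 1], [-1, 1, 1],
                         [-1, -1, 1], [-1, 1, -1], [1, -1, -1], [-1, -1, -1]],
                        dtype=float)
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        shell.atoms = [Atom(name="C", element="C", coord=2.0 * d) for d in dirs]
        s = Structure([Chain(chain_id="A", residues=[res, shell])])
        result = shrake_rupley_sasa(s, n_points=960)
        assert result.per_residue_sasa[("A", 1, "")] == 0.0

    def test_point_density_convergence(self, small_fibril):
        lo = shrake_rupley_sasa(small_fibril, n_points=960)
        hi = shrake_rupley_sasa(small_fibril, n_points=1920)
        for key, v in lo.per_residue_sasa.items():
            # 1% relative with a ~1.5 Å² discretisation floor for
            # nearly-buried residues
            assert v == pytest.approx(hi.per_residue_sasa[key],
                                      rel=0.01, abs=1.5)

    def test_rigid_motion_invariance(self, small_fibril):
        from coassembler._geom import apply_rigid
        from scipy.spatial.transform import Rotation

        base = shrake_rupley_sasa(small_fibril, n_points=960).total
        rot = Rotation.from_euler("xyz", [31, -57, 113], degrees=True).as_matrix()
        moved = small_fibril.with_coords(
            apply_rigid(small_fibril.coords[0], rot, np.array([5., -3., 11.]))[None])
        assert shrake_rupley_sasa(moved, n_points=960).total == \
            pytest.approx(base, rel=0.005)

    def test_multi_model_requires_frame(self, small_fibril):
        two = small_fibril.with_coords(
            np.concatenate([small_fibril.coords, small_fibril.coords]))
        with pytest.raises(ValueError):
            shrake_rupley_sasa(two)

    def test_relative_sasa_bounded(self, small_fibril):
        rel = shrake_rupley_sasa(small_fibril, n_points=960).per_residue_relative
        assert all(0.0 <= v <= 1.2 for v in rel.values())
        assert set(MAX_ASA) == STANDARD_AA
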
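import numpy as np
import pytest

from coassembler.fixtures import (
    AB42_SEQUENCE,
    BinderSpec,
    ContactDirective,
    EnsembleSpec,
    FibrilSpec,
    ITCSpec,
    add_ion,
    build_binder,
    build_fibril,
    perturb_ensemble,
    simulate_itc,
)
from coassembler.interfaces import detect_beta_bridges, pair_contact_matrix
from coassembler.structio import shrake_rupley_sasa


class TestBuildFibril:
    def test_chain_and_residue_counts(self, ab_fibril):
        assert len(ab_fibril.protein_chains) == 5
        assert all(len(c.residues) == 42 for c in ab_fibril.protein_chains)
        assert ab_fibril.sequence("A") == AB42_SEQUENCE

    def test_rise_between_aligned_calphas(self, small_fibril):
        for i in (1, 3, 5):
            a = small_fibril.get_residue("A", i).atom("CA").coord
            b = small_fibril.get_residue("B", i).atom("CA").coord
            assert np.linalg.norm(a - b) == pytest.approx(4.8, abs=0.1)

    def test_parallel_bridges_between_adjacent_monomers(self, small_fibril):
        bridges = detect_beta_bridges(small_fibril)
        kinds = {b.kind for b in bridges}
        assert kinds == {"parallel"}
        # in-register: aligned residue indices on adjacent chains
        aligned = [(b.res_i, b.res_j) for b in bridges
                   if b.res_i[1] == b.res_j[1]]
        assert len(aligned) >= 8

    def test_antiparallel_arrangement_gives_antiparallel_bridges(
            self, antiparallel_fibril):
        bridges = detect_beta_bridges(antiparallel_fibril)
        assert bridges and all(b.kind == "antiparallel" for b in bridges)

    def test_hinged_nterm_is_unpaired(self, ab_fibril):
        edge = ab_fibril.metadata["edge_chain"]
        bridges = detect_beta_bridges(ab_fibril)
        hinged = [b for b in bridges
                  if (b.res_i[0] == edge and b.res_i[1] <= 8)
                  or (b.res_j[0] == edge and b.res_j[1] <= 8)]
        assert hinged == []

    def test_bad_sequence_rejected(self):
        with pytest.raises(ValueError):
            FibrilSpec(sequence="KLVXFE")

    def test_determinism(self):
        a = build_fibril(FibrilSpec(n_monomers=2, sequence="VQIVYK",
                                    disordered_nterm_len=0))
        b = build_fibril(FibrilSpec(n_monomers=2, sequence="VQIVYK",
                                    disordered_nterm_len=0))
        np.testing.assert_array_equal(a.coords, b.coords)


class TestBuildBinder:
    def test_strand_residues_have_beta_dihedrals(self, binder):
        # phi of strand residues ~ -119, psi ~ +113
        ch = binder.chain("X")
        res = {r.resseq: r for r in ch.residues}
        for resseq in range(427, 433):
            prev, cur = res[resseq - 1], res[resseq]
            phi = _dihedral(prev.atom("C").coord, cur.atom("N").coord,
                            cur.atom("CA").coord, cur.atom("C").coord)
            assert phi == pytest.approx(-119.0, abs=2.0)

    def test_extended_coil_scaffold_is_clash_free(self, binder):
        fr = binder.frame(0)
        residues = list(binder.residues())
        for i, ra in enumerate(residues):
            for rb in residues[i + 2:]:  # skip bonded neighbours
                d = fr[ra.atom_indices][:, None, :] - fr[rb.atom_indices][None, :, :]
                assert np.sqrt((d ** 2).sum(axis=2).min()) > 2.2

    def test_strand_is_solvent_exposed(self, binder):
        rel = shrake_rupley_sasa(binder, n_points=480).per_residue_relative
        strand = [rel[("X", r, "")] for r in range(426, 434)]
        assert np.mean(strand) > 0.3

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            BinderSpec(sequence="")

    def test_strand_range_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            BinderSpec(sequence="GSGS", strand_range=(1, 10), start_resseq=1)


class TestPerturbEnsemble:
    def test_zero_noise_empty_schedule_identity(self, coassembly):
        ens = perturb_ensemble(coassembly.structure,
                               EnsembleSpec(n_frames=4, backbone_noise_sd=0.0))
        for f in range(4):
            np.testing.assert_array_equal(ens.frame(f),
                                          coassembly.structure.frame(0))

    def test_fraction_schedule_measured_persistence(self, coassembly):
        sched = [ContactDirective(label="p", mobile=("X", 429),
                                  anchor=("E", 4), profile=("fraction", 0.5))]
        ens = perturb_ensemble(coassembly.structure,
                               EnsembleSpec(n_frames=100, backbone_noise_sd=0.1,
                                            contact_schedule=sched, seed=3))
        mat = pair_contact_matrix(ens, [(("X", 429), ("E", 4))])
        assert mat.mean() == pytest.approx(0.5, abs=0.05)

    def test_dissociate_after_schedule(self, coassembly):
        sched = [ContactDirective(label="d", mobile=("X", 429),
                                  anchor=("E", 4),
                                  profile=("dissociate_after", 5))]
        ens = perturb_ensemble(coassembly.structure,
                               EnsembleSpec(n_frames=10, backbone_noise_sd=0.05,
                                            contact_schedule=sched, seed=1))
        mat = pair_contact_matrix(ens, [(("X", 429), ("E", 4))])[:, 0]
        assert mat[:5].all() and not mat[5:].any()

    def test_same_seed_bit_identical(self, coassembly):
        spec = EnsembleSpec(n_frames=6, backbone_noise_sd=0.2, seed=11)
        a = perturb_ensemble(coassembly.structure, spec)
        b = perturb_ensemble(coassembly.structure, spec)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_schedule_referencing_absent_residue_rejected(self, coassembly):
        sched = [ContactDirective(label="bad", mobile=("X", 9999),
                                  anchor=("E", 4), profile=("always",))]
        with pytest.raises(KeyError):
            perturb_ensemble(coassembly.structure,
                             EnsembleSpec(n_frames=2, contact_schedule=sched))


class TestAddIon:
    def test_ion_near_named_atom(self, small_fibril):
        s = add_ion(small_fibril, element="NA", near=("A", 7, "OE1"),
                    distance=3.0)
        ion = s.ion_chains[0].residues[0]
        d = np.linalg.norm(ion.atoms[0].coord
                           - s.get_residue("A", 7).atom("OE1").coord)
        assert d == pytest.approx(3.0, abs=1e-6)


class TestSimulateItc:
    def test_zero_enthalpy_gives_zero_heats(self):
        spec = ITCSpec(sites=[(2.5, 121e-9, 0.0), (18.0, 1.92e-6, 0.0)],
                       noise_sd=0.0)
        iso = simulate_itc(spec)
        np.testing.assert_allclose(iso.heats, 0.0, atol=1e-30)

    def test_same_seed_identical(self):
        a = simulate_itc(ITCSpec(seed=5))
        b = simulate_itc(ITCSpec(seed=5))
        np.testing.assert_array_equal(a.heats, b.heats)

    def test_two_site_isotherm_shows_two_transitions(self):
        iso = simulate_itc(ITCSpec(noise_sd=0.0))
        h = iso.heats
        # exothermic high-affinity phase first, endothermic low-affinity
        # phase later, decaying back toward zero: one sign change plus a
        # subsequent magnitude decay
        sign_changes = int(np.sum(np.diff(np.sign(h)) != 0))
        assert sign_changes >= 1
        crossover = int(np.argmax(h > 0))
        peak = crossover + int(np.argmax(h[crossover:]))
        assert h[peak] > 0
        assert abs(h[-1]) < 0.25 * h[peak]
        assert h[0] < 0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ITCSpec(sites=[(2.5, -1e-9, -8.0)])


def _dihedral(a, b, c, d):
    b0, b1, b2 = a - b, c - b, d - c
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return np.degrees(np.arctan2(y, x))
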
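"""SASA engine vs analytic/grid oracles; mapping, contacts, classification."""

import math

import numpy as np
import pandas as pd
import pytest

from plasmapipe.interface import (
    ATOM_RADII,
    ComplexDescriptors,
    PeptideQuery,
    aggregate_complexes,
    classify_location,
    count_contacts,
    k_sasa,
    map_peptide,
    min_partner_distance,
    sasa,
    shrake_rupley,
)
from plasmapipe.io_formats import StructureModel
from plasmapipe.synthetic import ToyComplexSpec, generate_toy_complex

ATOM_COLS = ["serial", "name", "element", "chain", "resseq", "icode",
             "resname", "x", "y", "z", "occupancy"]


def build_structure(atom_rows, chain_seqs):
    atoms = pd.DataFrame(atom_rows, columns=ATOM_COLS)
    ligands = pd.DataFrame(columns=ATOM_COLS)
    return StructureModel(atoms, ligands, chain_seqs, name="fixture")


def grid_sasa_oracle(coords, radii, probe=1.4, n_theta=240, n_phi=480):
    """Latitude-longitude surface quadrature, independent of the engine."""
    coords = np.asarray(coords, float)
    ext = np.asarray(radii, float) + probe
    theta = (np.arange(n_theta) + 0.5) * math.pi / n_theta
    phi = (np.arange(n_phi) + 0.5) * 2 * math.pi / n_phi
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    dirs = np.stack([np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp),
                     np.cos(tt)], axis=-1).reshape(-1, 3)
    w = (np.sin(tt) * (math.pi / n_theta) * (2 * math.pi / n_phi)).ravel()
    total = 0.0
    for i in range(len(coords)):
        pts = coords[i] + ext[i] * dirs
        ok = np.ones(len(pts), dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            ok &= np.sum((pts - coords[j]) ** 2, axis=1) > ext[j] ** 2
        total += ext[i] ** 2 * w[ok].sum()
    return total


class TestShrakeRupley:
    def test_isolated_carbon_is_probe_inflated_sphere(self):
        area = shrake_rupley(np.array([[0.0, 0, 0]]), ["C"])
        assert area[0] == pytest.approx(4 * math.pi * (1.87 + 1.4) ** 2,
                                        rel=1e-6)

    def test_distant_atoms_additive(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        areas = shrake_rupley(coords, ["C", "N"])
        lone_c = shrake_rupley(np.array([[0.0, 0, 0]]), ["C"])[0]
        lone_n = shrake_rupley(np.array([[0.0, 0, 0]]), ["N"])[0]
        assert areas.sum() == pytest.approx(lone_c + lone_n, rel=1e-9)

    def test_two_overlapping_spheres_analytic(self):
        # equal spheres: accessible area loses a cap of height R - d/2
        d = 2.0
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        areas = shrake_rupley(coords, ["C", "C"])
        R = 1.87 + 1.4
        cap = 2 * math.pi * R * (R - d / 2)
        expected = 4 * math.pi * R ** 2 - cap
        assert areas[0] == pytest.approx(expected, rel=0.02)
        assert areas[1] == pytest.approx(expected, rel=0.02)

    @pytest.mark.parametrize("n_atoms", [2, 3, 5])
    def test_matches_grid_integration_oracle(self, n_atoms):
        rng = np.random.default_rng(n_atoms)
        coords = rng.uniform(0, 4.0, size=(n_atoms, 3))
        elements = rng.choice(["C", "N", "O", "S"], n_atoms)
        mine = shrake_rupley(coords, elements).sum()
        oracle = grid_sasa_oracle(coords, [ATOM_RADII[e] for e in elements])
        assert mine == pytest.approx(oracle, rel=0.02)

    def test_agrees_with_independent_implementation(self, toy_half):
        biotite_structure = pytest.importorskip("biotite.structure")
        atoms = toy_half.structure.atoms
        arr = biotite_structure.AtomArray(len(atoms))
        arr.coord = atoms[["x", "y", "z"]].to_numpy()
        arr.chain_id = atoms["chain"].to_numpy()
        arr.res_id = atoms["resseq"].to_numpy()
        arr.res_name = atoms["resname"].to_numpy()
        arr.atom_name = atoms["name"].to_numpy()
        arr.element = atoms["element"].to_numpy()
        radii = np.array([ATOM_RADII[e] for e in atoms["element"]])
        ref = biotite_structure.sasa(arr, probe_radius=1.4, vdw_radii=radii,
                                     point_number=960).sum()
        mine = sasa(atoms).sum()
        assert mine == pytest.approx(ref, rel=0.02)

    def test_unknown_element_named_in_rejection(self):
        with pytest.raises(ValueError, match="Xx"):
            shrake_rupley(np.zeros((1, 3)), ["Xx"])


class TestMapPeptide:
    def test_unique_match_fully_resolved(self, toy_half):
        hits = map_peptide(PeptideQuery(toy_half.peptide),
                           toy_half.structure)
        mine = [h for h in hits if h.chain == "A"]
        assert len(mine) == 1
        assert mine[0].fraction_resolved == 1.0
        assert mine[0].start == toy_half.start
        assert mine[0].end == toy_half.end

    def test_absent_peptide_empty_list(self, toy_half):
        assert map_peptide(PeptideQuery("WWWWWW"), toy_half.structure) == []

    def test_internal_gap_tolerated_up_to_fraction(self):
        # chain with residues 1-4 and 6-10: residue 5 unresolved
        seq = "ACDEFGHIKL"
        rows = []
        residues = []
        for i, aa in enumerate(seq):
            resseq = i + 1
            if resseq == 5:
                continue
            rows.append((resseq, "CA", "C", "A", resseq, "", "ALA",
                         resseq * 3.8, 0.0, 0.0, 1.0))
            residues.append((resseq, "", aa))
        st = build_structure(rows, {"A": residues})
        hits = map_peptide(PeptideQuery(seq), st)
        assert len(hits) == 1
        assert hits[0].fraction_resolved == pytest.approx(0.9)
        # a 3-residue gap in a 10-mer exceeds the 20% tolerance
        st2 = build_structure(
            [r for r in rows if r[0] not in (4, 6)],
            {"A": [r for r in residues if r[0] not in (4, 6)]})
        assert map_peptide(PeptideQuery(seq), st2) == []

    def test_multiple_matches_all_reported(self):
        seq = "ACDACD"
        rows = [(i + 1, "CA", "C", "A", i + 1, "", "ALA",
                 (i + 1) * 3.8, 0.0, 0.0, 1.0) for i in range(len(seq))]
        residues = [(i + 1, "", aa) for i, aa in enumerate(seq)]
        st = build_structure(rows, {"A": residues})
        with pytest.warns(UserWarning, match="matches 2"):
            hits = map_peptide(PeptideQuery("ACD"), st)
        assert [(h.start, h.end) for h in hits] == [(1, 3), (4, 6)]


class TestKSasa:
    def test_partner_removed_forces_unity(self, toy_half):
        full = toy_half.structure
        chain_a_only = StructureModel(
            full.chain_atoms("A").copy(), full.ligands,
            {"A": full.chain_residues["A"]}, name="alone")
        mapping = [m for m in map_peptide(PeptideQuery(toy_half.peptide),
                                          chain_a_only)][0]
        assert k_sasa(mapping, chain_a_only) == pytest.approx(1.0, abs=0.02)

    def test_rigid_motion_invariance(self, toy_half):
        full = toy_half.structure
        mapping = [m for m in map_peptide(PeptideQuery(toy_half.peptide),
                                          full) if m.chain == "A"][0]
        k0 = k_sasa(mapping, full)
        theta = 0.7
        rot = np.array([
            [math.cos(theta), -math.sin(theta), 0],
            [math.sin(theta), math.cos(theta), 0],
            [0, 0, 1],
        ])
        atoms = full.atoms.copy()
        xyz = atoms[["x", "y", "z"]].to_numpy() @ rot.T + [5.0, -3.0, 11.0]
        atoms[["x", "y", "z"]] = xyz
        moved = StructureModel(atoms, full.ligands, full.chain_residues,
                               name="moved")
        k1 = k_sasa(mapping, moved)
        assert k1 == pytest.approx(k0, abs=0.02)
        d0 = min_partner_distance(mapping, full)
        d1 = min_partner_distance(mapping, moved)
        assert d1 == pytest.approx(d0, abs=1e-6)


class TestCountContacts:
    @staticmethod
    def _pair_structure(d, el_a="N", el_b="O"):
        rows = [
            (1, el_a, el_a, "A", 1, "", "GLY", 0.0, 0.0, 0.0, 1.0),
            (2, el_b, el_b, "B", 1, "", "GLY", d, 0.0, 0.0, 1.0),
        ]
        return build_structure(rows, {"A": [(1, "", "G")],
                                      "B": [(1, "", "G")]})

    @staticmethod
    def _mapping():
        from plasmapipe.interface import PeptideMapping
        return PeptideMapping(structure_id="fixture", chain="A", start=1,
                              end=1, fraction_resolved=1.0)

    def test_hb_within_threshold(self):
        hb, hp = count_contacts(self._mapping(), self._pair_structure(2.9))
        assert hb == 1

    def test_hb_beyond_threshold(self):
        hb, hp = count_contacts(self._mapping(), self._pair_structure(3.8))
        assert hb == 0

    def test_distant_partner_no_contacts(self):
        hb, hp = count_contacts(self._mapping(), self._pair_structure(12.0))
        assert (hb, hp) == (0, 0)

    def test_apolar_carbon_pair_counts_hp(self):
        hb, hp = count_contacts(self._mapping(),
                                self._pair_structure(4.5, "C", "C"))
        assert (hb, hp) == (0, 1)

    def test_carbon_bonded_to_oxygen_is_polar(self):
        rows = [
            (1, "C", "C", "A", 1, "", "GLY", 0.0, 0.0, 0.0, 1.0),
            (2, "O", "O", "A", 1, "", "GLY", 0.0, 1.3, 0.0, 1.0),
            (3, "C", "C", "B", 1, "", "GLY", 4.5, 0.0, 0.0, 1.0),
        ]
        st = build_structure(rows, {"A": [(1, "", "G")],
                                    "B": [(1, "", "G")]})
        hb, hp = count_contacts(self._mapping(), st)
        assert hp == 0  # the peptide carbon carries a bonded oxygen


class TestClassification:
    def test_low_k_is_in(self):
        cls, _ = classify_location([0.6], min_distance=3.0)
        assert cls == "In"

    def test_unit_k_distant_partner_is_out(self):
        cls, _ = classify_location([1.0], min_distance=30.0)
        assert cls == "Out"

    def test_unit_k_grazing_partner_is_near(self):
        cls, _ = classify_location([1.0], min_distance=5.0)
        assert cls == "Near"

    def test_grazing_toy_complex_is_near(self):
        toy = generate_toy_complex(ToyComplexSpec(
            peptide_length=8, burial_fraction=0.03, seed=6))
        mapping = [m for m in map_peptide(PeptideQuery(toy.peptide),
                                          toy.structure) if m.chain == "A"][0]
        k = k_sasa(mapping, toy.structure)
        d = min_partner_distance(mapping, toy.structure)
        cls, _ = classify_location([k], d)
        assert 0.9 <= k <= 1.1
        assert cls == "Near"

    def test_surface_flag_thresholds(self):
        _, flag = classify_location([1.0], 30.0,
                                    peptide_sasa_isolated=250.0,
                                    peptide_length=10)
        assert flag is True
        _, flag = classify_location([1.0], 30.0,
                                    peptide_sasa_isolated=150.0,
                                    peptide_length=10)
        assert flag is False


class TestAggregation:
    @staticmethod
    def _desc(sid, k, hb=1, hp=2, dist=5.0):
        return ComplexDescriptors(structure_id=sid, chain="A", k_sasa=k,
                                  hb=hb, hp=hp, min_partner_distance=dist,
                                  peptide_sasa_isolated=500.0,
                                  partner_chains=["B"])

    def test_single_complex_sd_zero(self):
        rep = aggregate_complexes(PeptideQuery("ACDEF"),
                                  [self._desc("s1", 0.7)])
        assert rep.k_mean == pytest.approx(0.7)
        assert rep.k_sd == 0.0

    def test_population_sd_of_two(self):
        rep = aggregate_complexes(
            PeptideQuery("ACDEF"),
            [self._desc("s1", 0.55), self._desc("s2", 0.65)])
        assert rep.k_mean == pytest.approx(0.60)
        assert rep.k_sd == pytest.approx(0.05)
        assert rep.location_class == "In"

    def test_screened_counts_reported(self):
        descs = [self._desc(f"s{i}", 0.6) for i in range(10)]
        rep = aggregate_complexes(PeptideQuery("ACDEF"), descs,
                                  n_structures_screened=15)
        assert rep.pdb_counts == "10/15"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_complexes(PeptideQuery("ACDEF"), [])
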
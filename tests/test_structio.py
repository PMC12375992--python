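import math

import numpy as np
import pytest

from hydrophobins import structio, synthdata
from hydrophobins.structio import (
    CANONICAL_TOPOLOGY,
    StructureParseError,
    build_model,
    detect_disulfides,
    parse_structure,
    shrake_rupley_sasa,
    write_pdb,
)
from hydrophobins.synthdata import random_rigid_motion

MINIMAL_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00 92.50           C
END
"""


class TestParse:
    def test_minimal_two_residues(self):
        models = parse_structure(MINIMAL_PDB)
        assert len(models) == 1
        model = models[0]
        assert len(model.residues) == 2
        assert model.sequence() == "AG"
        assert model.residues[1].confidence == pytest.approx(92.5)
        np.testing.assert_allclose(model.residues[1].ca, [3.8, 0.0, 0.0])

    def test_multi_model_ensemble(self):
        block = MINIMAL_PDB.replace("END\n", "")
        text = ""
        for i in (1, 2, 3):
            text += f"MODEL     {i:4d}\n" + block + "ENDMDL\n"
        models = parse_structure(text + "END\n")
        assert [m.model_index for m in models] == [1, 2, 3]

    def test_no_atom_records_is_error(self):
        with pytest.raises(StructureParseError, match="no ATOM"):
            parse_structure("HEADER    NOTHING\nEND\n")

    def test_malformed_coordinate_names_line(self):
        bad = MINIMAL_PDB.replace("3.800", "3.8xx")
        with pytest.raises(StructureParseError, match="line 2"):
            parse_structure(bad)

    def test_altloc_highest_occupancy_wins(self):
        text = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40 10.00           C\n"
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.60 10.00           C\n"
            "ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00 10.00           C\n"
            "ATOM      4  CA  GLY A   3       7.600   0.000   0.000  1.00 10.00           C\n"
            "END\n"
        )
        model = parse_structure(text)[0]
        np.testing.assert_allclose(model.residues[0].ca, [5.0, 0.0, 0.0])

    def test_write_read_round_trip_preserves_geometry(self, tmp_path):
        reference, perturbed = synthdata.synth_structure_pair(
            synthdata.StructureGenSpec(n_residues=20, noise_sd=0.5, seed=4, n_models=2)
        )
        path = tmp_path / "ensemble.pdb"
        write_pdb(perturbed, path)
        back = parse_structure(path)
        assert len(back) == 2
        np.testing.assert_allclose(back[0].ca_coords(), perturbed[0].ca_coords(), atol=1e-3)


class TestDisulfides:
    def test_covalent_distance_pairs(self):
        model = build_model(
            np.array([[0.0, 0, 0], [10.0, 0, 0], [20.0, 0, 0]]),
            sequence="CAC",
            sg_coords={0: np.array([0.0, 2.0, 0]), 2: np.array([0.0, 2.0, 2.04])},
        )
        topo = detect_disulfides(model)
        assert topo.bonds == frozenset({(1, 2)})  # ordinals among cysteines

    def test_beyond_cutoff_not_bonded(self):
        model = build_model(
            np.array([[0.0, 0, 0], [10.0, 0, 0], [20.0, 0, 0]]),
            sequence="CAC",
            sg_coords={0: np.array([0.0, 2.0, 0]), 2: np.array([0.0, 2.0, 3.5])},
        )
        topo = detect_disulfides(model)
        assert topo.bonds == frozenset()
        assert topo.free_cysteines == (1, 2)

    def test_canonical_octet_recovered(self):
        model = synthdata.synth_disulfide_structure()
        topo = detect_disulfides(model)
        assert topo.n_bonds == 4
        assert topo.bonds == CANONICAL_TOPOLOGY
        assert topo.canonical_match
        assert topo.mapping_to_canonical == {b: b for b in sorted(CANONICAL_TOPOLOGY)}

    def test_invariant_under_rigid_motion(self, rng):
        model = synthdata.synth_disulfide_structure()
        rot, trans = random_rigid_motion(rng)
        moved = model.transformed(rot, trans)
        assert detect_disulfides(moved).bonds == detect_disulfides(model).bonds

    def test_shifted_topology_maps_onto_canonical_reference(self):
        # a decet whose middle bonds mirror the canonical geometry: the
        # spatial correspondence should pair each bond with the canonical
        # bond occupying the same site
        reference = synthdata.synth_disulfide_structure()
        shifted = synthdata.synth_disulfide_structure(
            topology=((1, 6), (2, 5), (3, 4), (7, 8), (9, 10)), n_residues=68
        )
        topo = detect_disulfides(shifted, canonical_reference=reference)
        assert topo.n_bonds == 5
        assert not topo.canonical_match
        mapped = {v for v in topo.mapping_to_canonical.values() if v is not None}
        assert mapped == set(CANONICAL_TOPOLOGY)


class TestSasa:
    def test_isolated_atom_matches_analytic_sphere(self):
        model = build_model(np.array([[0.0, 0, 0], [100.0, 0, 0], [200.0, 0, 0]]))
        with pytest.warns(UserWarning):
            result = shrake_rupley_sasa(model)
        exact = 3 * 4 * math.pi * (1.70 + 1.4) ** 2
        assert result.total == pytest.approx(exact, rel=0.01)

    def test_coincident_atoms_count_once(self):
        single = build_model(np.array([[0.0, 0, 0], [100.0, 0, 0], [200.0, 0, 0]]))
        doubled = build_model(
            np.array([[0.0, 0, 0], [0.0, 0, 0], [100.0, 0, 0], [200.0, 0, 0]])
        )
        with pytest.warns(UserWarning):
            a = shrake_rupley_sasa(single).total
        with pytest.warns(UserWarning):
            b = shrake_rupley_sasa(doubled).total
        assert b == pytest.approx(a, rel=1e-9)

    def test_enclosed_atom_is_buried(self):
        # centre atom caged by a dense shell of atoms
        shell = structio._sphere_points(200) * 2.5
        coords = np.vstack(([[0.0, 0.0, 0.0]], shell))
        model = build_model(coords)
        with pytest.warns(UserWarning):
            result = shrake_rupley_sasa(model)
        assert result.per_residue[0] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance_and_point_density_stability(self, rng):
        model = synthdata.synth_structure_pair(
            synthdata.StructureGenSpec(n_residues=30, noise_sd=0.0, seed=8)
        )[0]
        rot, trans = random_rigid_motion(rng)
        with pytest.warns(UserWarning):
            base = shrake_rupley_sasa(model)
            moved = shrake_rupley_sasa(model.transformed(rot, trans))
            half = shrake_rupley_sasa(model, n_points=480)
        assert moved.total == pytest.approx(base.total, rel=5e-3)
        assert abs(half.total - base.total) / base.total < 0.02

    def test_monte_carlo_oracle_on_small_cluster(self, rng):
        # independent oracle: random (not spiral) surface sampling
        coords = np.array(
            [[0.0, 0, 0], [2.5, 0.5, 0.2], [1.0, 2.0, -0.5], [-1.5, 1.0, 1.0]]
        )
        model = build_model(coords)
        with pytest.warns(UserWarning):
            result = shrake_rupley_sasa(model, n_points=2000)
        expanded = 1.70 + 1.4
        total_mc = 0.0
        n_mc = 4000
        for i in range(len(coords)):
            v = rng.normal(size=(n_mc, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            pts = coords[i] + expanded * v
            free = np.ones(n_mc, dtype=bool)
            for j in range(len(coords)):
                if j != i:
                    free &= np.sum((pts - coords[j]) ** 2, axis=1) >= expanded**2
            total_mc += 4 * math.pi * expanded**2 * free.mean()
        assert result.total == pytest.approx(total_mc, rel=0.03)
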
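import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hydrophobins import structcompare, synthdata
from hydrophobins.structcompare import (
    DegenerateInputError,
    benchmark_model,
    kabsch_superpose,
    lddt_ca,
    pair_residues,
    tm_d0,
    tm_from_distances,
    tm_score,
)
from hydrophobins.structio import build_model
from hydrophobins.synthdata import helix_template, random_rigid_motion


def _equilateral(side: float) -> np.ndarray:
    return side * np.array([[0.0, 0, 0], [1.0, 0, 0], [0.5, np.sqrt(3) / 2, 0]])


class TestKabsch:
    def test_identical_sets_give_zero_rmsd_identity_rotation(self, rng):
        pts = rng.normal(size=(12, 3))
        sup = kabsch_superpose(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_rigid_motion_recovered_exactly(self, rng):
        pts = rng.normal(size=(20, 3)) * 5
        rot = Rotation.from_rotvec(np.deg2rad(37) * np.array([0.3, 0.5, 0.81])).as_matrix()
        moved = pts @ rot.T + np.array([1.0, -2.0, 3.0])
        sup = kabsch_superpose(moved, pts)
        assert sup.rmsd <= 1e-6
        np.testing.assert_allclose(sup.apply(moved), pts, atol=1e-8)

    def test_too_few_points_error(self):
        with pytest.raises(DegenerateInputError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_reference_error(self):
        line = np.column_stack((np.arange(5.0), np.zeros(5), np.zeros(5)))
        with pytest.raises(DegenerateInputError):
            kabsch_superpose(line + 0.0, line)

    def test_proper_rotation_enforced_on_mirrored_input(self, rng):
        pts = rng.normal(size=(10, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        sup = kabsch_superpose(mirrored, pts)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0)

    def test_optimal_versus_rotation_grid_oracle(self, rng):
        """Kabsch must beat (or match) a brute-force Euler-grid search."""
        pts = rng.normal(size=(10, 3)) * 4
        noisy = pts + rng.normal(scale=0.5, size=pts.shape)
        rot, trans = random_rigid_motion(rng)
        mobile = noisy @ rot.T + trans

        sup = kabsch_superpose(mobile, pts)
        cm, cr = mobile.mean(axis=0), pts.mean(axis=0)
        p, q = mobile - cm, pts - cr
        step = np.deg2rad(9)
        angles = np.arange(0, 2 * np.pi, step)
        half = np.arange(0, np.pi + step, step)
        best = np.inf
        for a in angles:
            for b in half:
                for c in angles:
                    r = Rotation.from_euler("zyz", [a, b, c]).as_matrix()
                    rmsd = np.sqrt(((p @ r.T - q) ** 2).sum() / len(p))
                    best = min(best, rmsd)
        assert sup.rmsd <= best + 1e-9
        assert best - sup.rmsd < 0.25  # grid resolution


class TestTMScore:
    def test_identical_structures_score_one(self):
        model = build_model(helix_template(40))
        assert tm_score(model, model).score == pytest.approx(1.0)

    def test_rigid_motion_invariance(self, rng):
        template = helix_template(50)
        rot, trans = random_rigid_motion(rng)
        moved = build_model(template @ rot.T + trans)
        assert tm_score(moved, build_model(template)).score == pytest.approx(1.0, abs=1e-9)

    def test_formula_all_distances_at_d0_gives_half(self):
        d0 = tm_d0(70)
        assert tm_from_distances(np.full(70, d0), d0, 70) == pytest.approx(0.5)

    def test_d0_floor_for_short_chains(self):
        assert tm_d0(10) == 0.5
        assert tm_d0(20) == pytest.approx(max(0.5, 1.24 * 5 ** (1 / 3) - 1.8))
        assert tm_d0(100) == pytest.approx(1.24 * 85 ** (1 / 3) - 1.8)

    def test_strictly_decreasing_with_noise(self):
        means = []
        for sd in (0.5, 1.0, 2.0, 4.0):
            scores = []
            for rep in range(20):
                ref, (mod,) = synthdata.synth_structure_pair(
                    synthdata.StructureGenSpec(noise_sd=sd, seed=900 + rep)
                )
                scores.append(tm_score(mod, ref).score)
            means.append(np.mean(scores))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_too_few_pairs_error(self):
        tiny = build_model(np.zeros((2, 3)) + np.arange(2)[:, None])
        with pytest.raises(DegenerateInputError):
            tm_score(tiny, tiny)


class TestLddt:
    def test_identical_structures_score_one(self):
        model = build_model(helix_template(30))
        assert lddt_ca(model, model) == pytest.approx(1.0)

    def test_uniform_3A_perturbation_scores_quarter(self):
        ref = build_model(_equilateral(5.0))
        mod = build_model(_equilateral(8.0))  # every distance off by exactly 3
        assert lddt_ca(mod, ref) == pytest.approx(0.25)

    def test_uniform_10A_perturbation_scores_zero(self):
        ref = build_model(_equilateral(5.0))
        mod = build_model(_equilateral(15.0))
        assert lddt_ca(mod, ref) == pytest.approx(0.0)

    def test_invariant_under_independent_rigid_motions(self, rng):
        ref, (mod,) = synthdata.synth_structure_pair(
            synthdata.StructureGenSpec(noise_sd=1.0, seed=6)
        )
        base = lddt_ca(mod, ref)
        r1, t1 = random_rigid_motion(rng)
        r2, t2 = random_rigid_motion(rng)
        assert lddt_ca(mod.transformed(r1, t1), ref.transformed(r2, t2)) == pytest.approx(base)


class TestPairing:
    def test_identical_sequences_pair_by_index(self):
        model = build_model(helix_template(10), sequence="ACDEFGHIKL")
        pairs = pair_residues(model, model)
        assert pairs == [(i, i) for i in range(10)]

    def test_alignment_pairing_skips_gapped_positions(self):
        a = build_model(helix_template(8), sequence="ACDEFGHI")
        b = build_model(helix_template(6), sequence="ACFGHI")  # DE deleted
        pairs = pair_residues(a, b)
        assert (0, 0) in pairs and (1, 1) in pairs
        assert len(pairs) == 6
        assert all(a.sequence()[i] == b.sequence()[j] for i, j in pairs)


class TestBenchmark:
    def test_member_identical_to_prediction_is_chosen(self):
        template = helix_template(40)
        rng = np.random.default_rng(0)
        m1 = build_model(template + rng.normal(scale=2.0, size=template.shape), model_index=1)
        m2 = build_model(template, model_index=2)
        m3 = build_model(template + rng.normal(scale=2.0, size=template.shape), model_index=3)
        predicted = build_model(template)
        result = benchmark_model(predicted, [m1, m2, m3])
        assert result.chosen_model_index == 2
        assert result.rmsd == pytest.approx(0.0, abs=1e-9)
        assert result.tm_score == pytest.approx(1.0)
        assert result.lddt_ca == pytest.approx(1.0)
        assert result.all_good

    def test_rigidly_moved_copy_flags_good(self, rng):
        template = helix_template(40)
        rot, trans = random_rigid_motion(rng)
        predicted = build_model(template @ rot.T + trans)
        result = benchmark_model(predicted, [build_model(template)])
        assert result.rmsd == pytest.approx(0.0, abs=1e-6)
        assert result.all_good

    def test_single_member_reduces_to_direct_metrics(self):
        ref, (mod,) = synthdata.synth_structure_pair(
            synthdata.StructureGenSpec(noise_sd=1.5, seed=13)
        )
        result = benchmark_model(mod, [ref])
        pairs = pair_residues(mod, ref)
        mob = np.array([mod.residues[i].ca for i, _ in pairs])
        refc = np.array([ref.residues[j].ca for _, j in pairs])
        assert result.rmsd == pytest.approx(kabsch_superpose(mob, refc).rmsd)
        assert result.tm_score == pytest.approx(tm_score(mod, ref).score)
        assert result.lddt_ca == pytest.approx(lddt_ca(mod, ref))

    def test_empty_ensemble_is_error(self):
        model = build_model(helix_template(10))
        with pytest.raises(ValueError):
            benchmark_model(model, [])

    def test_common_rigid_motion_leaves_all_metrics_unchanged(self, rng):
        ref, (mod,) = synthdata.synth_structure_pair(
            synthdata.StructureGenSpec(noise_sd=1.0, seed=17)
        )
        base = benchmark_model(mod, [ref])
        rot, trans = random_rigid_motion(rng)
        moved = benchmark_model(mod.transformed(rot, trans), [ref.transformed(rot, trans)])
        assert moved.rmsd == pytest.approx(base.rmsd, abs=1e-6)
        assert moved.lddt_ca == pytest.approx(base.lddt_ca)
        assert moved.tm_score == pytest.approx(base.tm_score, abs=1e-6)


def test_class_summary_aggregates_mean_and_sd():
    entries = []
    for i, label in enumerate(["class_I", "class_I", "class_II"]):
        ref, (mod,) = synthdata.synth_structure_pair(
            synthdata.StructureGenSpec(noise_sd=1.0, seed=40 + i)
        )
        entries.append((f"p{i}", mod, [ref], label))
    table, summary = structcompare.benchmark_table(entries)
    assert len(table) == 3
    counts = dict(zip(summary["class_label"], summary[("rmsd", "count")]))
    assert counts == {"class_I": 2, "class_II": 1}
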
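"""Superposition, RMSD, TM-score, secondary-structure gain, mean confidence."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import loopbench as lb
from loopbench._geom import rotation_matrix
from loopbench.loops import extract_loops, pair_loops
from loopbench.metrics import (
    kabsch_superpose,
    loop_rmsd,
    mean_plddt,
    tm_d0,
    tm_score,
    tm_score_coords,
)
from loopbench.secstruct import assign_secstruct
from loopbench.structure_io import StructureError


def first_pairs(manifest, k=0):
    exp = lb.read_structure(manifest.exp_path[k], "experimental")
    pred = lb.read_structure(manifest.pred_path[k], "predicted")
    ea, pa = assign_secstruct(exp), assign_secstruct(pred)
    loops = extract_loops(exp, ea)
    pairs, _ = pair_loops(exp, loops, pred, pa)
    return exp, pred, pairs


def random_points(n, seed):
    return np.random.default_rng(seed).normal(size=(n, 3)) * 3.0


class TestKabsch:
    def test_identity(self):
        pts = random_points(6, 0)
        res = kabsch_superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_rigid_transform_recovers_zero(self):
        pts = random_points(8, 1)
        rot = rotation_matrix([0, 0, 1], 90.0)
        moved = pts @ rot.T + np.array([5.0, 5.0, 5.0])
        res = kabsch_superpose(pts, moved)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a, b = rng.normal(size=(2, 5, 3))
            res = kabsch_superpose(a, b)
            assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_agrees_with_scipy_align_vectors(self):
        """Independent cross-check against scipy's Wahba solver."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            fixed = rng.normal(size=(7, 3))
            mobile = rng.normal(size=(7, 3))
            res = kabsch_superpose(fixed, mobile)
            rot, _ = Rotation.align_vectors(fixed - fixed.mean(0),
                                            mobile - mobile.mean(0))
            moved = (mobile - mobile.mean(0)) @ rot.as_matrix().T + fixed.mean(0)
            scipy_rmsd = np.sqrt(np.mean(np.sum((moved - fixed) ** 2, axis=1)))
            assert res.rmsd == pytest.approx(scipy_rmsd, abs=1e-9)

    def test_contract_errors(self):
        pts = random_points(4, 4)
        with pytest.raises(ValueError):
            kabsch_superpose(pts, pts[:3])
        with pytest.raises(ValueError):
            kabsch_superpose(pts[:2], pts[:2])

    def test_degenerate_collinear_flagged(self):
        line = np.array([[float(i), 0.0, 0.0] for i in range(5)])
        res = kabsch_superpose(line, line + 1.0)
        assert res.degenerate
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_symmetry_of_rmsd(self):
        a, b = random_points(6, 5), random_points(6, 6)
        assert kabsch_superpose(a, b).rmsd == pytest.approx(
            kabsch_superpose(b, a).rmsd, abs=1e-9)


class TestTMScore:
    @pytest.mark.parametrize("length,expected", [
        (65, 1.24 * np.cbrt(50.0) - 1.8),   # 2.768 A
        (21, 0.5),                           # raw formula gives 0.453 -> floor
        (22, 0.572066),
        (5, 0.5),
    ])
    def test_d0_formula(self, length, expected):
        assert tm_d0(length) == pytest.approx(expected, abs=1e-4)

    def test_identity_is_one(self):
        pts = random_points(10, 7)
        assert tm_score_coords(pts, pts) == pytest.approx(1.0, abs=1e-9)

    def test_rigid_invariance(self):
        pts = random_points(10, 8)
        rot = rotation_matrix([1, 1, 0], 35.0)
        moved = pts @ rot.T + 2.0
        assert tm_score_coords(pts, moved) == pytest.approx(1.0, abs=1e-6)

    def test_at_least_naive_kabsch_score(self):
        rng = np.random.default_rng(9)
        from loopbench.synthetic_data import build_backbone
        for seed in range(5):
            tors = [(rng.uniform(-150, -60), rng.uniform(80, 170))
                    for _ in range(8)]
            fixed = build_backbone(tors)[:, 1, :]
            mobile = fixed + rng.normal(0, 0.7, fixed.shape)
            sup = kabsch_superpose(fixed, mobile)
            d = np.linalg.norm(sup.apply(mobile) - fixed, axis=1)
            d0 = tm_d0(len(fixed))
            naive = np.mean(1 / (1 + (d / d0) ** 2))
            assert tm_score_coords(fixed, mobile) >= naive - 1e-12

    def test_decreases_with_noise_on_average(self):
        rng = np.random.default_rng(10)
        from loopbench.synthetic_data import build_backbone
        tors = [(rng.uniform(-150, -60), rng.uniform(80, 170)) for _ in range(10)]
        fixed = build_backbone(tors)[:, 1, :]
        means = []
        for sigma in (0.1, 0.4, 1.0):
            vals = [tm_score_coords(fixed, fixed + rng.normal(0, sigma, fixed.shape))
                    for _ in range(8)]
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


class TestPairMetrics:
    def test_identity_pair_metrics(self, bench_manifest):
        exp, _, pairs = first_pairs(bench_manifest)
        from loopbench.loops import LoopPair
        for p in pairs[:3]:
            selfpair = LoopPair(exp=p.exp, pred=p.exp, pair_id=p.pair_id)
            assert loop_rmsd(selfpair) == pytest.approx(0.0, abs=1e-9)

    def test_rmsd_positive_on_noisy_pairs(self, bench_manifest):
        _, _, pairs = first_pairs(bench_manifest)
        for p in pairs:
            assert loop_rmsd(p) > 0
            assert 0 < tm_score(p) <= 1

    def test_atom_set_fallback(self, bench_manifest):
        _, _, pairs = first_pairs(bench_manifest)
        p = pairs[0]
        # strip O atoms from the predicted fragment: backbone falls back to CA
        for r in p.pred.residues:
            r.atoms = [a for a in r.atoms if a.name != "O"]
        ca_only = loop_rmsd(p, atom_set="CA")
        assert loop_rmsd(p, atom_set="backbone") == pytest.approx(ca_only)


class TestDeltaSSE:
    def make_pair(self, n):
        st = lb.make_ideal_segment("coil", n, seed=1)
        loops = extract_loops(st, np.ones(n, dtype=bool), min_len=3)
        from loopbench.loops import LoopPair
        import copy
        pred_loop = copy.deepcopy(loops[0])
        pred_loop.source = "predicted"
        return LoopPair(exp=loops[0], pred=pred_loop, pair_id="t")

    def test_half_helix_is_fifty_percent(self):
        p = self.make_pair(6)
        assert lb.delta_sse(p, "CCCCCC", "CCHHHC") == pytest.approx(50.0)

    def test_identity_classes_zero(self):
        p = self.make_pair(6)
        for classes in ("CCCCCC", "CTSTSC", "HHHHHH"):
            assert lb.delta_sse(p, classes, classes) == 0.0

    def test_fully_helical_hundred(self):
        p = self.make_pair(6)
        assert lb.delta_sse(p, "CCCCCC", "HHHHHH") == pytest.approx(100.0)

    def test_length_mismatch_errors(self):
        p = self.make_pair(6)
        with pytest.raises(StructureError):
            lb.delta_sse(p, "CCC", "CCHHHC")


class TestMeanPlddt:
    def test_atom_weighted_mean(self):
        """3 atoms at 60 + 6 atoms at 90 -> 80 (atom-weighted, not 75)."""
        from loopbench.loops import LoopRegion
        from loopbench.structure_io import Atom, Residue

        def res(seq, n_atoms, b):
            return Residue(aa="A", seq_id=str(seq), name="ALA", atoms=[
                Atom(name=f"C{i}", element="C", coords=np.zeros(3), bfactor=b)
                for i in range(n_atoms)])

        loop = LoopRegion(parent_id="x", chain="A", start=0, end=2,
                          sequence="AA", residues=[res(1, 3, 60.0), res(2, 6, 90.0)],
                          source="predicted")
        assert mean_plddt(loop) == pytest.approx(80.0)

    def test_uniform_and_simple_means(self, bench_manifest):
        _, _, pairs = first_pairs(bench_manifest)
        p = pairs[0]
        for r in p.pred.residues:
            for a in r.atoms:
                a.bfactor = 90.0
        assert mean_plddt(p.pred) == pytest.approx(90.0)

    def test_rejects_experimental_fragment(self, bench_manifest):
        _, _, pairs = first_pairs(bench_manifest)
        with pytest.raises(StructureError):
            mean_plddt(pairs[0].exp)
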
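"""Superposition, pairwise alignment and progressive core construction."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import strucphylo as sp
from strucphylo.corealign import aa_similarity, score_core
from strucphylo.errors import AlignmentError
from strucphylo.structio import Residue, StructureModel


def rigid(seed):
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-30, 30, 3)
    return R, t


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(20, 3))
        sup = sp.kabsch_superpose(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(sup.translation, 0.0, atol=1e-9)

    def test_recovers_known_rigid_motion(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(30, 3)) * 5
        R, t = rigid(3)
        B = A @ R.T + t
        sup = sp.kabsch_superpose(A, B)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(sup.rotation, R, atol=1e-8)
        assert np.allclose(sup.apply(A), B, atol=1e-8)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(15, 3))
        B = rng.normal(size=(15, 3))
        sup = sp.kabsch_superpose(A, B)
        assert np.allclose(sup.rotation.T @ sup.rotation, np.eye(3), atol=1e-8)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_rmsd_recomputable(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(40, 3)) * 4
        B = A + rng.normal(scale=0.7, size=(40, 3))
        sup = sp.kabsch_superpose(A, B)
        d = np.linalg.norm(sup.apply(A) - B, axis=1)
        assert sup.rmsd == pytest.approx(float(np.sqrt(np.mean(d**2))), abs=1e-12)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            sp.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_flagged(self):
        x = np.linspace(0, 10, 12)
        A = np.stack([x, np.zeros(12), np.zeros(12)], axis=1)
        sup = sp.kabsch_superpose(A, A)
        assert sup.degenerate
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_matches_scipy_align_vectors(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(50, 3)) * 6
        B = A @ rigid(7)[0].T + rng.normal(scale=0.5, size=(50, 3))
        sup = sp.kabsch_superpose(A, B)
        rot, rssd = Rotation.align_vectors(B - B.mean(0), A - A.mean(0))
        assert sup.rmsd == pytest.approx(rssd / np.sqrt(len(A)), abs=1e-8)


def two_diverged_models(sigma, seed=0, n=120):
    """Template + noisy, rigidly moved copy with known 1:1 correspondence."""
    template = sp.make_template(n, seed=seed)
    rng = np.random.default_rng(seed + 100)
    R, t = rigid(seed + 200)
    coords = template.coords + rng.normal(scale=sigma, size=(n, 3))
    res = [Residue(i + 1, template.residues[i].aa, R @ coords[i] + t, 95.0)
           for i in range(n)]
    return template, StructureModel(model_id="b", residues=res)


class TestAlignPair:
    def test_self_alignment(self):
        m = sp.make_template(100, seed=5)
        al = sp.align_pair(m, m)
        assert len(al.pairs) == 100
        assert al.pairs == [(i, i) for i in range(1, 101)]
        assert al.rmsd == pytest.approx(0.0, abs=1e-9)
        assert al.score == pytest.approx(sp.self_score(m), abs=1e-6)

    def test_rigid_copy_full_length(self):
        m = sp.make_template(100, seed=6)
        R, t = rigid(8)
        copy = m.transformed(R, t)
        copy.model_id = "copy"
        al = sp.align_pair(m, copy)
        assert len(al.pairs) == 100
        assert al.rmsd <= 1e-6
        assert al.score == pytest.approx(sp.self_score(m), rel=1e-9)

    @pytest.mark.parametrize("sigma", [0.5, 1.0])
    def test_ground_truth_pairing(self, sigma):
        a, b = two_diverged_models(sigma, seed=3)
        al = sp.align_pair(a, b)
        assert len(al.pairs) >= 0.90 * len(a)
        correct = sum(p == q for p, q in al.pairs)
        assert correct >= 0.95 * len(al.pairs)

    def test_too_short_model_rejected(self):
        m = sp.make_template(60, seed=1)
        short = m.subset(range(1, 21))
        with pytest.raises(AlignmentError):
            sp.align_pair(short, short)

    def test_sequence_swapped_segments_realigned(self):
        """Two 40-residue segments swapped in sequence order but not in
        space: the aligner must still recover the spatial correspondence."""
        a, b = two_diverged_models(0.5, seed=9)
        order = list(range(120))
        order[10:50], order[60:100] = order[60:100], order[10:50]
        res = [Residue(i + 1, b.residues[k].aa, b.residues[k].ca_coord, 95.0)
               for i, k in enumerate(order)]
        b_swapped = StructureModel(model_id="swap", residues=res)
        al = sp.align_pair(a, b_swapped)
        # ground truth: position in a <-> where that residue moved in b_swapped
        truth = {order[i] + 1: i + 1 for i in range(120)}
        correct = sum(truth[p] == q for p, q in al.pairs)
        assert correct >= 0.90 * len(al.pairs)
        assert len(al.pairs) >= 0.90 * 120


class TestScoresAndInvariants:
    def test_score_symmetric_and_dominant(self, low_noise_core):
        _, _, _, scores = low_noise_core
        assert np.allclose(scores.S, scores.S.T, atol=1e-9)
        diag = np.diag(scores.S)
        assert np.all(scores.S <= np.minimum.outer(diag, diag) + 1e-9)

    def test_rigid_motion_invariance(self, low_noise_dataset):
        models, _, _ = low_noise_dataset
        core, scores = sp.build_core(models[:4] if len(models) > 4 else models)
        R, t = rigid(11)
        moved = [models[0].transformed(R, t)] + list(models[1:4])
        core2, scores2 = sp.build_core(moved)
        assert len(core2) == len(core) or abs(len(core2) - len(core)) <= 2
        ids = scores.ids
        # compare on the shared column count via normalized per-column score
        s1 = scores.S / len(core)
        s2 = scores2.S / len(core2)
        assert np.allclose(s1, s2, atol=1e-6)

    def test_column_additivity(self, low_noise_core):
        _, _, core, scores = low_noise_core
        total = scores.contrib.sum(axis=2)
        assert np.allclose(total, scores.S, atol=1e-10)

    def test_restrict_scores_all_columns_is_identity(self, low_noise_core):
        _, _, core, scores = low_noise_core
        sub = sp.restrict_scores(scores, np.arange(len(core)))
        assert np.allclose(sub.S, scores.S, atol=1e-12)

    def test_restrict_scores_single_column(self, low_noise_core):
        _, _, core, scores = low_noise_core
        sub = sp.restrict_scores(scores, [7])
        assert np.allclose(sub.S, scores.contrib[:, :, 7], atol=1e-12)

    def test_restrict_scores_random_subset_matches_bruteforce(self, low_noise_core):
        _, _, core, scores = low_noise_core
        rng = np.random.default_rng(0)
        cols = np.sort(rng.choice(len(core), size=len(core) // 2, replace=False))
        sub = sp.restrict_scores(scores, cols)
        brute = np.zeros_like(scores.S)
        for c in cols:
            brute += scores.contrib[:, :, c]
        assert np.allclose(sub.S, brute, atol=1e-12)

    def test_restrict_scores_empty_subset_rejected(self, low_noise_core):
        _, _, _, scores = low_noise_core
        with pytest.raises(ValueError):
            sp.restrict_scores(scores, [])

    def test_aa_similarity_range_and_diagonal_dominance(self):
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for x in aas:
            for y in aas:
                v = aa_similarity(x, y)
                assert 0.0 <= v <= 1.0
                assert v <= min(aa_similarity(x, x), aa_similarity(y, y)) + 1e-12
        assert aa_similarity("X", "A") == 0.0


class TestBuildCore:
    def test_three_identical_copies(self):
        m = sp.make_template(90, seed=12)
        copies = []
        for k in range(3):
            R, t = rigid(20 + k)
            c = m.transformed(R, t)
            c.model_id = f"c{k}"
            copies.append(c)
        core, scores = sp.build_core(copies)
        assert len(core) == 90
        assert core.avg_rmsd == pytest.approx(0.0, abs=1e-6)

    def test_low_noise_core_covers_template(self):
        spec = sp.SimulationSpec(n_leaves=4, template_len=100,
                                 noise_per_unit_branch=0.3,
                                 spatial_correlation_length=2.0, seed=21)
        models, _, _ = sp.simulate_dataset(spec)
        core, _ = sp.build_core(models)
        assert len(core) >= 0.95 * 100

    def test_inserted_loop_excluded_from_core(self):
        spec = sp.SimulationSpec(n_leaves=4, template_len=100,
                                 noise_per_unit_branch=0.3,
                                 spatial_correlation_length=2.0, seed=22)
        models, _, template = sp.simulate_dataset(spec)
        # splice a 30-residue excursion loop into one model
        m = models[0]
        at = 50
        rng = np.random.default_rng(5)
        direction = np.array([0.0, 0.0, 1.0])
        base_pt = m.residues[at - 1].ca_coord
        loop_pts = [base_pt + direction * 3.8 * (k + 1)
                    + rng.normal(scale=0.2, size=3) for k in range(30)]
        res = list(m.residues[:at])
        res += [Residue(1, "A", p, 95.0) for p in loop_pts]
        res += list(m.residues[at:])
        res = [Residue(i + 1, r.aa, r.ca_coord, r.plddt)
               for i, r in enumerate(res)]
        models[0] = StructureModel(model_id=m.model_id, residues=res)
        core, _ = sp.build_core(models)
        shortest = min(len(x) for x in models)
        assert len(core) <= shortest
        # inserted positions (at+1 .. at+30 in model 0) never enter the core
        inserted = set(range(at + 1, at + 31))
        used = {c.members[m.model_id] for c in core.columns}
        assert not (used & inserted)

    def test_core_rmsd_matches_pairwise_mean(self, low_noise_core):
        models, _, core, _ = low_noise_core
        import itertools
        vals = []
        for a, b in itertools.combinations(core.model_ids, 2):
            ma = next(x for x in models if x.model_id == a)
            mb = next(x for x in models if x.model_id == b)
            xa = ma.coords[core.positions(a)]
            xb = mb.coords[core.positions(b)]
            vals.append(sp.kabsch_superpose(xa, xb).rmsd)
        assert sp.core_rmsd(core, models) == pytest.approx(np.mean(vals), abs=1e-9)

    def test_fewer_than_three_models_rejected(self):
        m = sp.make_template(80, seed=30)
        with pytest.raises(AlignmentError):
            sp.build_core([m])

    def test_unalignable_model_excluded(self, caplog):
        spec = sp.SimulationSpec(n_leaves=3, template_len=100,
                                 noise_per_unit_branch=0.3,
                                 spatial_correlation_length=2.0, seed=23)
        models, _, _ = sp.simulate_dataset(spec)
        rng = np.random.default_rng(0)
        blob = [Residue(i + 1, "A", rng.normal(scale=30.0, size=3), 95.0)
                for i in range(100)]
        models.append(StructureModel(model_id="blob", residues=blob))
        with caplog.at_level("WARNING"):
            core, scores = sp.build_core(models)
        assert "blob" not in core.model_ids
        with pytest.raises(AlignmentError):
            sp.build_core(models, strict=True)
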
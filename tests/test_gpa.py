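"""Procrustes superimposition, bending energy, and semilandmark sliding."""

import numpy as np
import pytest

from cranioforge.gpa import (
    GeneralizedProcrustes,
    bending_energy,
    bending_energy_matrix,
    centroid_size,
    gpa,
    procrustes_distance,
    slide_semilandmarks,
)
from conftest import rotation


def random_similarity_copies(base, n, rng):
    out = []
    for _ in range(n):
        s = rng.uniform(0.5, 2.0)
        out.append(s * base @ rotation(rng.uniform(0, 2 * np.pi)).T + rng.normal(size=2))
    return np.stack(out)


class TestCentroidSize:
    def test_square_closed_form(self):
        pts = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], dtype=float)
        assert centroid_size(pts) == pytest.approx(np.sqrt(8))

    def test_homogeneity_and_translation(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(9, 2))
        cs = centroid_size(pts)
        assert centroid_size(2 * pts) == pytest.approx(2 * cs)
        assert centroid_size(pts + [5, -3]) == pytest.approx(cs)

    def test_degenerate(self):
        with pytest.raises(ValueError):
            centroid_size(np.zeros((4, 2)))


class TestGpa:
    def test_similarity_copies_align_exactly(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(12, 2))
        ds = gpa(random_similarity_copies(base, 10, rng))
        for i in range(10):
            for j in range(i):
                d = np.sqrt(np.sum((ds.aligned[i] - ds.aligned[j]) ** 2))
                assert d < 1e-9

    def test_unit_size_centred_invariants(self, small_dataset):
        ds = gpa(small_dataset.landmarks)
        for cfg in ds.aligned:
            assert np.allclose(cfg.mean(axis=0), 0, atol=1e-8)
            assert np.sqrt(np.sum(cfg**2)) == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(ds.aligned.mean(axis=0), ds.consensus, atol=1e-12)

    def test_two_shape_distance_matches_rotation_grid_oracle(self):
        """Procrustes distance equals the brute-force minimum over a fine
        rotation grid (10^6 angles)."""
        A = np.array([[0, 0], [2, 0], [1, 1.5]], dtype=float)
        B = np.array([[0, 0.1], [1.8, -0.2], [0.7, 1.9]], dtype=float)
        d = procrustes_distance(A, B)
        Ac = A - A.mean(0); Ac /= np.sqrt((Ac**2).sum())
        Bc = B - B.mean(0); Bc /= np.sqrt((Bc**2).sum())
        thetas = np.linspace(0, 2 * np.pi, 10**6, endpoint=False)
        # ||B R - A||^2 = 2 - 2 (cos t * (M00+M11) + sin t * (M10-M01)), M = B^T A
        M = Bc.T @ Ac
        d2 = 2 - 2 * (np.cos(thetas) * (M[0, 0] + M[1, 1]) + np.sin(thetas) * (M[1, 0] - M[0, 1]))
        assert d == pytest.approx(np.sqrt(d2.min()), abs=1e-5)

    def test_reflection_not_matched(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(8, 2))
        mirrored = base @ np.diag([-1.0, 1.0])
        ds = gpa(np.stack([base, mirrored]))
        d = np.sqrt(np.sum((ds.aligned[0] - ds.aligned[1]) ** 2))
        assert d > 0.1

    def test_invariant_to_input_similarity_transforms(self, small_dataset):
        rng = np.random.default_rng(4)
        arr = np.stack([c.points for c in small_dataset.landmarks[:8]])
        ds1 = gpa(arr)
        moved = np.stack([
            rng.uniform(0.5, 2) * a @ rotation(rng.uniform(0, 2 * np.pi)).T + rng.normal(size=2)
            for a in arr
        ])
        ds2 = gpa(moved)
        np.testing.assert_allclose(ds1.aligned, ds2.aligned, atol=1e-6)

    def test_degenerate_configuration_named(self):
        arr = np.stack([np.random.default_rng(0).normal(size=(5, 2)), np.zeros((5, 2))])
        with pytest.raises(ValueError, match="spec_1"):
            gpa(arr)


class TestBendingEnergy:
    def test_affine_null_space(self, template):
        B = bending_energy_matrix(template.points)
        rng = np.random.default_rng(5)
        A = rng.normal(size=(2, 2))
        aff = template.points @ A.T + rng.normal(size=2)
        assert abs(bending_energy(B, aff)) < 1e-9

    def test_exactly_three_zero_eigenvalues(self, template):
        w = np.linalg.eigvalsh(bending_energy_matrix(template.points))
        assert np.all(w > -1e-9)
        assert int(np.sum(np.abs(w) < 1e-9)) == 3

    def test_symmetry(self, template):
        B = bending_energy_matrix(template.points)
        np.testing.assert_allclose(B, B.T, atol=1e-12)

    def test_four_point_closed_form_oracle(self):
        """Energy of a displaced square matches direct evaluation of the TPS
        functional: solve L [w; a] = [v; 0] and evaluate w^T K w."""
        ref = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        target = ref.copy()
        target[2] += [0.0, 0.3]
        B = bending_energy_matrix(ref)

        k = ref.shape[0]
        d2 = np.sum((ref[:, None] - ref[None, :]) ** 2, axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            K = np.where(d2 > 0, d2 * np.log(d2), 0.0)
        Q = np.column_stack([np.ones(k), ref])
        L = np.block([[K, Q], [Q.T, np.zeros((3, 3))]])
        energy = 0.0
        for dim in range(2):
            rhs = np.concatenate([target[:, dim], np.zeros(3)])
            w = np.linalg.solve(L, rhs)[:k]
            energy += w @ K @ w
        assert bending_energy(B, target) == pytest.approx(energy, abs=1e-8)

    def test_collinear_reference_rejected(self):
        pts = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(ValueError, match="collinear"):
            bending_energy_matrix(pts)


class TestSliding:
    def test_specimen_equal_to_consensus_does_not_move(self, template):
        tpl = template.points - template.points.mean(axis=0)
        tpl = tpl / np.sqrt((tpl**2).sum())
        arr = np.stack([tpl, tpl])
        est = GeneralizedProcrustes(n_slide_cycles=1).fit(
            arr, roles=template.roles, curves=template.curves
        )
        assert est.max_slide_ < 1e-10

    def test_tangential_displacement_recovered(self, template):
        """A semilandmark pushed along its own tangent slides back: the
        post-slide bending energy vanishes."""
        tpl = template.points - template.points.mean(axis=0)
        tpl = tpl / np.sqrt((tpl**2).sum())
        moved = tpl.copy()
        curve = template.curves[0]
        j = curve[5]
        tangent = tpl[curve[6]] - tpl[curve[4]]
        tangent /= np.linalg.norm(tangent)
        moved[j] += 0.004 * tangent
        est = GeneralizedProcrustes(n_slide_cycles=1).fit(
            np.stack([tpl, moved]), roles=template.roles, curves=template.curves
        )
        before, after = est.bending_energy_path_[0][1]  # second specimen
        assert after < before
        assert after < 1e-7

    def test_energy_non_increasing_over_cycles(self, small_dataset):
        est = GeneralizedProcrustes(n_slide_cycles=3).fit(small_dataset.landmarks[:10])
        for cycle in est.bending_energy_path_:
            before, after = cycle[:, 0], cycle[:, 1]
            assert np.all(after <= before + 1e-12)

    def test_sliding_without_semilandmarks_is_identity(self):
        rng = np.random.default_rng(6)
        arr = rng.normal(size=(5, 10, 2))
        ds0 = gpa(arr)
        ds1 = slide_semilandmarks(ds0, n_cycles=2)
        np.testing.assert_allclose(ds0.aligned, ds1.aligned, atol=1e-12)
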
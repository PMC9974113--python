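import numpy as np
import pytest

from lungrepair.gvf_snake import (
    GVFConfig,
    GVFField,
    SnakeConfig,
    SnakeState,
    apply_corrections,
    compute_gvf,
    correct_block,
    edge_map,
    evolve,
    init_contour,
    interior_mask,
    internal_matrix,
    outward_normals,
    polygon_area,
)
from lungrepair.recognize import BlockRegion, RectRC
from .conftest import disk_mask, notched_disk


def snake_setup(block, cfg=None, gvf=None):
    cfg = cfg or SnakeConfig()
    field = compute_gvf(edge_map(block, cfg.sigma_edge), gvf or GVFConfig())
    state = init_contour(block.shape, cfg.n_points)
    A = internal_matrix(cfg.n_points, cfg.lambda1, cfg.lambda2)
    return state, field, A, cfg


class TestEdgeMap:
    def test_constant_block_gives_zero(self):
        f = edge_map(np.ones((32, 32), np.uint8), 1.2)
        assert (f == 0).all()

    def test_step_edge_ridge_position_and_symmetry(self):
        block = np.zeros((64, 64), np.uint8)
        block[:, 32:] = 1
        f = edge_map(block, 1.2)
        interior = f[20:44]  # away from the constant-padded frame
        cols = interior.argmax(axis=1)
        assert (np.abs(cols - 31.5) <= 1).all()  # ridge at the step
        np.testing.assert_allclose(interior[:, 28], interior[:, 35], rtol=0.05)

    def test_step_profile_matches_gaussian_derivative(self):
        """The cross-edge profile is the squared Gaussian-smoothed delta."""
        sigma = 2.0
        block = np.zeros((64, 64), np.uint8)
        block[:, 32:] = 1
        f = edge_map(block, sigma)
        x = np.arange(64) - 31.5
        analytic = np.exp(-(x**2) / (2 * sigma**2)) ** 2
        profile = f[32] / f[32].max()
        np.testing.assert_allclose(profile[24:40], analytic[24:40] / analytic.max(), atol=0.05)

    def test_normalized_to_unit_maximum(self):
        f = edge_map(notched_disk(), 1.2)
        assert f.min() >= 0 and f.max() == 1.0


class TestGVF:
    def test_constant_edge_map_gives_zero_field(self):
        field = compute_gvf(np.full((32, 32), 0.3), GVFConfig(n_iter=50))
        assert np.abs(field.u).max() == 0 and np.abs(field.v).max() == 0

    def test_field_matches_gradient_at_strong_ridge(self):
        """Where the squared edge-gradient weight is large the data term
        pins (u, v) to the edge-map gradient. The edge is "strong" relative
        to the diffusion weight, so the check uses a small mu; larger mu
        trades edge fidelity for capture range."""
        block = np.zeros((64, 64), np.uint8)
        block[:, 32:] = 1
        f = edge_map(block, 1.2)
        field = compute_gvf(f, GVFConfig(mu=0.02, n_iter=80))
        fr, fc = np.gradient(f)
        row = 32
        for col in (np.argmax(fc[row]), np.argmin(fc[row])):
            assert abs(field.u[row, col] - fc[row, col]) <= 0.10 * abs(fc[row, col])
        # far from the edge the diffused field is nonzero and smooth
        far = np.hypot(field.u[:, 5], field.v[:, 5])
        assert far.max() > 0
        assert np.abs(np.diff(field.u[20:44, 5])).max() < 0.01

    def test_stability_bound_enforced(self):
        with pytest.raises(ValueError, match="stability"):
            GVFConfig(mu=0.5, dt=1.0)


class TestContourAndMatrix:
    def test_init_square_four_points_hit_corners(self):
        st = init_contour((100, 100), 4, inset=2.0)
        pts = sorted(zip(st.ys, st.xs))
        assert pts == [(2.0, 2.0), (2.0, 97.0), (97.0, 2.0), (97.0, 97.0)]

    def test_init_spacing_uniform_along_perimeter(self):
        st = init_contour((80, 50), 40)
        # arc length along the rectangle (L1 between consecutive points is
        # exact off the corners; corner-straddling chords are shorter)
        d = np.hypot(np.diff(np.r_[st.xs, st.xs[0]]), np.diff(np.r_[st.ys, st.ys[0]]))
        nominal = (2.0 * ((80 - 5) + (50 - 5))) / 40
        assert d.max() <= nominal + 1e-9
        assert d.min() >= nominal / np.sqrt(2) - 1e-9

    def test_init_too_small_block(self):
        with pytest.raises(ValueError):
            init_contour((5, 5), 16, inset=3.0)

    def test_matrix_annihilates_constants(self):
        A = internal_matrix(32, 0.04, 3.0)
        out = A.apply(np.full(32, 7.3))
        np.testing.assert_allclose(out, 0, atol=1e-10)

    def test_matrix_eigenvalue_identity_on_cosine(self):
        n, lam1, lam2 = 40, 0.04, 3.0
        A = internal_matrix(n, lam1, lam2)
        m = 3
        theta = 2 * np.pi * m / n
        vec = np.cos(theta * np.arange(n))
        expected = (lam1 * (2 * np.cos(theta) - 2) - lam2 * (2 * np.cos(theta) - 2) ** 2) * vec
        np.testing.assert_allclose(A.apply(vec), expected, atol=1e-10)

    def test_solve_inverse_consistency(self):
        n, gamma = 24, 1.0
        A = internal_matrix(n, 0.04, 3.0)
        rng = np.random.default_rng(0)
        x = rng.random(n)
        M = gamma * np.eye(n) - A.dense
        np.testing.assert_allclose(np.linalg.solve(M, M @ x), x, atol=1e-10)

    def test_matrix_requires_five_points(self):
        with pytest.raises(ValueError):
            internal_matrix(4, 0.04, 3.0)


class TestNormals:
    def circle_state(self, n=64, r=10.0, reverse=False):
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        if reverse:
            t = t[::-1]
        return SnakeState(xs=20 + r * np.cos(t), ys=20 + r * np.sin(t))

    def test_circle_normals_are_radial(self):
        st = self.circle_state()
        normals = outward_normals(st)
        radial = np.stack([(st.xs - 20) / 10.0, (st.ys - 20) / 10.0], axis=1)
        np.testing.assert_allclose(normals, radial, atol=1e-3)

    def test_reversal_preserves_outward_orientation(self):
        """The signed-area test keeps normals outward whichever way the
        contour is traversed; the unoriented tangent rotation alone flips."""
        a = outward_normals(self.circle_state())
        b = outward_normals(self.circle_state(reverse=True))
        np.testing.assert_allclose(a, b[::-1], atol=1e-12)

    def test_unit_norm(self):
        normals = outward_normals(self.circle_state(n=48, r=7.3))
        np.testing.assert_allclose(np.hypot(normals[:, 0], normals[:, 1]), 1.0, atol=1e-12)

    def test_coincident_points_rejected(self):
        st = SnakeState(xs=np.zeros(16), ys=np.zeros(16))
        with pytest.raises(ValueError, match="degenerate"):
            outward_normals(st)


class TestEvolve:
    def test_pure_smoothing_shrinks_area_monotonically(self):
        block = np.zeros((101, 101), np.uint8)
        cfg = SnakeConfig(kappa1=0.0, kappa2=0.0, max_iter=50, tol=0.0)
        field = GVFField(
            u=np.zeros((101, 101)), v=np.zeros((101, 101)), f=block.astype(float)
        )
        state = init_contour(block.shape, cfg.n_points)
        A = internal_matrix(cfg.n_points, cfg.lambda1, cfg.lambda2)
        rec = []
        evolve(state, field, A, cfg, record=rec)
        areas = [abs(polygon_area(xs, ys)) for xs, ys in rec]
        assert len(areas) == 50
        assert all(a2 <= a1 + 1e-9 for a1, a2 in zip(areas, areas[1:]))

    def test_disk_convergence_to_analytic_circle(self):
        block = disk_mask((101, 101), (50, 50), 30)
        state, field, A, cfg = snake_setup(block)
        final = evolve(state, field, A, cfg)
        dist = np.abs(np.hypot(final.xs - 50, final.ys - 50) - 30)
        assert dist.mean() <= 1.5

    def test_infinite_gamma_limit_is_a_fixed_point(self):
        block = np.zeros((64, 64), np.uint8)
        cfg = SnakeConfig(kappa1=0.0, kappa2=0.0, gamma=1e9, max_iter=1, tol=0.0)
        field = GVFField(u=np.zeros((64, 64)), v=np.zeros((64, 64)), f=block.astype(float))
        state = init_contour(block.shape, cfg.n_points)
        A = internal_matrix(cfg.n_points, cfg.lambda1, cfg.lambda2)
        final = evolve(state, field, A, cfg)
        np.testing.assert_allclose(final.xs, state.xs, atol=1e-6)
        np.testing.assert_allclose(final.ys, state.ys, atol=1e-6)

    def test_iteration_cap_and_bookkeeping(self):
        block = disk_mask((64, 64), (32, 32), 18)
        cfg = SnakeConfig(max_iter=7, tol=0.0)
        state, field, A, _ = snake_setup(block, cfg)
        final = evolve(state, field, A, cfg)
        assert final.iteration == 7
        assert np.isfinite(final.mean_step)


class TestInterior:
    def test_square_contour_pixel_count(self):
        st = SnakeState(
            xs=np.array([10.0, 20.0, 20.0, 10.0]), ys=np.array([10.0, 10.0, 20.0, 20.0])
        )
        m = interior_mask(st, (32, 32))
        assert m.sum() == 11 * 11
        assert m[10:21, 10:21].all()

    def test_disk_contour_area(self):
        t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        st = SnakeState(xs=50 + 30 * np.cos(t), ys=50 + 30 * np.sin(t))
        m = interior_mask(st, (101, 101))
        assert abs(m.sum() - np.pi * 30**2) / (np.pi * 30**2) < 0.05

    def test_degenerate_contour_rejected(self):
        st = SnakeState(xs=np.linspace(0, 10, 16), ys=np.zeros(16))
        with pytest.raises(ValueError, match="degenerate"):
            interior_mask(st, (32, 32))


class TestCorrectBlock:
    def flagged_block(self, block):
        h, w = block.shape
        return BlockRegion(
            line_id=0,
            orig_rect=RectRC(0, 0, h, w),
            ext_rect=RectRC(0, 0, h, w),
            block=block,
            descriptor=None,
            flagged=True,
        )

    def test_requires_flagged(self):
        blk = self.flagged_block(disk_mask((64, 64), (32, 32), 20))
        blk.flagged = False
        with pytest.raises(ValueError, match="flagged"):
            correct_block(blk)

    def test_smooth_block_nearly_unchanged(self):
        block = disk_mask((101, 101), (50, 50), 30)
        corrected = correct_block(self.flagged_block(block))
        assert (corrected >= block).all()
        added = (corrected == 1) & (block == 0)
        # any additions hug the contour: within a 2-px band of the disk edge
        rr, cc = np.nonzero(added)
        if len(rr):
            assert np.abs(np.hypot(rr - 50.0, cc - 50.0) - 30).max() <= 2.0

    def test_notched_block_recovers_most_of_the_notch(self, small_lung_case):
        """The principal notch block of the fixture refills >= 80% of the
        carved pixels that fall inside its extended rectangle."""
        from lungrepair import RecognitionConfig
        from lungrepair.sift import detect, keypoint_pixels
        from lungrepair.supportive import (
            extract_boundary,
            project_to_boundary,
            split_lines,
            supportive_mask,
        )
        from lungrepair.recognize import build_blocks

        mask = small_lung_case.defective
        truth = small_lung_case.truth
        boundary = extract_boundary(mask)
        anchors = project_to_boundary(
            keypoint_pixels(detect(mask.astype(float)), mask.shape), boundary
        )
        lines = split_lines(supportive_mask(boundary, anchors, 20.0), 5)
        blocks = [b for b in build_blocks(mask, lines, RecognitionConfig()) if b.flagged]
        assert blocks
        s = small_lung_case.notches[0]
        rr = np.arange(mask.shape[0])[:, None]
        cc = np.arange(mask.shape[1])[None, :]
        notch = (rr - s.center.row) ** 2 + (cc - s.center.col) ** 2 <= s.radius**2
        lost = notch & (truth == 1) & (mask == 0)
        best, best_lost = None, 0
        for blk in blocks:
            inside = lost[blk.ext_rect.slices].sum()
            if inside > best_lost:
                best, best_lost = blk, inside
        assert best is not None and best_lost > 0
        corrected = correct_block(best)
        recovered = (lost[best.ext_rect.slices] & (corrected == 1)).sum()
        assert recovered >= 0.8 * best_lost

    def test_union_definition_holds(self):
        block = notched_disk()
        corrected = correct_block(self.flagged_block(block))
        # nothing outside (interior | original) can appear, and the original
        # is always preserved
        assert ((corrected == 1) | (block == 0)).all()
        assert (corrected[block == 1] == 1).all()


class TestApplyCorrections:
    def test_zero_flagged_is_identity(self, small_lung_case):
        out = apply_corrections(small_lung_case.defective, [], [])
        np.testing.assert_array_equal(out, small_lung_case.defective)

    def test_output_contains_input(self):
        mask = disk_mask((64, 64), (32, 32), 20)
        blk = BlockRegion(
            line_id=0,
            orig_rect=RectRC(10, 10, 30, 30),
            ext_rect=RectRC(5, 5, 35, 35),
            block=mask[5:35, 5:35].copy(),
            descriptor=None,
            flagged=True,
        )
        corrected_crop = np.ones((30, 30), np.uint8)
        out = apply_corrections(mask, [blk], [corrected_crop])
        assert (out >= mask).all()
        # only the OR portion was written
        assert out[9, 9] == mask[9, 9]
        assert out[15, 15] == 1

    def test_misaligned_lists_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            apply_corrections(disk_mask((16, 16), (8, 8), 4), [], [None])
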
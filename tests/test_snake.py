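"""Greedy active contour: energies, iteration, node management, propagation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vtseg as v
import vtseg.snake as sn


def _flat_grad(shape=(64, 64)):
    return sn.GradientImage(np.zeros(shape))


class TestInitCircle:
    def test_nodes_on_circle_counter_clockwise(self):
        c = v.init_circle((50, 50), 10, 8)
        d = np.hypot(*(c.nodes - 50).T)
        np.testing.assert_allclose(d, 10.0, atol=1e-12)
        angles = np.arctan2(c.nodes[:, 1] - 50, c.nodes[:, 0] - 50)
        assert np.all(np.diff(np.unwrap(angles)) > 0)

    def test_default_sizing_rule_targets_double_smin_spacing(self):
        n = v.default_node_count(10.0, 3.0)
        assert n == int(np.ceil(2 * np.pi * 10 / 6.0))
        spacing = v.init_circle((0, 0), 10.0, n).spacings()
        assert np.all(spacing >= 3.0) and np.all(spacing <= 12.0)

    def test_polygon_area_close_to_circle(self):
        c = v.init_circle((0, 0), 10, 64)
        assert v.contour_area(c, 1.0) == pytest.approx(np.pi * 100, rel=5e-3)


class TestNodeEnergy:
    def test_first_slice_has_zero_deviation_term(self):
        p = v.SnakeParams(alpha=0, beta=0, gamma=0, delta=5.0, normalize=False)
        c = v.init_circle((32, 32), 10, 8)
        e = v.node_energy(c, 0, c.nodes[0] + (1, 0), _flat_grad(), None, p)
        assert e == 0.0

    def test_unnormalized_deviation_is_distance_to_fourth(self):
        p = v.SnakeParams(alpha=0, beta=0, gamma=0, delta=1.0, normalize=False)
        c = v.init_circle((32, 32), 10, 8)
        cand = c.nodes[0] + np.array([1.0, 0.0])
        prev = v.Contour(cand[None] + [[2.0, 0.0], [30.0, 0.0], [0.0, 30.0]])
        e = v.node_energy(c, 0, cand, _flat_grad(), prev, p)
        assert e == pytest.approx(2.0 ** 4)

    def test_uniform_image_external_term_identical_everywhere(self):
        p = v.SnakeParams(alpha=0, beta=0, gamma=3.0, delta=0)
        c = v.init_circle((32, 32), 10, 8)
        grad = _flat_grad()
        es = [v.node_energy(c, 0, c.nodes[0] + (du, dv), grad, None, p)
              for du in (-1, 0, 1) for dv in (-1, 0, 1)]
        assert np.ptp(es) == 0.0

    def test_out_of_bounds_candidate_is_infinite(self):
        p = v.SnakeParams()
        c = v.init_circle((2, 2), 1.5, 6)
        e = v.node_energy(c, 0, (-5.0, 0.0), _flat_grad((8, 8)), None, p)
        assert np.isinf(e)


class TestGreedyIterate:
    def test_fixed_point_on_strong_edge(self):
        """A contour whose nodes sit on gradient maxima does not move when only
        the edge term acts."""
        uu, vv = np.mgrid[0:64, 0:64]
        ring = np.hypot(uu - 32, vv - 32)
        # binary ridge: every on-ring pixel is a window maximum (ties keep
        # the current position)
        grad = sn.GradientImage((np.round(ring) == 20.0).astype(float))
        p = v.SnakeParams(alpha=0, beta=0, gamma=1.0, delta=0)
        c = v.Contour(np.round(v.init_circle((32, 32), 20, 16).nodes))
        assert np.all(grad.sample(c.nodes) == 1.0)
        out, moved = v.greedy_iterate(v.Contour(c.nodes.copy()), grad, None, p)
        assert moved == 0
        np.testing.assert_array_equal(out.nodes, c.nodes)

    def test_node_moves_up_gradient_ramp(self):
        """With only the edge term and a ramped edge map, every node moves one
        pixel toward stronger gradients per pass."""
        ramp = np.tile(np.arange(64.0), (64, 1))  # increases along v
        grad = sn.GradientImage(ramp)
        p = v.SnakeParams(alpha=0, beta=0, gamma=1.0, delta=0)
        c = v.init_circle((32, 30), 6, 8)
        out, moved = v.greedy_iterate(c, grad, None, p)
        assert moved == len(c)
        np.testing.assert_allclose(out.nodes[:, 1] - c.nodes[:, 1], 1.0)

    def test_greedy_choice_matches_exhaustive_window_search(self, disk_image):
        """Dual route: replaying the pass node by node with node_energy over
        every window candidate reproduces greedy_iterate exactly."""
        img, center, r = disk_image
        grad = sn.GradientImage.from_image(img)
        p = v.SnakeParams()
        c = v.init_circle(center, 25, 20)
        prev = v.init_circle(center, 26, 18)

        expected = v.Contour(c.nodes.copy())
        half = p.window // 2
        for i in range(len(expected)):
            cands = []
            for du in range(-half, half + 1):
                for dv in range(-half, half + 1):
                    cands.append(expected.nodes[i] + (du, dv))
            es = [v.node_energy(expected, i, cand, grad, prev, p) for cand in cands]
            # tie-break: current position, then offset magnitude, then row-major
            offs = [(du, dv) for du in range(-half, half + 1)
                    for dv in range(-half, half + 1)]
            order = sorted(range(len(offs)),
                           key=lambda k: (offs[k] != (0, 0),
                                          offs[k][0] ** 2 + offs[k][1] ** 2, k))
            best = min(order, key=lambda k: (es[k], order.index(k)))
            expected.nodes[i] = cands[best]

        out, _ = v.greedy_iterate(v.Contour(c.nodes.copy()), grad, prev, p)
        np.testing.assert_allclose(out.nodes, expected.nodes, atol=1e-12)

    def test_disk_expansion_is_monotone_until_edge(self, disk_image):
        img, center, r = disk_image
        from scipy import ndimage

        grad = sn.GradientImage(ndimage.gaussian_filter(
            sn.GradientImage.from_image(img).values, 4.0))
        p = v.SnakeParams()
        c = v.init_circle(center, 15, 16)
        radii = [15.0]
        for _ in range(25):
            c, moved = v.greedy_iterate(c, grad, None, p)
            c = v.resample_nodes(c, p)
            radii.append(float(np.hypot(*(c.nodes - np.asarray(center)).T).mean()))
        inside = [rad for rad in radii if rad < r - 2]
        assert all(b >= a - 0.3 for a, b in zip(inside, inside[1:]))
        assert radii[-1] > r - 3


class TestResampleNodes:
    def test_midpoint_inserted_beyond_smax(self):
        p = v.SnakeParams(s_min=3, s_max=12)
        nodes = np.array([[0, 0], [13, 0], [13, 13]], float)
        out = v.resample_nodes(v.Contour(nodes), p)
        assert len(out) == 6  # every 13 px side gets a midpoint (incl. closing)
        assert np.all(out.spacings() <= 12.0 + 1e-9)

    def test_close_pair_deleted(self):
        p = v.SnakeParams(s_min=3, s_max=12)
        nodes = np.array([[0, 0], [2, 0], [8, 0], [8, 8], [0, 8]], float)
        out = v.resample_nodes(v.Contour(nodes), p)
        assert len(out) == 4
        assert not any(np.allclose(n, [2, 0]) for n in out.nodes)

    def test_conforming_contour_unchanged(self):
        p = v.SnakeParams(s_min=3, s_max=12)
        c = v.init_circle((0, 0), 10, 11)  # spacing ~5.7 px
        out = v.resample_nodes(c, p)
        np.testing.assert_array_equal(out.nodes, c.nodes)

    def test_never_drops_below_three_nodes(self):
        p = v.SnakeParams(s_min=3, s_max=12)
        nodes = np.array([[0, 0], [1, 0], [0.5, 1]], float)
        out = v.resample_nodes(v.Contour(nodes), p)
        assert len(out) == 3

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_spacings_converge_into_bounds(self, seed):
        """Iterated resampling drives all spacings into [s_min, s_max] unless
        the 3-node floor binds."""
        rng = np.random.default_rng(seed)
        nodes = rng.uniform(0, 60, (rng.integers(3, 12), 2))
        if np.any(np.linalg.norm(np.diff(np.vstack([nodes, nodes[:1]]), axis=0),
                                 axis=1) < 1e-6):
            return
        p = v.SnakeParams(s_min=3, s_max=12)
        c = v.Contour(nodes)
        for _ in range(20):
            c = v.resample_nodes(c, p)
        sp = c.spacings()
        if len(c) > 3:
            assert np.all(sp <= p.s_max + 1e-9)
            assert np.all(sp >= p.s_min - 1e-9) or len(c) == 3


class TestSegmentSlice:
    def test_disk_contour_within_one_pixel_of_circle(self, disk_image):
        img, center, r = disk_image
        c = v.segment_slice(img, v.init_circle(center, 24, 24), None,
                            v.SnakeParams())
        radii = np.hypot(*(c.nodes - np.asarray(center)).T)
        assert np.abs(radii - r).max() < 1.5

    def test_iteration_cap_respected(self, disk_image):
        img, center, _ = disk_image
        p = v.SnakeParams(max_iter=1, edge_blur_px=0, refine_iter=0)
        rep = {}
        v.segment_slice(img, v.init_circle(center, 10, 10), None, p, report=rep)
        assert rep["iterations"] == 1

    def test_converged_input_returns_after_first_pass(self):
        uu, vv = np.mgrid[0:64, 0:64]
        ring = np.hypot(uu - 32, vv - 32)
        grad = sn.GradientImage(np.exp(-(ring - 20.0) ** 2))
        p = v.SnakeParams(alpha=0, beta=0, gamma=1.0, delta=0,
                          edge_blur_px=0)
        init = v.Contour(np.round(v.init_circle((32, 32), 20, 16).nodes))
        rep = {}
        out = v.segment_slice(np.zeros((64, 64)), init, None, p, grad=grad,
                              report=rep)
        assert rep["converged"]
        assert rep["iterations"] <= 3


@pytest.fixture(scope="module")
def cylinder_xsecs():
    """Cross sections of a realistic straight tube: blurred border, mild
    noise, edge-preserving smoothing as in the full pipeline."""
    spec = v.PhantomSpec(centerline_kind="straight", shape=(48, 48, 48),
                         spacing=(1.0, 1.0, 1.0), length_mm=30.0,
                         radius_mm=6.0, noise_sd=1.0, blur_sd_mm=0.5)
    stack, spline, _ = v.generate(spec, 0)
    stack = v.anisotropic_diffusion(stack, 10, 30.0, 0.15)
    return spec, v.resample_cross_sections(stack, spline, 2.0, 69, 0.35)


class TestSegmentStack:
    def test_cylinder_areas_within_five_percent(self, cylinder_xsecs):
        spec, xs = cylinder_xsecs
        contours = v.segment_stack(xs, (34, 34), v.SnakeParams(), start_index=0)
        analytic = np.pi * spec.radius_mm ** 2
        for c in contours:
            assert c is not None
            assert v.contour_area(c, 0.35) == pytest.approx(analytic, rel=0.05)

    def test_override_replaces_slice_verbatim(self, cylinder_xsecs):
        _, xs = cylinder_xsecs
        manual = v.init_circle((34, 34), 5, 7, slice_index=3)
        contours = v.segment_stack(xs, (34, 34), v.SnakeParams(),
                                   overrides={3: manual})
        np.testing.assert_array_equal(contours[3].nodes, manual.nodes)

    def test_mask_excludes_forbidden_region(self, cylinder_xsecs):
        """Pixels under the forbidden mask never host contour nodes."""
        spec, xs = cylinder_xsecs
        mask = np.zeros((69, 69), bool)
        mask[:, 50:] = True  # forbid the right part of every slice
        masks = [mask] * len(xs.images)
        contours = v.segment_stack(xs, (34, 34), v.SnakeParams(), masks=masks)
        for c in contours:
            assert c is not None
            iv = np.rint(c.nodes[:, 1]).astype(int)
            assert np.all(iv < 50)

    def test_strong_coupling_keeps_adjacent_contours_close(self, cylinder_xsecs):
        """With a large deviation weight, consecutive contours on identical
        slices stay within 1 px symmetric Hausdorff distance."""
        _, xs = cylinder_xsecs
        p = v.SnakeParams(delta=50.0)
        contours = v.segment_stack(xs, (34, 34), p)
        for a, b in zip(contours[2:-2], contours[3:-2]):
            d_ab = max(np.min(np.linalg.norm(b.nodes - pt, axis=1))
                       for pt in a.nodes)
            d_ba = max(np.min(np.linalg.norm(a.nodes - pt, axis=1))
                       for pt in b.nodes)
            assert max(d_ab, d_ba) < 1.0 + 1e-9

    def test_deterministic_repeat_is_bit_identical(self, cylinder_xsecs):
        _, xs = cylinder_xsecs
        a = v.segment_stack(xs, (34, 34), v.SnakeParams())
        b = v.segment_stack(xs, (34, 34), v.SnakeParams())
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.nodes, cb.nodes)

    def test_contour_json_round_trip(self, tmp_path, cylinder_xsecs):
        _, xs = cylinder_xsecs
        contours = v.segment_stack(xs, (34, 34), v.SnakeParams())
        path = tmp_path / "contours.json"
        sn.save_contours(contours, 0.5, path)
        back, px = sn.load_contours(path)
        assert px == 0.5
        np.testing.assert_allclose(back[1].nodes, contours[1].nodes)
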
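import numpy as np
import pytest

from fibremetrics.image import GrayImage
from fibremetrics.ridge import (
    RidgeParams,
    detect_lines,
    detect_multiscale,
    prune_short_branches,
    rasterize,
    sigma_from_width,
)
from fibremetrics.synthetic import centreline_recovery

from conftest import make_network, render_lines


class TestSigmaFromWidth:
    def test_closed_form(self):
        assert sigma_from_width(4) == pytest.approx(4 / (2 * np.sqrt(3)) + 0.5, abs=1e-9)
        assert sigma_from_width(4) == pytest.approx(1.6547, abs=1e-4)

    def test_non_positive_raises(self):
        for w in (0, -1):
            with pytest.raises(ValueError):
                sigma_from_width(w)

    def test_strictly_increasing(self):
        widths = np.linspace(0.5, 20, 40)
        sigmas = [sigma_from_width(w) for w in widths]
        assert all(a < b for a, b in zip(sigmas, sigmas[1:]))


def _params(w, **kw):
    return RidgeParams(line_width_min_px=w, line_width_max_px=w, **kw)


class TestDetectLines:
    def test_single_straight_line(self):
        truth = np.array([[64.0, 10.0], [64.0, 118.0]])
        img = render_lines([truth], width=4)
        net = prune_short_branches(detect_lines(img, _params(4)), 10)
        assert net.n_fibres == 1
        # perpendicular deviation from the true centreline (row 64)
        assert np.abs(net.fibres[0].vertices[:, 0] - 64.0).max() < 0.5

    def test_blank_image_empty_network(self):
        net = detect_lines(GrayImage(np.full((64, 64), 37.0)), _params(4))
        assert net.n_fibres == 0 and len(net.junctions) == 0

    def test_cross_junction_location(self):
        img = render_lines(
            [[(64.0, 10.0), (64.0, 118.0)], [(10.0, 64.0), (118.0, 64.0)]], width=4
        )
        net = prune_short_branches(detect_lines(img, _params(4)), 10)
        assert len(net.junctions) >= 1
        d = np.linalg.norm(net.junctions - np.array([64.0, 64.0]), axis=1)
        assert d.min() < 2.0

    def test_too_large_width_raises(self):
        with pytest.raises(ValueError, match="width"):
            detect_lines(GrayImage(np.zeros((64, 64))), _params(4), width_px=30)

    def test_translation_equivariance(self):
        base = np.array([[30.0, 20.0], [90.0, 100.0]])
        shift = np.array([7.0, 11.0])
        img1 = render_lines([base], width=4, size=160)
        img2 = render_lines([base + shift], width=4, size=160)
        n1 = prune_short_branches(detect_lines(img1, _params(4)), 10)
        n2 = prune_short_branches(detect_lines(img2, _params(4)), 10)
        frac, rmse = centreline_recovery(
            [f.vertices + shift for f in n1.fibres], [f.vertices for f in n2.fibres]
        )
        assert frac > 0.98 and rmse < 0.3

    def test_rot90_equivariance(self):
        img = render_lines([[(30.0, 20.0), (100.0, 90.0)], [(20.0, 100.0), (100.0, 110.0)]], width=4, size=160)
        net = prune_short_branches(detect_lines(img, _params(4)), 10)
        rot = GrayImage(np.rot90(img.pixels).copy())
        net_r = prune_short_branches(detect_lines(rot, _params(4)), 10)
        assert net_r.n_fibres == net.n_fibres
        assert net_r.total_length_px() == pytest.approx(net.total_length_px(), rel=0.01)


class TestPrune:
    def test_long_fibre_untouched(self):
        net = make_network([[(10.0, 10.0), (10.0, 110.0)]])
        out = prune_short_branches(net, 10)
        assert out.n_fibres == 1

    def test_min_zero_identity(self, y_network):
        out = prune_short_branches(y_network, 0)
        assert out.n_fibres == 3 and len(out.junctions) == 1

    def test_y_twig_removed_and_junction_dissolved(self):
        # oracle: explicit graph edit on the 3-edge toy graph — removing the
        # 3 px twig leaves a single through-fibre and no junction
        net = make_network(
            [
                [(64.0, 64.0), (64.0, 20.0)],
                [(64.0, 64.0), (64.0, 110.0)],
                [(64.0, 64.0), (61.0, 64.0)],  # 3 px twig
            ],
            junctions=[(64.0, 64.0)],
        )
        out = prune_short_branches(net, 10)
        assert out.n_fibres == 1
        assert len(out.junctions) == 0
        assert out.fibres[0].length_px == pytest.approx(90.0, abs=1e-6)

    def test_iterative_pruning(self):
        # after the twig goes, the stub that remains becomes prunable too
        net = make_network(
            [
                [(64.0, 10.0), (64.0, 60.0)],
                [(64.0, 60.0), (64.0, 66.0)],  # 6 px stub between junctions
                [(64.0, 60.0), (60.0, 60.0)],  # 4 px twig
                [(64.0, 66.0), (60.0, 66.0)],  # 4 px twig
                [(64.0, 66.0), (64.0, 116.0)],
            ],
            junctions=[(64.0, 60.0), (64.0, 66.0)],
        )
        out = prune_short_branches(net, 10)
        assert len(out.junctions) == 0
        assert out.n_fibres == 1
        assert out.fibres[0].length_px == pytest.approx(106.0, abs=1e-6)


class TestRasterize:
    def test_empty_network(self):
        mask = rasterize(make_network([[(10.0, 5.0), (10.0, 50.0)]], shape=(64, 64)))
        assert mask.shape == (64, 64)

    def test_horizontal_exact_pixels(self):
        mask = rasterize(make_network([[(10.0, 5.0), (10.0, 50.0)]], shape=(64, 64)))
        rows, cols = np.nonzero(mask)
        assert mask.sum() == 46
        assert set(rows) == {10}
        assert cols.min() == 5 and cols.max() == 50

    def test_pixel_count_bound(self):
        rng = np.random.default_rng(5)
        verts = np.cumsum(rng.uniform(-1.5, 1.5, (40, 2)), axis=0) + 60
        net = make_network([verts], shape=(128, 128))
        total = sum(f.length_px for f in net.fibres)
        assert rasterize(net).sum() <= np.ceil(total) + len(verts)


class TestMultiscale:
    def test_width_schedule(self):
        assert RidgeParams(line_width_min_px=5, line_width_max_px=20).widths() == [5, 10, 15, 20]
        assert RidgeParams(line_width_min_px=4, line_width_max_px=4).widths() == [4]
        # max is force-included even off the 5-grid
        assert RidgeParams(line_width_min_px=4, line_width_max_px=8).widths() == [4, 8]

    def test_single_width_equals_own_mask(self):
        img = render_lines([[(64.0, 10.0), (64.0, 118.0)]], width=4)
        amalgam, nets = detect_multiscale(img, _params(4, min_branch_px=10))
        assert len(nets) == 1
        assert np.array_equal(amalgam, rasterize(nets[0]))

    def test_union_is_exact_superset(self):
        img = render_lines(
            [[(40.0, 10.0), (40.0, 150.0)], [(110.0, 10.0), (110.0, 150.0)]],
            width=4,
            size=160,
        )
        params = RidgeParams(line_width_min_px=3, line_width_max_px=8, min_branch_px=10)
        amalgam, nets = detect_multiscale(img, params)
        union = np.zeros_like(amalgam)
        for net in nets:
            m = rasterize(net)
            assert np.array_equal(amalgam & m, m)  # superset of each
            union |= m
        assert np.array_equal(amalgam, union)  # exactly the union

    def test_thin_and_thick_pair(self):
        thin = np.array([[40.0, 10.0], [40.0, 190.0]])
        thick = np.array([[140.0, 10.0], [140.0, 190.0]])
        img = GrayImage(
            render_lines([thin], width=3, size=200).pixels
            + render_lines([thick], width=15, size=200, bg=0).pixels
        )
        params = RidgeParams(line_width_min_px=3, line_width_max_px=15, min_branch_px=12)
        amalgam, nets = detect_multiscale(img, params)
        # thin fibre recovered by the smallest width pass
        frac_thin, _ = centreline_recovery([thin], [f.vertices for f in nets[0].fibres])
        assert frac_thin > 0.9
        # both centrelines present in the amalgamated mask
        rows = np.nonzero(amalgam.any(axis=1))[0]
        assert (np.abs(rows - 40) <= 1).any() and (np.abs(rows - 140) <= 1).any()
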
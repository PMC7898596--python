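import numpy as np
import pytest

from fibremetrics.network_metrics import (
    MetricsRecord,
    avg_fibre_length,
    count_branchpoints,
    count_endpoints,
    curvature,
    curvature_sweep,
    fibre_thickness,
    hgu,
    network_record,
    normalise_record,
    total_length,
)
from fibremetrics.ridge import Fibre, FibreNetwork

from conftest import make_network


class TestCounts:
    def test_single_open_line(self, straight_network):
        assert count_endpoints(straight_network) == 2
        assert count_branchpoints(straight_network) == 0

    def test_closed_loop(self, loop_network):
        assert count_endpoints(loop_network) == 0
        assert count_branchpoints(loop_network) == 0

    def test_y_shape(self, y_network):
        assert count_endpoints(y_network) == 3
        assert count_branchpoints(y_network) == 1

    def test_cross_counts_once(self):
        net = make_network(
            [
                [(64.0, 64.0), (64.0, 10.0)],
                [(64.0, 64.0), (64.0, 118.0)],
                [(64.0, 64.0), (10.0, 64.0)],
                [(64.0, 64.0), (118.0, 64.0)],
            ],
            junctions=[(64.0, 64.0)],
        )
        assert count_endpoints(net) == 4
        assert count_branchpoints(net) == 1

    def test_two_disjoint_lines(self):
        net = make_network([[(10.0, 10.0), (10.0, 60.0)], [(40.0, 10.0), (40.0, 60.0)]])
        assert count_endpoints(net) == 4
        assert count_branchpoints(net) == 0


class TestLength:
    def test_straight_span(self, straight_network):
        assert total_length(straight_network) == pytest.approx(100.0, abs=0.5)

    def test_empty(self):
        assert total_length(make_network([])) == 0.0

    def test_diagonal(self):
        net = make_network([[(0.0, 0.0), (100.0, 100.0)]])
        assert total_length(net) == pytest.approx(100 * np.sqrt(2), abs=1.0)

    def test_micron_calibration(self):
        net = make_network([[(10.0, 5.0), (10.0, 105.0)]])
        net.pixel_size_um = 0.5
        assert total_length(net) == pytest.approx(50.0)


class TestRatios:
    def test_hgu_is_length_per_endpoint(self):
        # the normalised end-point metric E/L must be the exact inverse
        assert hgu(2, 100.0) == pytest.approx(50.0)
        assert 1.0 / hgu(2, 100.0) == pytest.approx(2 / 100.0)

    def test_hgu_missing_when_no_endpoints(self):
        assert np.isnan(hgu(0, 100.0))

    def test_hgu_scale_invariant(self):
        assert hgu(4, 200.0) == hgu(8, 400.0)

    def test_hgu_alternative_convention(self):
        assert hgu(2, 100.0, convention="endpoints_per_length") == pytest.approx(0.02)

    def test_avg_fibre_length_formula(self):
        assert avg_fibre_length(100.0, 2, 0) == pytest.approx(100.0)
        assert avg_fibre_length(120.0, 3, 1) == pytest.approx(60.0)
        assert np.isnan(avg_fibre_length(50.0, 0, 0))

    def test_fibre_thickness(self):
        # a 100 px line of width 4 occupies 400 px of matrix area
        assert fibre_thickness(400.0, 100.0) == pytest.approx(4.0)
        assert np.isnan(fibre_thickness(400.0, 0.0))
        assert fibre_thickness(800.0, 100.0) == 2 * fibre_thickness(400.0, 100.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_toy_graphs_against_enumeration(self, seed):
        # brute-force oracle: build star graphs whose E, B, L are known by
        # construction, then check the counting functions and the average
        # fibre length identity L / (0.5 (E + B)) on the network object
        rng = np.random.default_rng(seed)
        n_junc = rng.integers(1, 4)
        junctions = rng.uniform(100, 400, (n_junc, 2))
        fibres, true_len, free_ends = [], 0.0, 0
        for j in junctions:
            for _ in range(rng.integers(3, 6)):
                end = j + rng.uniform(30, 80) * _unit(rng)
                fibres.append([tuple(j), tuple(end)])
                true_len += float(np.linalg.norm(end - j))
                free_ends += 1
        for _ in range(rng.integers(0, 3)):  # isolated fibres
            a = rng.uniform(100, 400, 2)
            b = a + rng.uniform(30, 80) * _unit(rng)
            fibres.append([tuple(a), tuple(b)])
            true_len += float(np.linalg.norm(b - a))
            free_ends += 2
        net = make_network(fibres, junctions=junctions, shape=(512, 512))
        E, B = count_endpoints(net), count_branchpoints(net)
        L = total_length(net)
        assert E == free_ends and B == n_junc
        assert L == pytest.approx(true_len, rel=1e-9)
        assert avg_fibre_length(L, E, B) == pytest.approx(L / (0.5 * (E + B)))


def _unit(rng):
    phi = rng.uniform(0, 2 * np.pi)
    return np.array([np.sin(phi), np.cos(phi)])


def _arc_network(radius, span=1.2 * np.pi, centre=(250.0, 250.0)):
    phi = np.linspace(0, span, 1500)
    pts = np.column_stack(
        [centre[0] + radius * np.sin(phi), centre[1] + radius * np.cos(phi)]
    )
    return make_network([pts], shape=(512, 512))


class TestCurvature:
    def test_straight_line_zero(self):
        net = make_network([[(10.0, 10.0), (200.0, 150.0)]], shape=(256, 256))
        assert curvature(net, 10) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("window", [10, 20, 40])
    def test_circle_closed_form(self, window):
        # chord geometry: stepping a circle of radius r at arc length w
        # turns by w/r ~= 2 arcsin(w / 2r) per step
        r = 100.0
        expected = np.degrees(2 * np.arcsin(window / (2 * r)))
        assert curvature(_arc_network(r), window) == pytest.approx(expected, abs=0.5)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(11)
        verts = np.cumsum(rng.uniform(-2, 2, (80, 2)) + [1.5, 1.0], axis=0) + 100
        net = make_network([verts], shape=(512, 512))
        theta = np.radians(33.0)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        net_r = make_network([(verts - 250) @ rot.T + 250], shape=(512, 512))
        assert curvature(net_r, 12) == pytest.approx(curvature(net, 12), abs=0.5)

    def test_short_fibres_missing(self):
        net = make_network([[(10.0, 10.0), (10.0, 20.0)]])
        assert np.isnan(curvature(net, 40))

    def test_window_validation(self):
        with pytest.raises(ValueError):
            curvature(make_network([]), 1)

    def test_sweep_single_and_straight(self):
        net = make_network([[(10.0, 10.0), (10.0, 200.0)]], shape=(256, 256))
        single = curvature_sweep(net, 10, 10)
        assert list(single) == [10]
        sweep = curvature_sweep(net, 10, 50, 10)
        assert all(v == pytest.approx(0.0, abs=1e-6) for v in sweep.values())

    def test_wave_scale_ordering_reversal(self):
        # fine waviness dominates at small windows, coarse bends at large
        def wave(wavelength, amplitude):
            t = np.linspace(0, 400, 3000)
            pts = np.column_stack([250 + amplitude * np.sin(2 * np.pi * t / wavelength), 50 + t])
            return make_network([pts], shape=(512, 512))

        tight, broad = wave(40, 7), wave(200, 40)
        assert curvature(tight, 10) > curvature(broad, 10)
        assert curvature(tight, 60) < curvature(broad, 60)


class TestNormalisation:
    def test_defining_ratios(self):
        rec = MetricsRecord(endpoints=10, branchpoints=4, total_length=500.0)
        normalise_record(rec, image_area_px=1000_000)
        assert rec.norm_endpoints == pytest.approx(0.02)
        assert rec.norm_branchpoints == pytest.approx(0.008)
        assert rec.norm_length == pytest.approx(0.5)  # per 1000 px^2

    def test_zero_length_stays_missing(self):
        rec = MetricsRecord(endpoints=0, branchpoints=0, total_length=0.0)
        normalise_record(rec, 1024**2)
        assert np.isnan(rec.norm_endpoints) and np.isnan(rec.norm_length)

    def test_empty_network_record_all_missing(self):
        rec = network_record(make_network([]), image_id="blank")
        assert rec.endpoints == 0 and rec.branchpoints == 0 and rec.total_length == 0.0
        assert np.isnan(rec.hgu) and np.isnan(rec.avg_fibre_length)
        assert np.isnan(rec.norm_endpoints)

    def test_record_row_has_curvature_columns(self, y_network):
        rec = network_record(y_network, curvature_windows=(10, 30, 10))
        row = rec.as_row()
        assert {"curvature_w10", "curvature_w20", "curvature_w30"} <= set(row)
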